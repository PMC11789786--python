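# omiclust

Fusion-free multi-omics clustering for cancer subtype discovery.

Molecular subtyping groups patients of one cancer type by the joint signal in
several omics layers (e.g. mRNA expression, DNA methylation, miRNA). Most
integrative methods first *fuse* the layers into one matrix or similarity
network; omiclust instead keeps one branch per omics layer and couples the
branches only through training losses, so each layer retains its individual
signal while the model extracts the consensus.

## Model

Given M aligned matrices X^m (N patients × D_m features), each branch builds a
binary KNN patient graph A^m (edge iff either sample is in the other's
k-nearest-neighbor set) and learns:

- **low-level features** Z^m from a two-layer graph-convolutional encoder
  `Z_l = tanh(D^{-1/2}(A+I)D^{-1/2} Z_{l-1} W_l)`, constrained by
  reconstruction of both node attributes and graph structure,
  `L_Z = Σ_m ‖X^m − X̂^m‖²_F + Σ_m ‖A^m − Â^m‖²_F`;
- **high-level features** H^m = tanh(Z^m W_f), tied across layers by an
  NT-Xent contrastive loss L_H whose positive pairs are the same patient in
  different layers (temperature τ_F = 0.5);
- **soft assignments** Q^m = softmax(Z^m W_q), whose K columns are contrasted
  across layers (positives: same cluster index; temperature τ_L = 1.0) with an
  added cluster-size regularizer Σ_j s_j log s_j, s_j = mean_i q_ij, giving
  L_Q.

K-means on H^m, aligned to the label head's clusters by solving a K×K
assignment problem on the contingency-derived cost `G = max(g̃) − g̃`, yields
one-hot pseudo-labels P̂^m and a cross-entropy fine-tuning term
`L_C = −Σ_m Σ_{ij} P̂^m_ij log Q^m_ij`. The total objective is

```
L = L_Z + α (L_H + L_C) + β L_Q,        α = β = 1
```

and the final subtype of patient i is `argmax_j (1/M) Σ_m q_ij^m`. The number
of clusters can be fixed a priori or chosen automatically by the silhouette
score of K-means on the concatenated low-level features.

Training is full-batch Adam on a small reverse-mode autodiff engine included
in the package; no GPU is needed at typical cohort sizes.

## Worked example

```python
from omiclust import (SyntheticSpec, generate_multiomics, ContrastiveGCN,
                      evaluate_clustering, generate_survival)

bundle = generate_multiomics(SyntheticSpec(n_samples=60, n_clusters=3,
                                           omics_dims=(40, 30), seed=7))
est = ContrastiveGCN(n_clusters=3, random_state=0).fit(bundle.omics)
surv = generate_survival(bundle.labels, hazards=[0.2, 1.0, 3.0],
                         censor_rate=0.1, seed=7)
report = evaluate_clustering(est.labels_, labels_true=bundle.labels,
                             survival=surv)
print("cluster sizes:", report.cluster_sizes)
print(f"ARI = {report.ari:.3f}, NMI = {report.nmi:.3f}")
print(f"log-rank chi2 = {report.logrank_stat:.2f}, p = {report.logrank_p:.2e}")
```

Output:

```
cluster sizes: (21, 22, 17)
ARI = 1.000, NMI = 1.000
log-rank chi2 = 35.49, p = 1.97e-08
```

The two-view synthetic cohort plants three subtypes; the fitted model recovers
them exactly (ARI/NMI 1.0), and because the simulated hazards differ by
subtype, the recovered groups separate survival strongly (log-rank p ≈ 2e-8).

The same pipeline is available from the shell:

```bash
omiclust simulate --out-dir data/ --seed 7 --hazards 0.2,1.0,3.0
omiclust fit --omics data/omics1.csv --omics data/omics2.csv --k 3 --out run/
omiclust evaluate --subtypes run/subtypes.tsv --labels data/labels.csv \
    --survival data/survival.csv
omiclust select-k --omics data/omics1.csv --omics data/omics2.csv
```

Omics inputs are CSV/TSV with a header row of feature names and a first column
of sample IDs; files are aligned on the intersection of their sample IDs.

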