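# Methods

## Model and assumptions

omiclust clusters N patients measured on M omics layers without ever fusing
the layers. The working assumptions are:

- subtype structure is *shared* across layers: the same partition of patients
  underlies every X^m, even though each layer expresses it through its own
  features and carries its own nuisance variation;
- patient similarity within a layer is informative, so a KNN graph per layer
  is a reasonable relational prior; the graph is built once from the scaled
  input features and held fixed throughout training (the schedule builds
  graphs before any learning, and a moving graph would make the structure
  reconstruction target ill-defined);
- features are bounded: inputs are min-max scaled to [-1, 1] so the
  tanh-activated attribute decoder can reach its targets.

Each layer owns an encoder/decoder pair and two heads; layers interact only
through the contrastive losses. Removing a layer leaves every other branch's
forward pass bit-identical given identical weights — the fusion-free
contract, covered by a test.

## Objective

`L = L_Z + α (L_H + L_C) + β L_Q` with

- `L_Z`: Frobenius reconstruction of node attributes and of the binary KNN
  adjacency (without self loops), summed over layers;
- `L_H`: NT-Xent over high-level features; anchor h_i^m is positive with
  h_i^n (same patient, other layer) and negative with every other feature in
  layers m and n. The self pair (i, m) is *excluded from the denominator*
  rather than subtracted as e^{1/τ}; the two are algebraically identical but
  exclusion cannot produce a negative denominator when floating-point
  cosine(h, h) deviates from 1;
- `L_Q`: the same contrast applied to the K columns of the soft-assignment
  matrices (cluster-membership profiles), plus the regularizer
  Σ_m Σ_j s_j^m log s_j^m, which is bounded in [−M log K, 0], minimized by
  uniform cluster sizes, and keeps the label heads from collapsing to one
  cluster;
- `L_C`: cross-entropy of Q^m against matched one-hot pseudo-labels, summed
  (not averaged) over samples, matching the matrix form of the objective; a
  mean would only rescale the term relative to α. Logs are clipped at 1e-12.

## Training schedule

1. **Warm-up** (default 200 epochs): Adam on L_Z alone.
2. **Joint phase** (default 300 epochs): Adam on the full objective, with the
   pseudo-label term L_C switched on only after `finetune_start` (default
   150) joint epochs. The delay exists because cluster *indices* are
   arbitrary per layer and only the label-level contrast aligns them across
   layers; enabling L_C immediately lets each label head cement its own index
   permutation (each branch perfectly clustered, yet the final
   assignment-probability averaging mixes misaligned columns). Contrast
   first, then match and fine-tune.
3. **Matching refresh** every epoch (configurable): per layer, K-means
   (k-means++, 10 restarts, fixed per-layer seed) on H^m, hard labels off
   Q^m, contingency g̃, cost `G = max g̃ − g̃`, exact assignment solve, and
   emission of one-hot P̂^m. P̂ is a constant target — gradients do not flow
   through the matching, the standard pseudo-label reading, which prevents
   degenerate collapse through the matcher.

Steps are full-batch: the graph convolution and both contrastive denominators
are defined over the whole cohort, and at the cohort sizes this method
targets (tens to ~1100 patients) one dense full-batch step is cheap. No
batch-related knobs are exposed.

Gradients come from a minimal reverse-mode autodiff engine over numpy arrays
(`omiclust.autodiff`), sized exactly to the op set the model needs and
verified against finite differences in the test suite; the optimizer is a
standard Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `k_neighbors` | min(10, N−1) | KNN graph degree; a common default at cohort scale, exposed for sensitivity checks |
| `metric` | euclidean | neighbor ranking on already-scaled features; cosine available |
| `tau_f`, `tau_l` | 0.5, 1.0 | contrastive temperatures (method is insensitive in a broad range) |
| `alpha`, `beta` | 1.0, 1.0 | loss trade-offs; equal weighting is the reference setting |
| `hidden_dim`, `latent_dim`, `head_dim` | 256, 64, 64 | encoder [D_m, 256, 64] and one-layer feature head; ordinary autoencoder widths at omics feature counts |
| `lr` | 1e-3 | Adam step size |
| `warmup_epochs`, `train_epochs`, `finetune_start` | 200, 300, 150 | schedule lengths; enough for loss plateaus at desk scale |
| `n_clusters` | int or "auto" | "auto" picks K by silhouette of K-means on concatenated Z over `k_range` (default 2–8), ties to the smaller K |

Ablation switches `use_reconstruction`, `use_consensus`,
`use_cluster_contrast` drop L_Z, (L_H + L_C) and L_Q respectively; with
reconstruction disabled, warm-up epochs take no optimizer step but are still
logged so the history-length contract holds.

## Deterministic tie-breaking

- KNN distance ties: lower sample index wins (stable argsort).
- Label argmax and subtype argmax ties: lowest cluster index.
- Assignment-problem ties: the lexicographically smallest optimal permutation,
  obtained by greedily fixing each row to its smallest admissible column and
  verifying optimal completability of the remainder exactly.
- Silhouette ties in auto-K: smallest K.

All randomness (weight init, K-means restarts, generators) derives from a
single `random_state`; identical seeds give bit-identical training histories
on one platform.

## Synthetic-data generator

The generator plants K shared clusters: per layer, cluster centers are drawn
in a latent space of dimension min(D_m, 8) at scale `separation`, pushed
through a fixed random linear map to D_m features, then perturbed by i.i.d.
Gaussian noise (`noise_sd`) and a rank-1 layer-specific nuisance component
(`nuisance_sd`, a crude stand-in for batch-like structured variation), and
finally min-max scaled per feature to [-1, 1]. Defaults (N = 60, K = 3, two
layers of 40 and 30 features, separation 8, noise 0.3, nuisance 0.3, uniform
cluster proportions) define the standard well-separated test-bed used across
the suite; `separation = 0` produces a provably signal-free cohort.
Survival times are exponential with cluster-dependent hazards and independent
exponential censoring.

What the generator does **not** emulate: realistic marginal distributions of
expression or methylation (negative binomial, beta), feature-feature
correlation structure beyond the planted low-rank signal, missingness, or
unequal per-layer sample coverage. Passing recovery tests therefore shows the
algorithm recovers planted low-rank cluster structure under bounded noise —
not that it matches any consortium-data benchmark.

## Problem sizes and numerical choices

The suite and the reproduction script run at desk scale by choice: 60-sample
two-layer cohorts for recovery and ablation (5 replicates each), 1000
simulated datasets for log-rank calibration, 100 and 200 random instances for
the loss and assignment oracles. Degenerate inputs are handled explicitly:
constant features are dropped at load time with a warning, zero-norm feature
rows and empty soft clusters raise rather than silently propagating NaNs, a
non-finite loss aborts training naming the first offending component, and
`0 log 0` is taken as 0 in the size regularizer.

## Known limitations

- The cross-view index alignment relies on the label contrast finding the
  permutation early; with many clusters and weak signal it can still settle
  in a misaligned optimum, in which case per-layer partitions may be good
  while the averaged assignment is not (the per-layer `assignments_` are
  exposed for diagnosis).
- Silhouette-based K selection inherits silhouette's bias toward compact,
  spherical clusters in the concatenated latent space.
- The log-rank utility is an evaluation aid, not a survival-modeling module;
  no covariate adjustment is offered.
- Full-batch training is quadratic in N through the graph and contrastive
  terms; cohorts far beyond ~10⁴ samples would need a different regime.
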