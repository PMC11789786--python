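"""The multi-omics contrastive-GCN clustering estimator.

:class:`ContrastiveGCN` is an sklearn-style clusterer over a *list* of aligned
sample-by-feature matrices (one per omics view). Training follows a two-phase
schedule:

1. **Warm-up** — each branch's graph-convolutional autoencoder minimizes the
   attribute + structure reconstruction loss L_Z alone, so the low-level
   features Z settle on view-intrinsic structure before any coupling.
2. **Joint phase** — every epoch takes one full-batch Adam step on
   ``L_Z + alpha * (L_H + L_C) + beta * L_Q``: the feature-level contrast L_H,
   the label-level contrast + size regularizer L_Q, and the pseudo-label
   cross-entropy L_C against matched K-means assignments on the high-level
   features (refreshed every ``match_refresh_every`` epochs; the pseudo-label
   targets are constants, gradients do not flow through the matching).

   The pseudo-label term only switches on after ``finetune_start`` joint
   epochs. Cluster *indices* are per-view arbitrary, and only the label-level
   contrast aligns them across views; letting it settle first prevents the
   pseudo-label loss from cementing a cross-view index permutation that the
   final assignment averaging cannot undo. This mirrors the method's stated
   order: contrastive learning, then matching, then fine-tuning.

Steps are full-batch because both the graph convolution and the contrastive
denominators are defined over the entire cohort; at the cohort sizes this
method targets (hundreds to ~1100 patients) a full-batch step is cheap.

Final subtypes average the per-view soft assignments and take the row argmax.
When ``n_clusters="auto"``, the cluster count is chosen after warm-up by the
silhouette score of K-means on the concatenated low-level features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .autodiff import Adam, as_tensor
from .graph import knn_graph
from .losses import (LossBreakdown, feature_contrastive_loss,
                     label_contrastive_loss, pseudo_label_ce,
                     reconstruction_loss)
from .matching import match_pseudo_labels
from .model import (ModelConfig, OmicsBranch, decode_attributes,
                    decode_structure, encode, feature_head, init_autoencoder,
                    init_heads, label_head)

__all__ = ["ContrastiveGCN", "TrainConfig", "predict_subtypes", "select_k",
           "fit_multiomics"]


def predict_subtypes(Q_list) -> np.ndarray:
    """Subtype labels: row argmax of the across-view mean soft assignment.

    Ties resolve to the lowest cluster index.
    """
    Qs = [np.asarray(Q, dtype=float) for Q in Q_list]
    shape = Qs[0].shape
    for Q in Qs:
        if Q.shape != shape:
            raise ValueError("all Q matrices must share one shape")
        if np.any(np.abs(Q.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("Q rows must sum to 1")
    return np.argmax(np.mean(Qs, axis=0), axis=1)


def select_k(Z_list, k_range, seed: int, return_scores: bool = False):
    """Silhouette-based choice of the cluster count.

    Concatenates the low-level features column-wise, runs K-means for each
    candidate K and returns the K with the highest mean silhouette
    (Euclidean); ties resolve to the smallest K.
    """
    k_range = sorted(int(k) for k in k_range)
    if not k_range:
        raise ValueError("k_range must not be empty")
    Z = np.hstack([np.asarray(Z, dtype=float) for Z in Z_list])
    n = Z.shape[0]
    if k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError("k_range must lie within [2, N - 1]")
    scores = {}
    for k in k_range:
        labels = KMeans(n_clusters=k, n_init=10,
                        random_state=int(seed)).fit_predict(Z)
        scores[k] = float(silhouette_score(Z, labels, metric="euclidean"))
    best = max(scores, key=lambda k: (scores[k], -k))
    if return_scores:
        return best, pd.DataFrame({"K": list(scores), "silhouette": list(scores.values())})
    return best


_HISTORY_COLS = ["epoch", "phase", "L_F", "L_G", "L_Z", "L_H", "L_Q_contrast",
                 "L_Q_reg", "L_Q", "L_C", "L_P", "total"]


class ContrastiveGCN(ClusterMixin, BaseEstimator):
    """Fusion-free multi-omics subtype clustering.

    Parameters
    ----------
    n_clusters : int or "auto"
        Number of subtypes K; "auto" selects K by silhouette over `k_range`
        after the reconstruction warm-up.
    k_neighbors : int or None
        Neighbor count of the per-view KNN graphs; None means
        ``min(10, N - 1)``.
    metric : {"euclidean", "cosine"}
        Distance for the KNN graphs.
    alpha, beta : float
        Trade-off weights of the consensus term (L_H + L_C) and the
        cluster-contrast term L_Q in the total objective; both default to 1.
    tau_f, tau_l : float
        Temperatures of the feature-level (0.5) and label-level (1.0)
        contrastive losses.
    lr : float
        Adam learning rate.
    warmup_epochs, train_epochs : int
        Lengths of the reconstruction-only and joint phases.
    match_refresh_every : int
        Epoch period of the K-means + assignment-matching refresh.
    hidden_dim, latent_dim, head_dim : int
        Encoder widths [D_m, hidden_dim, latent_dim] and feature-head output.
    use_reconstruction, use_consensus, use_cluster_contrast : bool
        Ablation switches for L_Z, L_H + L_C and L_Q respectively.
    k_range : sequence of int
        Candidate cluster counts for ``n_clusters="auto"``.
    random_state : int
        Seed for every source of randomness (init, K-means).

    Attributes
    ----------
    labels_ : (N,) ndarray of int
        Final subtype of each sample.
    n_clusters_ : int
        The cluster count actually used.
    embedding_ : list of (N, latent_dim) ndarray
        Low-level features Z per view.
    high_level_ : list of (N, head_dim) ndarray
        High-level features H per view.
    assignments_ : list of (N, K) ndarray
        Soft assignments Q per view (rows sum to 1).
    branches_ : list of OmicsBranch
        Trained weights per view.
    graphs_ : list of AdjacencyGraph
        The fixed KNN graphs (built once from the input, never rebuilt).
    history_ : DataFrame
        Per-epoch loss components; length = warmup_epochs + train_epochs.
    """

    def __init__(self, n_clusters=3, *, k_neighbors=None, metric="euclidean",
                 alpha=1.0, beta=1.0, tau_f=0.5, tau_l=1.0, lr=1e-3,
                 warmup_epochs=200, train_epochs=300, match_refresh_every=1,
                 finetune_start=150, hidden_dim=256, latent_dim=64, head_dim=64,
                 use_reconstruction=True, use_consensus=True,
                 use_cluster_contrast=True, k_range=(2, 3, 4, 5, 6, 7, 8),
                 random_state=0):
        self.n_clusters = n_clusters
        self.k_neighbors = k_neighbors
        self.metric = metric
        self.alpha = alpha
        self.beta = beta
        self.tau_f = tau_f
        self.tau_l = tau_l
        self.lr = lr
        self.warmup_epochs = warmup_epochs
        self.train_epochs = train_epochs
        self.match_refresh_every = match_refresh_every
        self.finetune_start = finetune_start
        self.hidden_dim = hidden_dim
        self.latent_dim = latent_dim
        self.head_dim = head_dim
        self.use_reconstruction = use_reconstruction
        self.use_consensus = use_consensus
        self.use_cluster_contrast = use_cluster_contrast
        self.k_range = k_range
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------

    def _validate_views(self, X) -> list:
        if hasattr(X, "omics"):
            X = X.omics
        if isinstance(X, np.ndarray) and X.ndim == 2:
            X = [X]
        Xs = [np.asarray(x, dtype=float) for x in X]
        if not Xs:
            raise ValueError("at least one omics matrix is required")
        n = Xs[0].shape[0]
        for m, x in enumerate(Xs):
            if x.ndim != 2:
                raise ValueError(f"omics {m} is not a 2-D matrix")
            if x.shape[0] != n:
                raise ValueError("omics matrices disagree on sample count")
            if not np.all(np.isfinite(x)):
                raise ValueError(f"omics {m} contains non-finite values")
        if n < 2:
            raise ValueError("need at least 2 samples")
        return Xs

    @staticmethod
    def _check_finite(parts: dict, epoch: int) -> None:
        for name, value in parts.items():
            if value is not None and not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite loss component {name} at epoch {epoch}")

    def _forward_z(self, Xs, graphs, branches):
        return [encode(X, g.A_norm, (b.W1, b.W2))
                for X, g, b in zip(Xs, graphs, branches)]

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None):
        """Train on a list of aligned sample-by-feature matrices."""
        Xs = self._validate_views(X)
        n = Xs[0].shape[0]
        if self.warmup_epochs < 0 or self.train_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.tau_f <= 0 or self.tau_l <= 0:
            raise ValueError("temperatures must be positive")
        if self.n_clusters == "auto" and not len(tuple(self.k_range)):
            raise ValueError("n_clusters='auto' requires a non-empty k_range")

        k_nn = min(10, n - 1) if self.k_neighbors is None else int(self.k_neighbors)
        graphs = [knn_graph(x, k_nn, metric=self.metric) for x in Xs]

        rng = np.random.default_rng(self.random_state)
        base_cfg = ModelConfig(hidden_dim=self.hidden_dim,
                               latent_dim=self.latent_dim,
                               head_dim=self.head_dim, n_clusters=2)
        auto_parts = [init_autoencoder(x.shape[1], base_cfg, rng) for x in Xs]
        km_seeds = [int(rng.integers(2 ** 31 - 1)) for _ in Xs]

        history: list[dict] = []

        # Phase 1: reconstruction warm-up (heads untouched).
        ae_params = [t for parts in auto_parts for t in parts.values()]
        opt = Adam(ae_params, lr=self.lr)
        for epoch in range(self.warmup_epochs):
            Zs = [encode(x, g.A_norm, (p["W1"], p["W2"]))
                  for x, g, p in zip(Xs, graphs, auto_parts)]
            Xhats = [decode_attributes(Z, g.A_norm, (p["Wd2"], p["Wd1"], p["Wd0"]))
                     for Z, g, p in zip(Zs, graphs, auto_parts)]
            Ahats = [decode_structure(Z, p["Wstruct"])
                     for Z, p in zip(Zs, auto_parts)]
            L_F, L_G, L_Z = reconstruction_loss(Xs, Xhats, [g.A for g in graphs],
                                                Ahats)
            self._check_finite({"L_Z": L_Z.item()}, epoch)
            if self.use_reconstruction:
                opt.zero_grad()
                L_Z.backward()
                opt.step()
            history.append({"epoch": epoch, "phase": "warmup",
                            "L_F": L_F.item(), "L_G": L_G.item(),
                            "L_Z": L_Z.item(), "L_H": np.nan,
                            "L_Q_contrast": np.nan, "L_Q_reg": np.nan,
                            "L_Q": np.nan, "L_C": np.nan, "L_P": np.nan,
                            "total": L_Z.item() if self.use_reconstruction
                            else np.nan})

        # Resolve K (silhouette on concatenated low-level features if "auto").
        if self.n_clusters == "auto":
            Z_now = [encode(x, g.A_norm,
                            (p["W1"].value, p["W2"].value))
                     for x, g, p in zip(Xs, graphs, auto_parts)]
            K = select_k(Z_now, self.k_range, seed=int(self.random_state))
        else:
            K = int(self.n_clusters)
            if K < 1:
                raise ValueError("n_clusters must be >= 1")
        cfg = ModelConfig(hidden_dim=self.hidden_dim, latent_dim=self.latent_dim,
                          head_dim=self.head_dim, n_clusters=K)
        cfg.validate()
        branches = [OmicsBranch(**parts, **init_heads(cfg, rng))
                    for parts in auto_parts]

        # Phase 2: joint objective with pseudo-label matching.
        opt = Adam([t for b in branches for t in b.parameters()], lr=self.lr)
        P_hats = None
        for step in range(self.train_epochs):
            epoch = self.warmup_epochs + step
            Zs = self._forward_z(Xs, graphs, branches)
            Hs = [feature_head(Z, b.Wf, b.bf) for Z, b in zip(Zs, branches)]
            Qs = [label_head(Z, b.Wq, b.bq) for Z, b in zip(Zs, branches)]
            Xhats = [decode_attributes(Z, g.A_norm, (b.Wd2, b.Wd1, b.Wd0))
                     for Z, g, b in zip(Zs, graphs, branches)]
            Ahats = [decode_structure(Z, b.Wstruct)
                     for Z, b in zip(Zs, branches)]
            L_F, L_G, L_Z = reconstruction_loss(Xs, Xhats, [g.A for g in graphs],
                                                Ahats)
            if len(Xs) >= 2:
                L_H = feature_contrastive_loss(Hs, self.tau_f)
                L_Qc, L_Qr, L_Q = label_contrastive_loss(Qs, self.tau_l)
            else:  # single view: cross-view contrasts are vacuous
                L_H = L_Qc = L_Qr = L_Q = as_tensor(0.0)
            L_C = None
            if self.use_consensus and step >= self.finetune_start:
                if P_hats is None or step % max(1, int(self.match_refresh_every)) == 0:
                    P_hats = [match_pseudo_labels(H.value, Q.value, s).P_hat
                              for H, Q, s in zip(Hs, Qs, km_seeds)]
                L_C = pseudo_label_ce(P_hats, Qs)

            objective = None
            if self.use_reconstruction:
                objective = L_Z
            if self.use_consensus:
                term = (L_H if L_C is None else L_H + L_C) * self.alpha
                objective = term if objective is None else objective + term
            if self.use_cluster_contrast:
                term = L_Q * self.beta
                objective = term if objective is None else objective + term

            parts = {"L_Z": L_Z.item(), "L_H": L_H.item(), "L_Q": L_Q.item(),
                     "L_C": None if L_C is None else L_C.item()}
            self._check_finite(parts, epoch)
            if objective is not None:
                opt.zero_grad()
                objective.backward()
                opt.step()
            lc = np.nan if L_C is None else L_C.item()
            history.append({"epoch": epoch, "phase": "train",
                            "L_F": L_F.item(), "L_G": L_G.item(),
                            "L_Z": L_Z.item(), "L_H": L_H.item(),
                            "L_Q_contrast": L_Qc.item(), "L_Q_reg": L_Qr.item(),
                            "L_Q": L_Q.item(), "L_C": lc,
                            "L_P": L_H.item() + (0.0 if L_C is None else lc),
                            "total": np.nan if objective is None
                            else objective.item()})

        # Final detached forward pass.
        Zv = [encode(x, g.A_norm, (b.W1.value, b.W2.value))
              for x, g, b in zip(Xs, graphs, branches)]
        Hv = [feature_head(Z, b.Wf.value, b.bf.value)
              for Z, b in zip(Zv, branches)]
        Qv = [label_head(Z, b.Wq.value, b.bq.value)
              for Z, b in zip(Zv, branches)]

        self.n_features_in_ = sum(x.shape[1] for x in Xs)
        self.n_clusters_ = K
        self.graphs_ = graphs
        self.branches_ = branches
        self.embedding_ = Zv
        self.high_level_ = Hv
        self.assignments_ = Qv
        self.labels_ = predict_subtypes(Qv)
        self.history_ = pd.DataFrame(history, columns=_HISTORY_COLS)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class TrainConfig:
    """Flat, file-friendly view of the estimator parameters (YAML/CLI use)."""

    n_clusters: int | str = 3
    k_neighbors: int | None = None
    metric: str = "euclidean"
    alpha: float = 1.0
    beta: float = 1.0
    tau_f: float = 0.5
    tau_l: float = 1.0
    lr: float = 1e-3
    warmup_epochs: int = 200
    train_epochs: int = 300
    match_refresh_every: int = 1
    finetune_start: int = 150
    hidden_dim: int = 256
    latent_dim: int = 64
    head_dim: int = 64
    use_reconstruction: bool = True
    use_consensus: bool = True
    use_cluster_contrast: bool = True
    k_range: tuple = (2, 3, 4, 5, 6, 7, 8)
    random_state: int = 0

    def build(self) -> ContrastiveGCN:
        params = asdict(self)
        n_clusters = params.pop("n_clusters")
        return ContrastiveGCN(n_clusters, **params)


def fit_multiomics(omics, config: TrainConfig | None = None) -> ContrastiveGCN:
    """Thin functional wrapper: build the estimator from `config` and fit."""
    config = config or TrainConfig()
    return config.build().fit(omics)
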