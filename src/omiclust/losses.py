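"""Objective terms coupling the per-omics branches.

Reconstruction keeps each branch faithful to its own view (attribute and
graph-structure Frobenius losses, L_F and L_G, summed to L_Z). Two contrastive
terms enforce cross-view consistency:

* a feature-level NT-Xent loss L_H on the high-level features H, whose
  positive pairs are the same patient seen in different views;
* a label-level contrast on the columns of the soft assignments Q (positive
  pairs: the same cluster index in different views), plus an entropy-style
  regularizer sum_j s_j log s_j on the mean assignment vector s that pushes
  cluster sizes away from degenerate collapse; their sum is L_Q.

A pseudo-label cross-entropy L_C ties Q to matched K-means assignments, and
the total objective is L_Z + alpha * (L_H + L_C) + beta * L_Q.

In both contrastive denominators the self term (the pair of an object with
itself, whose cosine is 1) is removed by *excluding* it from the double sum
rather than subtracting e^{1/tau}; the two are mathematically identical, but
exclusion cannot go negative when floating-point cosine(h, h) != 1 exactly.

Like the model forward functions, every loss accepts plain ndarrays or
autodiff Tensors and returns the same kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = ["LossBreakdown", "reconstruction_loss", "cosine_sim",
           "feature_contrastive_loss", "label_contrastive_loss",
           "pseudo_label_ce", "total_loss"]

_LOG_CLIP = 1e-12


@dataclass
class LossBreakdown:
    """All loss components of one epoch, as plain floats.

    Invariants: ``L_Z = L_F + L_G``; ``L_P = L_H + L_C``;
    ``total = L_Z + alpha * L_P + beta * L_Q`` (restricted to the enabled
    components during ablations); ``L_Q_reg in [-M log K, 0]``.
    """

    L_F: float = 0.0
    L_G: float = 0.0
    L_Z: float = 0.0
    L_H: float = 0.0
    L_Q_contrast: float = 0.0
    L_Q_reg: float = 0.0
    L_Q: float = 0.0
    L_C: float = 0.0
    L_P: float = 0.0
    total: float = 0.0
    s: list = field(default_factory=list)


def _any_tensor(*seqs) -> bool:
    return any(isinstance(x, Tensor) for seq in seqs for x in seq)


def _out(t: Tensor, tensor_mode: bool):
    return t if tensor_mode else float(t.value)


def reconstruction_loss(X_list, Xhat_list, A_list, Ahat_list):
    """Frobenius reconstruction losses summed over views.

    Returns ``(L_F, L_G, L_Z)`` with ``L_F = sum_m ||X^m - Xhat^m||_F^2``,
    ``L_G = sum_m ||A^m - Ahat^m||_F^2`` (A is the binary KNN graph without
    self loops) and ``L_Z = L_F + L_G``.
    """
    if not (len(X_list) == len(Xhat_list) == len(A_list) == len(Ahat_list)):
        raise ValueError("all four lists must have one entry per view")
    tensor_mode = _any_tensor(X_list, Xhat_list, A_list, Ahat_list)
    L_F = as_tensor(0.0)
    L_G = as_tensor(0.0)
    for X, Xh, A, Ah in zip(X_list, Xhat_list, A_list, Ahat_list):
        X, Xh, A, Ah = map(as_tensor, (X, Xh, A, Ah))
        if X.shape != Xh.shape:
            raise ValueError("X and Xhat shape mismatch")
        if A.shape != Ah.shape:
            raise ValueError("A and Ahat shape mismatch")
        dX = X - Xh
        dA = A - Ah
        L_F = L_F + (dX * dX).sum()
        L_G = L_G + (dA * dA).sum()
    L_Z = L_F + L_G
    return (_out(L_F, tensor_mode), _out(L_G, tensor_mode),
            _out(L_Z, tensor_mode))


def cosine_sim(u, v) -> float:
    """Cosine similarity of two vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("degenerate feature vector (zero norm)")
    return float(u @ v / (nu * nv))


def _row_normalize(H: Tensor) -> Tensor:
    norms = (H * H).sum(axis=1, keepdims=True) ** 0.5
    return H / norms


def _ntxent_pair(Am: Tensor, An: Tensor, tau: float) -> Tensor:
    """One ordered NT-Xent term over the rows of row-normalized Am, An.

    Positives are matching rows; the denominator for anchor row i sums the
    exponentiated similarities of row i of Am against every row of An and
    every *other* row of Am (self pair excluded).
    """
    n = Am.shape[0]
    eye = np.eye(n)
    S_mn = Am @ An.T
    S_mm = Am @ Am.T
    E_mn = (S_mn / tau).exp()
    E_mm = (S_mm / tau).exp()
    pos = (S_mn * eye).sum(axis=1) / tau                      # d(a_i, b_i)/tau
    denom = (E_mn.sum(axis=1) + E_mm.sum(axis=1)
             - (E_mm * eye).sum(axis=1))                      # self excluded
    return (denom.log() - pos).mean()


def feature_contrastive_loss(H_list, tau_f: float):
    """Cumulative high-level feature contrast L_H across all view pairs.

    ``L_H = 1/2 * sum_m sum_{n != m} l_F^{(mn)}`` where each ordered term is
    the NT-Xent loss with the same patient across views as positive pair.
    """
    if len(H_list) < 2:
        raise ValueError("contrast requires >= 2 omics")
    if tau_f <= 0:
        raise ValueError("temperature must be positive")
    tensor_mode = _any_tensor(H_list)
    Hs = [as_tensor(H) for H in H_list]
    n = Hs[0].shape[0]
    for H in Hs:
        if H.shape[0] != n:
            raise ValueError("all views must share the sample count")
        if np.any(np.linalg.norm(H.value, axis=1) == 0):
            raise ValueError("degenerate feature vector (zero norm row)")
    normed = [_row_normalize(H) for H in Hs]
    L = as_tensor(0.0)
    for m in range(len(Hs)):
        for nn in range(len(Hs)):
            if nn != m:
                L = L + _ntxent_pair(normed[m], normed[nn], tau_f)
    return _out(L * 0.5, tensor_mode)


def label_contrastive_loss(Q_list, tau_l: float):
    """Cluster-assignment contrast plus the cluster-size regularizer.

    The contrasted objects are the K columns of each Q (the per-cluster
    membership profiles); positives are the same cluster index across views.
    The regularizer is ``sum_m sum_j s_j^m log s_j^m`` with
    ``s_j^m = mean_i q_ij^m`` and the convention ``0 log 0 = 0``.

    Returns ``(L_Q_contrast, L_Q_reg, L_Q)``.
    """
    if len(Q_list) < 2:
        raise ValueError("contrast requires >= 2 omics")
    if tau_l <= 0:
        raise ValueError("temperature must be positive")
    tensor_mode = _any_tensor(Q_list)
    Qs = [as_tensor(Q) for Q in Q_list]
    k = Qs[0].shape[1]
    if k < 2:
        raise ValueError("label contrast requires K >= 2")
    for Q in Qs:
        if Q.shape != Qs[0].shape:
            raise ValueError("all Q matrices must share one shape")
        if np.any(np.linalg.norm(Q.value, axis=0) == 0):
            raise ValueError("empty soft cluster (zero-norm column)")
        rowsum = Q.value.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-6):
            raise ValueError("Q rows must sum to 1")
    cols = [_row_normalize(Q.T) for Q in Qs]  # rows of Q.T are the columns
    contrast = as_tensor(0.0)
    for m in range(len(Qs)):
        for nn in range(len(Qs)):
            if nn != m:
                contrast = contrast + _ntxent_pair(cols[m], cols[nn], tau_l)
    contrast = contrast * 0.5
    reg = as_tensor(0.0)
    for Q in Qs:
        s = Q.mean(axis=0)
        reg = reg + (s * s.clip_min(_LOG_CLIP).log()).sum()
    total = contrast + reg
    return (_out(contrast, tensor_mode), _out(reg, tensor_mode),
            _out(total, tensor_mode))


def pseudo_label_ce(P_list, Q_list):
    """Cross-entropy of soft assignments against matched one-hot pseudo-labels.

    ``L_C = -sum_m sum_{i,j} P^m_ij log Q^m_ij`` (a sum, not a mean, over
    samples); the log is clipped below at 1e-12.
    """
    if len(P_list) != len(Q_list):
        raise ValueError("P and Q lists must have one entry per view")
    tensor_mode = _any_tensor(P_list, Q_list)
    L = as_tensor(0.0)
    for P, Q in zip(P_list, Q_list):
        P, Q = as_tensor(P), as_tensor(Q)
        if P.shape != Q.shape:
            raise ValueError("P and Q shape mismatch")
        pv = P.value
        if not (np.all(np.isin(pv, (0.0, 1.0))) and np.all(pv.sum(axis=1) == 1)):
            raise ValueError("pseudo-label rows must be one-hot")
        L = L + (-(P * Q.clip_min(_LOG_CLIP).log()).sum())
    return _out(L, tensor_mode)


def total_loss(breakdown: LossBreakdown, alpha: float, beta: float) -> float:
    """Total objective ``L_Z + alpha * (L_H + L_C) + beta * L_Q``."""
    return breakdown.L_Z + alpha * (breakdown.L_H + breakdown.L_C) \
        + beta * breakdown.L_Q
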