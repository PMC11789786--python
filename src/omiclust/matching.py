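"""Aligning K-means clusters on high-level features with label-head clusters.

K-means cluster indices and label-head cluster indices are arbitrary and do not
correspond; before the K-means partition can serve as a pseudo-label target for
the label head, its indices must be permuted to agree. The alignment is the
classic assignment problem on a cost matrix derived from the label/K-means
contingency table: minimizing ``G = max(g) - g`` maximizes the diagonal
agreement of the permuted contingency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = ["MatchingState", "kmeans_assign", "contingency", "cost_matrix",
           "solve_assignment", "relabel", "match_pseudo_labels"]


@dataclass
class MatchingState:
    """Per-view matching artifacts of one refresh."""

    p: np.ndarray          # K-means labels, length N
    centers: np.ndarray    # K x d_h
    L: np.ndarray          # label-head argmax labels, length N
    g: np.ndarray          # K x K contingency counts (rows: L, cols: p)
    G: np.ndarray          # K x K cost
    E: np.ndarray          # K x K permutation matrix
    P_hat: np.ndarray      # N x K matched one-hot pseudo-labels


def kmeans_assign(H: np.ndarray, K: int, seed: int):
    """Lloyd's K-means (k-means++ init, 10 restarts) on high-level features.

    Returns ``(labels, centers)`` with ``labels[i] = argmin_j ||h_i - c_j||``.
    """
    H = np.asarray(H, dtype=float)
    if H.shape[0] < K:
        raise ValueError("K-means needs at least K samples")
    km = KMeans(n_clusters=K, n_init=10, random_state=int(seed))
    p = km.fit_predict(H)
    return p, km.cluster_centers_


def contingency(L: np.ndarray, p: np.ndarray, K: int) -> np.ndarray:
    """Count matrix g[i, j] = #{samples with label-head label i, K-means label j}."""
    L = np.asarray(L)
    p = np.asarray(p)
    if L.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    for name, v in (("L", L), ("p", p)):
        if v.min() < 0 or v.max() >= K:
            raise ValueError(f"{name} contains labels outside [0, {K})")
    g = np.zeros((K, K), dtype=int)
    np.add.at(g, (L, p), 1)
    return g


def cost_matrix(g: np.ndarray) -> np.ndarray:
    """Turn agreement counts into assignment costs: G = max(g) - g."""
    g = np.asarray(g)
    if np.any(g < 0):
        raise ValueError("contingency counts must be nonnegative")
    return g.max() - g


def solve_assignment(G: np.ndarray) -> np.ndarray:
    """Exact minimum-cost permutation matrix for a square cost matrix.

    Among all optimal permutations the lexicographically smallest one (read as
    the sequence of matched columns for rows 0, 1, ...) is returned, so the
    result is deterministic even when ties occur. Row i is constrained
    greedily to its smallest admissible column, admissibility being checked by
    solving the remaining subproblem exactly.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("cost matrix must be square")
    K = G.shape[0]
    rows, cols = linear_sum_assignment(G)
    best = G[rows, cols].sum()
    perm = np.empty(K, dtype=int)
    free = list(range(K))
    fixed_cost = 0.0
    for i in range(K):
        for j in free:
            rest_rows = np.arange(i + 1, K)
            rest_cols = [c for c in free if c != j]
            sub_cost = 0.0
            if rest_rows.size:
                sub = G[np.ix_(rest_rows, rest_cols)]
                rr, cc = linear_sum_assignment(sub)
                sub_cost = sub[rr, cc].sum()
            if np.isclose(fixed_cost + G[i, j] + sub_cost, best,
                          rtol=1e-12, atol=1e-9):
                perm[i] = j
                fixed_cost += G[i, j]
                free.remove(j)
                break
        else:  # pragma: no cover - defensive
            raise RuntimeError("no admissible column found (numerical issue)")
    E = np.zeros((K, K))
    E[np.arange(K), perm] = 1.0
    return E


def relabel(p: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Map K-means labels through the matching permutation to one-hot targets.

    ``E[k, s] = 1`` matches label-head cluster k with K-means cluster s; a
    sample with K-means label s therefore gets the one-hot vector at k.
    """
    E = np.asarray(E)
    K = E.shape[0]
    if (E.shape != (K, K) or not np.all(np.isin(E, (0.0, 1.0)))
            or not np.all(E.sum(axis=0) == 1) or not np.all(E.sum(axis=1) == 1)):
        raise ValueError("E must be a permutation matrix")
    p = np.asarray(p)
    if p.min() < 0 or p.max() >= K:
        raise ValueError("p contains labels outside the permutation range")
    col_to_row = np.argmax(E, axis=0)  # s -> k
    hard = col_to_row[p]
    P_hat = np.zeros((len(p), K))
    P_hat[np.arange(len(p)), hard] = 1.0
    return P_hat


def match_pseudo_labels(H: np.ndarray, Q: np.ndarray, seed: int) -> MatchingState:
    """One full matching refresh for a single view.

    Runs K-means on H, reads hard labels off Q, builds the contingency and
    cost matrices, solves the assignment and emits matched one-hot
    pseudo-labels.
    """
    K = Q.shape[1]
    p, centers = kmeans_assign(H, K, seed)
    L = np.argmax(Q, axis=1)  # ties resolve to the lowest index
    g = contingency(L, p, K)
    G = cost_matrix(g)
    E = solve_assignment(G)
    P_hat = relabel(p, E)
    return MatchingState(p=p, centers=centers, L=L, g=g, G=G, E=E, P_hat=P_hat)
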