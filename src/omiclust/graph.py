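"""Patient-similarity KNN graphs and their normalized adjacency.

Each omics view gets its own binary graph: an edge joins samples i and j when
either is among the other's k nearest neighbors (the OR-union rule, which makes
the adjacency symmetric by construction). Graph convolutions then operate on
the self-loop symmetric normalization D^{-1/2} (A + I) D^{-1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import pairwise_distances

__all__ = ["AdjacencyGraph", "knn_graph", "normalize_adjacency"]


@dataclass
class AdjacencyGraph:
    """A binary KNN graph and its self-loop symmetric normalization.

    Attributes
    ----------
    A : (N, N) ndarray
        Binary adjacency, symmetric, zero diagonal.
    A_prime : (N, N) ndarray
        ``A + I``.
    D : (N,) ndarray
        Degrees of ``A_prime`` (each >= 1 because of the self loop).
    A_norm : (N, N) ndarray
        ``D^{-1/2} A_prime D^{-1/2}``; symmetric, eigenvalues in (-1, 1].
    k : int
        Neighbor count used to build ``A``.
    """

    A: np.ndarray
    A_prime: np.ndarray
    D: np.ndarray
    A_norm: np.ndarray
    k: int


def knn_graph(X: np.ndarray, k: int, metric: str = "euclidean") -> AdjacencyGraph:
    """Build the binary KNN graph of the rows of `X`.

    ``A[i, j] = 1`` iff i is among the k nearest neighbors of j OR j is among
    the k nearest neighbors of i; the self sample is excluded from neighbor
    sets. Distance ties are broken toward the lower sample index so the graph
    is reproducible across platforms.

    Parameters
    ----------
    X : (N, D) array-like
        Sample feature matrix; must be finite.
    k : int
        Neighbor count, ``1 <= k <= N - 1``.
    metric : {"euclidean", "cosine"}
        Distance used to rank neighbors.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D sample-by-feature matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    n = X.shape[0]
    if k >= n:
        raise ValueError("k must be < number of samples")
    if k < 1:
        raise ValueError("k must be >= 1")
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unsupported metric: {metric!r}")

    dist = pairwise_distances(X, metric=metric)
    np.fill_diagonal(dist, np.inf)  # self excluded from neighbor sets
    # stable sort keeps the lower index first among distance ties
    order = np.argsort(dist, axis=1, kind="stable")
    neigh = order[:, :k]

    A = np.zeros((n, n), dtype=float)
    rows = np.repeat(np.arange(n), k)
    A[rows, neigh.ravel()] = 1.0
    A = np.maximum(A, A.T)  # OR-union symmetrization
    np.fill_diagonal(A, 0.0)

    A_prime, D, A_norm = normalize_adjacency(A)
    return AdjacencyGraph(A=A, A_prime=A_prime, D=D, A_norm=A_norm, k=k)


def normalize_adjacency(A: np.ndarray):
    """Self-loop symmetric normalization of a binary adjacency.

    Returns ``(A_prime, D, A_norm)`` with ``A_prime = A + I``,
    ``D_ii = sum_j A_prime[i, j]`` and ``A_norm = D^{-1/2} A_prime D^{-1/2}``.

    Raises
    ------
    ValueError
        If `A` is not square/symmetric or has a nonzero diagonal.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("A must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("A must have a zero diagonal")
    A_prime = A + np.eye(A.shape[0])
    D = A_prime.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(D)
    A_norm = A_prime * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return A_prime, D, A_norm
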