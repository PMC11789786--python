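"""K-means, contingency, assignment solving and pseudo-label emission."""

from itertools import permutations

import numpy as np
import pytest

from omiclust import (contingency, cost_matrix, kmeans_assign,
                      match_pseudo_labels, relabel, solve_assignment)


def brute_force_assignment(G):
    """Enumerate all K! permutations; return (best cost, lex-smallest argmin)."""
    K = G.shape[0]
    best_cost, best_perm = None, None
    for perm in permutations(range(K)):
        cost = sum(G[i, perm[i]] for i in range(K))
        if best_cost is None or cost < best_cost - 1e-12:
            best_cost, best_perm = cost, perm
    return best_cost, best_perm


def test_kmeans_two_obvious_clusters():
    H = np.array([[0.0], [0.1], [10.0], [10.1]])
    p, centers = kmeans_assign(H, 2, seed=0)
    assert p[0] == p[1] != p[2] == p[3]
    np.testing.assert_allclose(sorted(centers.ravel()), [0.05, 10.05])
    # exhaustive over all 2-partitions: no split has lower within-cluster SS
    def wss(idx):
        sub = H[list(idx)]
        return float(np.sum((sub - sub.mean(axis=0)) ** 2))

    from itertools import combinations
    best = min(wss(part) + wss(set(range(4)) - set(part))
               for r in (1, 2, 3) for part in combinations(range(4), r))
    found = sum(wss(np.flatnonzero(p == c)) for c in (0, 1))
    assert found == pytest.approx(best)


def test_kmeans_degenerate_cluster_counts(rng):
    H = rng.normal(size=(6, 2))
    p1, c1 = kmeans_assign(H, 1, seed=0)
    assert set(p1) == {0}
    np.testing.assert_allclose(c1[0], H.mean(axis=0))
    pn, cn = kmeans_assign(H, 6, seed=0)
    assert len(set(pn)) == 6
    np.testing.assert_allclose(np.sort(cn, axis=0), np.sort(H, axis=0))
    with pytest.raises(ValueError):
        kmeans_assign(H, 7, seed=0)


def test_contingency_examples():
    np.testing.assert_array_equal(
        contingency(np.array([0, 0, 1, 1]), np.array([0, 0, 1, 1]), 2),
        [[2, 0], [0, 2]])
    np.testing.assert_array_equal(
        contingency(np.array([0, 0, 1, 1]), np.array([1, 1, 0, 0]), 2),
        [[0, 2], [2, 0]])


def test_contingency_total_is_n(rng):
    for _ in range(10):
        k = int(rng.integers(2, 5))
        n = int(rng.integers(3, 20))
        L = rng.integers(0, k, size=n)
        p = rng.integers(0, k, size=n)
        assert contingency(L, p, k).sum() == n
    with pytest.raises(ValueError, match="outside"):
        contingency(np.array([0, 3]), np.array([0, 1]), 2)


def test_cost_matrix_examples():
    np.testing.assert_array_equal(cost_matrix(np.array([[0, 2], [2, 0]])),
                                  [[2, 0], [0, 2]])
    np.testing.assert_array_equal(cost_matrix(np.full((3, 3), 5)), 0)
    assert cost_matrix(np.array([[1, 4], [0, 2]])).min() == 0


def test_solve_assignment_examples():
    np.testing.assert_array_equal(solve_assignment(np.array([[2.0, 0.0], [0.0, 2.0]])),
                                  [[0, 1], [1, 0]])
    np.testing.assert_array_equal(solve_assignment(np.zeros((3, 3))), np.eye(3))
    np.testing.assert_array_equal(solve_assignment(np.array([[0.0, 1.0], [1.0, 0.0]])),
                                  np.eye(2))
    with pytest.raises(ValueError, match="square"):
        solve_assignment(np.zeros((2, 3)))


def test_solve_assignment_matches_brute_force_with_lex_ties(rng):
    for _ in range(60):
        k = int(rng.integers(2, 7))
        # small integer costs force frequent ties
        G = rng.integers(0, 4, size=(k, k)).astype(float)
        E = solve_assignment(G)
        best_cost, best_perm = brute_force_assignment(G)
        perm = tuple(int(np.argmax(row)) for row in E)
        assert sum(G[i, perm[i]] for i in range(k)) == pytest.approx(best_cost)
        assert perm == best_perm  # lexicographically smallest optimum


def test_matching_maximizes_contingency_trace(rng):
    for _ in range(20):
        k = int(rng.integers(2, 6))
        n = int(rng.integers(k, 30))
        L = rng.integers(0, k, size=n)
        p = rng.integers(0, k, size=n)
        g = contingency(L, p, k)
        E = solve_assignment(cost_matrix(g))
        achieved = np.sum(g * E)
        best = max(sum(g[i, perm[i]] for i in range(k))
                   for perm in permutations(range(k)))
        assert achieved == best


def test_relabel_examples():
    E = np.array([[0.0, 1.0], [1.0, 0.0]])
    P = relabel(np.array([1, 1, 0, 0]), E)
    np.testing.assert_array_equal(np.argmax(P, axis=1), [0, 0, 1, 1])
    p = np.array([2, 0, 1])
    identity = relabel(p, np.eye(3))
    np.testing.assert_array_equal(np.argmax(identity, axis=1), p)
    # applying E then its transpose recovers the original labeling
    E3 = np.eye(3)[[2, 0, 1]]
    once = np.argmax(relabel(p, E3), axis=1)
    np.testing.assert_array_equal(np.argmax(relabel(once, E3.T), axis=1), p)
    with pytest.raises(ValueError, match="permutation"):
        relabel(p, np.ones((3, 3)))


def test_end_to_end_permuted_labels_recovered(rng):
    # if label-head and K-means partitions agree up to a permutation,
    # relabeled hard labels equal the label-head labels exactly
    for _ in range(10):
        k = int(rng.integers(2, 5))
        L = rng.integers(0, k, size=40)
        perm = rng.permutation(k)
        p = perm[L]
        E = solve_assignment(cost_matrix(contingency(L, p, k)))
        np.testing.assert_array_equal(np.argmax(relabel(p, E), axis=1), L)


def test_match_pseudo_labels_deterministic(rng):
    H = rng.normal(size=(30, 4))
    Q = rng.random((30, 3)) + 0.1
    Q /= Q.sum(axis=1, keepdims=True)
    a = match_pseudo_labels(H, Q, seed=5)
    b = match_pseudo_labels(H, Q, seed=5)
    np.testing.assert_array_equal(a.p, b.p)
    np.testing.assert_array_equal(a.E, b.E)
    np.testing.assert_array_equal(a.P_hat, b.P_hat)
    assert a.g.sum() == 30
    assert np.all(a.P_hat.sum(axis=1) == 1)
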