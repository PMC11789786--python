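"""Loss terms: closed forms, brute-force oracles and invariances."""

import numpy as np
import pytest

from omiclust import (cosine_sim, feature_contrastive_loss,
                      label_contrastive_loss, pseudo_label_ce,
                      reconstruction_loss, total_loss)
from omiclust.losses import LossBreakdown


# -- independent brute-force oracles ---------------------------------------

def _cos(u, v):
    return u @ v / (np.linalg.norm(u) * np.linalg.norm(v))


def brute_feature_contrast(Hs, tau):
    """Literal double-loop enumeration of the NT-Xent sums over samples."""
    M, N = len(Hs), Hs[0].shape[0]
    total = 0.0
    for m in range(M):
        for n in range(M):
            if n == m:
                continue
            acc = 0.0
            for i in range(N):
                num = np.exp(_cos(Hs[m][i], Hs[n][i]) / tau)
                den = 0.0
                for j in range(N):
                    for v in (m, n):
                        if v == m and j == i:
                            continue  # self pair excluded
                        den += np.exp(_cos(Hs[m][i], Hs[v][j]) / tau)
                acc -= np.log(num / den)
            total += acc / N
    return total / 2


def brute_label_contrast(Qs, tau):
    """Column-pair enumeration for the cluster-assignment contrast."""
    M, K = len(Qs), Qs[0].shape[1]
    total = 0.0
    for m in range(M):
        for n in range(M):
            if n == m:
                continue
            acc = 0.0
            for j in range(K):
                num = np.exp(_cos(Qs[m][:, j], Qs[n][:, j]) / tau)
                den = 0.0
                for k in range(K):
                    for v in (m, n):
                        if v == m and k == j:
                            continue
                        den += np.exp(_cos(Qs[m][:, j], Qs[v][:, k]) / tau)
                acc -= np.log(num / den)
            total += acc / K
    return total / 2


def random_Q(rng, n, k):
    Q = rng.random((n, k)) + 0.05
    return Q / Q.sum(axis=1, keepdims=True)


# -- reconstruction ---------------------------------------------------------

def test_reconstruction_perfect_is_zero(rng):
    X = [rng.normal(size=(3, 2))]
    A = [np.ones((3, 3)) - np.eye(3)]
    assert reconstruction_loss(X, X, A, A) == (0.0, 0.0, 0.0)


def test_reconstruction_single_entry_and_additivity():
    lf, lg, lz = reconstruction_loss([np.array([[1.0, 0.0]])],
                                     [np.array([[0.0, 0.0]])],
                                     [np.zeros((1, 1))], [np.zeros((1, 1))])
    assert (lf, lg, lz) == (1.0, 0.0, 1.0)
    X = [np.array([[1.0, 1.0]]), np.array([[1.0, 1.0]])]
    Xh = [np.array([[0.0, 0.0]]), np.array([[0.0, 0.0]])]
    A = [np.array([[3.0]]), np.array([[0.0]])]
    Ah = [np.array([[0.0]]), np.array([[-np.sqrt(3.0)]])]
    lf, lg, lz = reconstruction_loss(X, Xh, A, Ah)
    np.testing.assert_allclose((lf, lg, lz), (4.0, 12.0, 16.0))


# -- cosine ------------------------------------------------------------------

def test_cosine_examples():
    assert cosine_sim([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)
    assert cosine_sim([1.0, 0.0], [0.0, 1.0]) == 0.0
    assert cosine_sim([1.0, 1.0], [1.0, 0.0]) == pytest.approx(1 / np.sqrt(2))
    with pytest.raises(ValueError, match="degenerate"):
        cosine_sim([0.0, 0.0], [1.0, 0.0])


# -- feature contrast --------------------------------------------------------

def test_feature_contrast_single_sample_is_zero(rng):
    H = [rng.normal(size=(1, 3)), rng.normal(size=(1, 3))]
    assert feature_contrastive_loss(H, 0.5) == pytest.approx(0.0, abs=1e-12)


def test_feature_contrast_identical_rows_closed_form():
    H = np.tile([0.3, -1.2, 0.5], (2, 1))
    for tau in (0.2, 0.5, 1.0):
        assert feature_contrastive_loss([H, H], tau) == pytest.approx(np.log(3))


def test_feature_contrast_matches_brute_force(rng):
    for _ in range(20):
        m = rng.integers(2, 4)
        n = rng.integers(2, 7)
        Hs = [rng.normal(size=(n, 4)) for _ in range(m)]
        tau = float(rng.uniform(0.2, 2.0))
        assert feature_contrastive_loss(Hs, tau) == pytest.approx(
            brute_feature_contrast(Hs, tau), abs=1e-9)


def test_feature_contrast_terms_nonnegative_and_scale_invariant(rng):
    Hs = [rng.normal(size=(5, 3)) for _ in range(2)]
    base = feature_contrastive_loss(Hs, 0.5)
    assert base >= 0
    Hs[0][2] *= 7.3  # positive row rescale leaves cosines unchanged
    assert feature_contrastive_loss(Hs, 0.5) == pytest.approx(base, abs=1e-9)


def test_feature_contrast_exchangeable_in_view_order(rng):
    Hs = [rng.normal(size=(4, 3)) for _ in range(3)]
    assert feature_contrastive_loss(Hs, 0.5) == pytest.approx(
        feature_contrastive_loss(Hs[::-1], 0.5), abs=1e-9)


def test_feature_contrast_requires_two_views(rng):
    with pytest.raises(ValueError, match="2 omics"):
        feature_contrastive_loss([rng.normal(size=(3, 2))], 0.5)


# -- label contrast ----------------------------------------------------------

def test_label_contrast_uniform_regularizer():
    Q = np.full((4, 3), 1 / 3)
    _, reg, _ = label_contrastive_loss([Q, Q], 1.0)
    assert reg == pytest.approx(-2 * np.log(3))


def test_label_contrast_onehot_view_contributes_zero_reg():
    onehot = np.zeros((4, 2))
    onehot[:, 0] = 1.0
    soft = np.full((4, 2), 0.5)
    _, reg, _ = label_contrastive_loss([onehot + 1e-13, soft], 1.0)
    # the concentrated view's s = e_1 contributes ~0; only the uniform view counts
    assert reg == pytest.approx(-np.log(2), abs=1e-6)


def test_label_contrast_matches_brute_force(rng):
    for _ in range(20):
        n = rng.integers(2, 7)
        k = rng.integers(2, 4)
        Qs = [random_Q(rng, n, k) for _ in range(2)]
        tau = float(rng.uniform(0.5, 2.0))
        contrast, reg, total = label_contrastive_loss(Qs, tau)
        assert contrast == pytest.approx(brute_label_contrast(Qs, tau), abs=1e-9)
        s_terms = sum((Q.mean(axis=0) * np.log(Q.mean(axis=0))).sum() for Q in Qs)
        assert reg == pytest.approx(s_terms, abs=1e-9)
        assert total == pytest.approx(contrast + reg, abs=1e-12)


def test_label_regularizer_bounds(rng):
    for _ in range(30):
        m = int(rng.integers(2, 4))
        k = int(rng.integers(2, 5))
        n = int(rng.integers(2, 8))
        Qs = [random_Q(rng, n, k) for _ in range(m)]
        _, reg, _ = label_contrastive_loss(Qs, 1.0)
        assert -m * np.log(k) - 1e-9 <= reg <= 0


def test_label_contrast_rejects_bad_Q(rng):
    Q = random_Q(rng, 4, 3)
    with pytest.raises(ValueError, match="sum to 1"):
        label_contrastive_loss([Q, Q * 2], 1.0)


# -- pseudo-label CE and total ----------------------------------------------

def test_pseudo_label_ce_examples():
    P = np.eye(2)
    assert pseudo_label_ce([P], [P + 1e-15]) == pytest.approx(0.0, abs=1e-10)
    P1 = np.array([[1.0, 0.0, 0.0, 0.0]])
    Q1 = np.full((1, 4), 0.25)
    assert pseudo_label_ce([P1], [Q1]) == pytest.approx(np.log(4))
    P2 = np.array([[1.0, 0.0], [0.0, 1.0]])
    Q2 = np.array([[0.8, 0.2], [0.3, 0.7]])
    assert pseudo_label_ce([P2], [Q2]) == pytest.approx(
        -(np.log(0.8) + np.log(0.7)))


def test_pseudo_label_ce_rejects_soft_targets():
    with pytest.raises(ValueError, match="one-hot"):
        pseudo_label_ce([np.array([[0.5, 0.5]])], [np.array([[0.5, 0.5]])])


def test_total_loss_combinations():
    bd = LossBreakdown(L_Z=1.0, L_H=2.0, L_C=3.0, L_Q=4.0)
    assert total_loss(bd, 0.5, 2.0) == pytest.approx(11.5)
    assert total_loss(bd, 1.0, 1.0) == pytest.approx(1 + 5 + 4)
    assert total_loss(bd, 0.0, 0.0) == pytest.approx(1.0)
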