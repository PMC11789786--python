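"""Clustering-quality and survival-separation metrics.

Against known labels (synthetic cohorts) the package reports ARI and NMI;
against survival tables it reports the G-group log-rank test, the standard
check that computed subtypes separate survival curves. Clinical-parameter
enrichment and Cox modeling require real clinical tables and are deliberately
not part of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import (adjusted_rand_score, normalized_mutual_info_score,
                             silhouette_score)

__all__ = ["EvalReport", "ari", "nmi", "logrank_test", "evaluate_clustering"]


@dataclass
class EvalReport:
    """Summary of one clustering evaluation."""

    ari: float | None = None
    nmi: float | None = None
    silhouette: float | None = None
    logrank_stat: float | None = None
    logrank_p: float | None = None
    cluster_sizes: tuple = ()

    def to_dict(self) -> dict:
        return {"ari": self.ari, "nmi": self.nmi, "silhouette": self.silhouette,
                "logrank_stat": self.logrank_stat, "logrank_p": self.logrank_p,
                "cluster_sizes": list(self.cluster_sizes)}


def _check_lengths(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return a, b


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index; 1 iff the partitions agree up to relabeling."""
    a, b = _check_lengths(labels_a, labels_b)
    return float(adjusted_rand_score(a, b))


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information (arithmetic-mean normalization)."""
    a, b = _check_lengths(labels_a, labels_b)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def logrank_test(time, event, groups):
    """G-group log-rank chi-square test with G - 1 degrees of freedom.

    Returns ``(statistic, p_value)``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    groups = np.asarray(groups)
    if not (len(time) == len(event) == len(groups)):
        raise ValueError("time, event and groups must have equal length")
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), float(res.p_value)


def evaluate_clustering(y_pred, labels_true=None, features=None,
                        survival=None) -> EvalReport:
    """Assemble an :class:`EvalReport` for a computed partition.

    Parameters
    ----------
    y_pred : array-like
        Computed subtype labels.
    labels_true : array-like, optional
        Ground-truth labels (ARI / NMI are reported when given).
    features : array-like, optional
        Sample-by-feature matrix for the silhouette score (needs >= 2
        distinct predicted clusters).
    survival : DataFrame, optional
        Columns ``time`` and ``event``; log-rank across predicted subtypes.
    """
    y_pred = np.asarray(y_pred)
    _, sizes = np.unique(y_pred, return_counts=True)
    report = EvalReport(cluster_sizes=tuple(int(c) for c in sizes))
    if labels_true is not None:
        report.ari = ari(labels_true, y_pred)
        report.nmi = nmi(labels_true, y_pred)
    if features is not None and len(sizes) >= 2:
        report.silhouette = float(silhouette_score(np.asarray(features, dtype=float),
                                                   y_pred))
    if survival is not None and len(sizes) >= 2:
        stat, p = logrank_test(survival["time"], survival["event"], y_pred)
        report.logrank_stat = stat
        report.logrank_p = p
    return report
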