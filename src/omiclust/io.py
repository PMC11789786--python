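"""Reading and writing omics matrices, subtypes and run artifacts.

Omics matrices travel as delimited text: a header row of feature names and a
first column of sample IDs. Multiple files are aligned on the intersection of
their sample IDs, reordered to the first file's order — real multi-omics
cohorts rarely overlap perfectly, so intersection (with logged counts) beats
hard failure. Delimiters are sniffed from the extension: ``.csv`` is comma,
everything else tab.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["OmicsBundle", "load_omics", "save_omics", "save_subtypes",
           "load_subtypes"]


@dataclass
class OmicsBundle:
    """M aligned sample-by-feature matrices plus their labeling metadata."""

    omics: list
    sample_ids: list
    feature_names: list = field(default_factory=list)
    omics_names: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _read_matrix(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"omics file not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID {dup!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(f"non-numeric cell at sample {df.index[r]!r}, "
                         f"feature {df.columns[c]!r} in {path}")
    if numeric.isna().any().any():
        raise ValueError(f"missing values in {path}")
    return numeric


def _scale(X: np.ndarray, how: str) -> np.ndarray:
    if how == "none":
        return X
    if how == "minmax":
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        return 2.0 * (X - lo) / span - 1.0
    if how == "zscore":
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return (X - X.mean(axis=0)) / sd
    raise ValueError(f"unknown scaling mode: {how!r}")


def load_omics(paths, scale: str = "minmax") -> OmicsBundle:
    """Load and align per-view matrices from delimited-text files.

    Samples are intersected across files and reordered to the first file's
    order; constant features are dropped with a warning; per-feature scaling
    (default: min-max to [-1, 1], the tanh decoder's range) is applied after
    alignment.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("at least one omics file is required")
    frames = [_read_matrix(p) for p in paths]
    ids = list(frames[0].index)
    common = set(ids)
    for df in frames[1:]:
        common &= set(df.index)
    if not common:
        raise ValueError("empty sample intersection across omics files")
    ids = [s for s in ids if s in common]
    logger.info("aligned %d samples across %d omics files", len(ids), len(paths))

    omics, feature_names, omics_names = [], [], []
    for path, df in zip(paths, frames):
        df = df.loc[ids]
        keep = df.nunique(axis=0) > 1
        if not keep.all():
            logger.warning("dropping %d constant feature(s) from %s",
                           int((~keep).sum()), path)
            df = df.loc[:, keep]
        omics.append(_scale(df.to_numpy(dtype=float), scale))
        feature_names.append(list(df.columns))
        omics_names.append(path.stem)
    return OmicsBundle(omics=omics, sample_ids=ids,
                       feature_names=feature_names, omics_names=omics_names)


def save_omics(X, sample_ids, feature_names, path) -> None:
    """Write one view as delimited text (sample_id column + features)."""
    df = pd.DataFrame(np.asarray(X), index=list(sample_ids),
                      columns=list(feature_names))
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path))


def save_subtypes(y, sample_ids, path) -> None:
    """Two-column TSV (sample_id, subtype); subtypes are written 1-based."""
    y = np.asarray(y)
    if len(y) != len(sample_ids):
        raise ValueError("y and sample_ids must have equal length")
    pd.DataFrame({"sample_id": list(sample_ids),
                  "subtype": y + 1}).to_csv(path, sep="\t", index=False)


def load_subtypes(path):
    """Read a subtypes TSV back to ``(sample_ids, y)`` with 0-based labels."""
    df = pd.read_csv(path, sep="\t")
    return list(df["sample_id"].astype(str)), df["subtype"].to_numpy() - 1
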