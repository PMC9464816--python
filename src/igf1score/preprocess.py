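"""Count filtering, median-of-ratios size factors, normalisation, log transform.

All functions take genes × samples pandas DataFrames (genes in rows),
the orientation used by the on-disk count formats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

__all__ = [
    "FilterRule",
    "LogMatrix",
    "validate_counts",
    "filter_genes",
    "estimate_size_factors",
    "normalize_counts",
    "log_transform",
]


@dataclass(frozen=True)
class FilterRule:
    """Low-count gene filter: keep genes with more than ``min_count``
    counts (strict) in at least ``min_fraction`` of samples (the sample
    quota is ``ceil(min_fraction * n_samples)``)."""

    min_count: int = 5
    min_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValueError(f"min_count must be >= 0, got {self.min_count!r}")
        if not 0.0 < self.min_fraction <= 1.0:
            raise ValueError(f"min_fraction must lie in (0, 1], got {self.min_fraction!r}")


@dataclass(frozen=True)
class LogMatrix:
    """Log-scale expression with its provenance (base and pseudocount)."""

    values: pd.DataFrame
    base: float
    pseudocount: float


def validate_counts(counts: pd.DataFrame, *, name: str = "counts") -> pd.DataFrame:
    """Validate a genes × samples count matrix; returns it unchanged."""
    if counts.index.has_duplicates:
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"{name}: duplicate gene identifiers {dupes[:5]}")
    if counts.columns.has_duplicates:
        dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"{name}: duplicate sample identifiers {dupes[:5]}")
    if counts.shape[1] < 2:
        raise ValueError(f"{name}: need at least 2 samples, got {counts.shape[1]}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{name}: non-numeric entries")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        bad = np.argwhere((arr < 0) | ~np.isclose(arr, np.round(arr)))
        g, j = bad[0]
        raise ValueError(
            f"{name}: entries must be non-negative integers; first offender at "
            f"gene {counts.index[g]!r}, sample {counts.columns[j]!r} (value {arr[g, j]!r})"
        )
    return counts


def filter_genes(counts: pd.DataFrame, rule: FilterRule = FilterRule()) -> pd.DataFrame:
    """Drop genes failing the low-count rule; sample set and gene order kept."""
    validate_counts(counts)
    quota = ceil(rule.min_fraction * counts.shape[1])
    keep = (counts.to_numpy() > rule.min_count).sum(axis=1) >= quota
    out = counts.loc[keep]
    if out.shape[0] == 0:
        raise ValueError(
            f"no gene passes the filter (> {rule.min_count} counts in >= "
            f"{quota} of {counts.shape[1]} samples); relax min_count or min_fraction"
        )
    return out


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, ``s_j`` is the median over reference genes of
    ``K_gj / exp(mean_j log K_gj)``; the reference set is the genes with
    strictly positive counts in every sample. The geometric mean is
    computed on the log scale for stability.
    """
    validate_counts(counts)
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has strictly positive counts in every sample; "
            "filter low-count genes first or supply a denser matrix"
        )
    logk = np.log(arr[positive])
    log_geomean = logk.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logk - log_geomean, axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if not counts.columns.equals(size_factors.index):
        raise ValueError("size factor index does not match the sample columns")
    s = size_factors.to_numpy(dtype=float)
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("size factors must be finite and strictly positive")
    return counts / s


def log_transform(normalized: pd.DataFrame, pseudocount: float = 1.0) -> LogMatrix:
    """log2(x + pseudocount), recording base and pseudocount."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount!r}")
    arr = normalized.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("log_transform expects non-negative input")
    values = pd.DataFrame(
        np.log2(arr + pseudocount), index=normalized.index, columns=normalized.columns
    )
    return LogMatrix(values=values, base=2.0, pseudocount=float(pseudocount))
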