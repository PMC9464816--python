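"""Single-sample signature scoring: the signed mean z-score (IGF1-score).

Given a cohort log-expression matrix and a signed gene set, each gene is
z-scored across all cohort samples jointly (sample SD, n-1 denominator),
down-regulated genes are sign-flipped so that a positive score always
indicates more pathway signalling, and the per-sample score is the
unweighted mean of the oriented z-scores over the signature genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import SignedGeneSet
from .preprocess import (
    FilterRule,
    LogMatrix,
    estimate_size_factors,
    filter_genes,
    log_transform,
    normalize_counts,
)

__all__ = ["ZScoreMatrix", "ScoreVector", "zscore_genes", "project_signature", "compute_igf1_score"]


@dataclass(frozen=True)
class ZScoreMatrix:
    """Row-standardised expression with the statistics used."""

    values: pd.DataFrame          # only rows with positive variance
    gene_means: pd.Series
    gene_sds: pd.Series
    ddof: int
    zero_variance_genes: list


@dataclass(frozen=True)
class ScoreVector:
    """Per-sample signature scores plus bookkeeping on the genes used."""

    scores: pd.Series
    n_genes_used: int
    dropped_genes: list           # (gene, reason) pairs
    provenance: dict = field(default_factory=dict)


def zscore_genes(logm: LogMatrix | pd.DataFrame, ddof: int = 1) -> ZScoreMatrix:
    """Standardise each gene row across samples: (x - mean) / SD.

    Zero-variance rows cannot be standardised; they are excluded from the
    result with a warning naming the genes.
    """
    values = logm.values if isinstance(logm, LogMatrix) else logm
    if values.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    arr = values.to_numpy(dtype=float)
    means = arr.mean(axis=1)
    sds = arr.std(axis=1, ddof=ddof)
    zero_var = sds == 0
    if zero_var.any():
        names = values.index[zero_var].tolist()
        warnings.warn(
            f"{len(names)} constant gene(s) excluded from z-scoring: {names[:10]}",
            UserWarning,
            stacklevel=2,
        )
    keep = ~zero_var
    z = (arr[keep] - means[keep, None]) / sds[keep, None]
    return ZScoreMatrix(
        values=pd.DataFrame(z, index=values.index[keep], columns=values.columns),
        gene_means=pd.Series(means, index=values.index, name="mean"),
        gene_sds=pd.Series(sds, index=values.index, name="sd"),
        ddof=ddof,
        zero_variance_genes=values.index[zero_var].tolist(),
    )


def project_signature(
    z: ZScoreMatrix,
    signature: SignedGeneSet,
    min_overlap: float = 0.5,
) -> ScoreVector:
    """Per-sample mean of sign-oriented z-scores over the signature genes.

    Signature genes missing from the matrix (filtered out or constant)
    are dropped with a reason; if fewer than ``min_overlap`` of the
    signature remains usable, scoring refuses rather than silently
    reporting a score built from a sliver of the gene set.
    """
    present = set(z.values.index)
    zero_var = set(z.zero_variance_genes)
    usable, dropped = [], []
    for g in signature.genes:
        if g in present:
            usable.append(g)
        elif g in zero_var:
            dropped.append((g, "zero variance"))
        else:
            dropped.append((g, "missing from matrix"))
    needed = min_overlap * len(signature)
    if len(usable) < needed or len(usable) == 0:
        raise ValueError(
            f"signature overlap too small: {len(usable)} of {len(signature)} genes usable, "
            f"need at least {needed:.1f} (min_overlap={min_overlap})"
        )
    w = np.array([signature.orientations[g] for g in usable], dtype=float)
    zmat = z.values.loc[usable].to_numpy()
    scores = (w[:, None] * zmat).mean(axis=0)
    return ScoreVector(
        scores=pd.Series(scores, index=z.values.columns, name="igf1_score"),
        n_genes_used=len(usable),
        dropped_genes=dropped,
        provenance={"min_overlap": min_overlap, "signature_size": len(signature)},
    )


def compute_igf1_score(
    counts: pd.DataFrame,
    signature: SignedGeneSet,
    rule: FilterRule = FilterRule(),
    pseudocount: float = 1.0,
    min_overlap: float = 0.5,
) -> ScoreVector:
    """Full cohort scoring pipeline from raw counts.

    Composition of filter -> size factors -> normalise -> log2 ->
    z-score -> signed projection, with stage provenance recorded.
    """
    filtered = filter_genes(counts, rule)
    size_factors = estimate_size_factors(filtered)
    normalized = normalize_counts(filtered, size_factors)
    logm = log_transform(normalized, pseudocount)
    z = zscore_genes(logm)
    sv = project_signature(z, signature, min_overlap)
    sv.provenance.update(
        {
            "filter_rule": {"min_count": rule.min_count, "min_fraction": rule.min_fraction},
            "pseudocount": pseudocount,
            "log_base": logm.base,
            "n_genes_after_filter": int(filtered.shape[0]),
            "size_factors": size_factors.to_dict(),
        }
    )
    return sv
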