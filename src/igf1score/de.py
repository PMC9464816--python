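"""Negative-binomial Wald differential expression and the signed signature.

A deliberately simple two-group NB Wald test: per-gene dispersions by
method of moments on normalised counts, group-mean log2 fold changes,
delta-method standard errors under the NB variance function
``var = mu + phi * mu**2``, normal two-sided p-values and
Benjamini-Hochberg adjustment. There is no dispersion shrinkage toward
a trend, no outlier replacement and no independent filtering; the DE
stage is pluggable, so an externally computed table with the same
columns can be substituted when full DESeq2-style machinery is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DISPERSION_FLOOR",
    "DE_COLUMNS",
    "SignedGeneSet",
    "estimate_dispersions",
    "wald_de",
    "bh_adjust",
    "build_signature",
]

DISPERSION_FLOOR = 1e-8
DE_COLUMNS = ["gene", "log2fc", "se", "stat", "pvalue", "padj"]


@dataclass(frozen=True)
class SignedGeneSet:
    """Mapping gene -> orientation (+1 up-regulated, -1 down-regulated
    with stimulation), with provenance of how it was built."""

    orientations: dict
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.orientations) == 0:
            raise ValueError("empty signature: no gene passed the threshold, scoring is undefined")
        bad = {g: w for g, w in self.orientations.items() if w not in (1, -1)}
        if bad:
            raise ValueError(f"orientations must be +1 or -1, got {bad}")

    @property
    def genes(self) -> list:
        return list(self.orientations)

    @property
    def up(self) -> list:
        return [g for g, w in self.orientations.items() if w == 1]

    @property
    def down(self) -> list:
        return [g for g, w in self.orientations.items() if w == -1]

    def __len__(self) -> int:
        return len(self.orientations)


def _two_groups(groups: pd.Series) -> tuple[np.ndarray, np.ndarray, list]:
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {list(levels)}")
    masks = [(groups == lv).to_numpy() for lv in levels]
    for lv, m in zip(levels, masks):
        if m.sum() < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 samples")
    return masks[0], masks[1], list(levels)


def estimate_dispersions(
    counts: pd.DataFrame,
    groups: pd.Series,
    size_factors: pd.Series,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments.

    Within-group variances of the normalised counts are pooled across
    the two groups and compared with the pooled mean:
    ``phi = max(floor, (var - mean) / mean**2)``.
    """
    m0, m1, _ = _two_groups(groups)
    y = (counts / size_factors).to_numpy(dtype=float)
    parts_var, parts_df = [], []
    for m in (m0, m1):
        parts_var.append(y[:, m].var(axis=1, ddof=1) * (m.sum() - 1))
        parts_df.append(m.sum() - 1)
    var_within = sum(parts_var) / sum(parts_df)
    mean = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (var_within - mean) / mean**2
    phi = np.where(np.isfinite(phi), phi, 0.0)
    phi = np.maximum(phi, floor)
    return pd.Series(phi, index=counts.index, name="dispersion")


def wald_de(
    counts: pd.DataFrame,
    groups: pd.Series,
    size_factors: pd.Series,
    dispersions: pd.Series | None = None,
    pseudocount: float = 1.0,
    *,
    treatment: str | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test on a genes × samples count matrix.

    Log2 fold change compares the ``treatment`` group mean against the
    other group (default: the second group level in order of appearance
    is the treatment). Returns a DataFrame with columns
    ``gene, log2fc, se, stat, pvalue, padj`` indexed by gene.

    P-values refer the Wald statistic to a t distribution with the
    residual degrees of freedom (n1 + n2 - 2) rather than the normal:
    the moment dispersion estimates carry sampling noise that a plug-in
    normal ignores, which inflates the type-I error at the small group
    sizes this test targets. (Shrinkage-based DE tools restore
    calibration by pooling dispersions across genes instead; this
    simplified test does not shrink.) The two references coincide as
    group sizes grow.
    """
    m_first, m_second, levels = _two_groups(groups)
    if treatment is None:
        treatment = levels[1]
    if treatment not in levels:
        raise ValueError(f"treatment {treatment!r} not among group levels {levels}")
    m1 = m_second if treatment == levels[1] else m_first
    m0 = ~m1
    if dispersions is None:
        dispersions = estimate_dispersions(counts, groups, size_factors)

    s = size_factors.to_numpy(dtype=float)
    y = counts.to_numpy(dtype=float) / s
    phi = dispersions.to_numpy(dtype=float)
    ln2 = np.log(2.0)

    def group_stats(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mbar = y[:, mask].mean(axis=1)
        # Var(K_gj/s_j) = mu/s_j^2 + phi * (mu/s_j)^2 with mu = s_j * mbar
        inv_s = 1.0 / s[mask]
        var_mean = (mbar[:, None] * inv_s[None, :] + phi[:, None] * mbar[:, None] ** 2).sum(axis=1)
        return mbar, var_mean / mask.sum() ** 2

    mbar1, v1 = group_stats(m1)
    mbar0, v0 = group_stats(m0)

    lfc = np.log2((mbar1 + pseudocount) / (mbar0 + pseudocount))
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(
            v1 / ((mbar1 + pseudocount) * ln2) ** 2 + v0 / ((mbar0 + pseudocount) * ln2) ** 2
        )
        stat = lfc / se
    from scipy.stats import t as t_dist

    df_resid = int(m1.sum() + m0.sum() - 2)
    pvalue = 2.0 * t_dist.sf(np.abs(stat), df=df_resid)

    # all-zero genes: no evidence by convention
    allzero = (counts.to_numpy() == 0).all(axis=1)
    degenerate = allzero | (se == 0) | ~np.isfinite(se)
    lfc = np.where(degenerate, 0.0, lfc)
    stat = np.where(degenerate, 0.0, stat)
    pvalue = np.where(degenerate, 1.0, pvalue)
    se = np.where(np.isfinite(se), se, np.nan)

    res = pd.DataFrame(
        {
            "gene": counts.index,
            "log2fc": lfc,
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
        },
        index=counts.index,
    )
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    return res


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_signature(
    de: pd.DataFrame,
    alpha: float = 0.05,
    *,
    source: str = "reference_experiment",
) -> SignedGeneSet:
    """Signed gene set from a DE table: genes with ``padj < alpha``
    oriented by the sign of their log2 fold change (exact zeros excluded)."""
    missing = {"gene", "log2fc", "padj"} - set(de.columns)
    if missing:
        raise ValueError(f"DE table is missing columns {sorted(missing)}")
    hits = de[(de["padj"] < alpha) & (de["log2fc"] != 0)]
    orientations = {
        str(g): (1 if lfc > 0 else -1)
        for g, lfc in zip(hits["gene"], hits["log2fc"])
    }
    return SignedGeneSet(
        orientations=orientations,
        provenance={"alpha": alpha, "source": source, "n_tested": int(len(de))},
    )
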