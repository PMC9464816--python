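"""Cohort stratification and nonparametric group-association statistics.

Implements the clinical-table workflow: split a cohort at the median of
a marker variable, compare continuous variables between strata with the
Mann-Whitney U test, compare binary flags with Fisher's exact test
(odds ratio with a Woolf log-interval), correlate variables with
Spearman's rank coefficient, and compare signature scores between
autoantibody-pattern groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StratifiedCohort",
    "AssociationReport",
    "median_split",
    "mann_whitney",
    "fisher_exact_or",
    "spearman_matrix",
    "summarize_cohort",
    "score_by_group",
]

TIE_POLICY = "at-or-above median -> high"


@dataclass(frozen=True)
class StratifiedCohort:
    """Binary high/low stratification at the median of a marker."""

    threshold: float
    labels: pd.Series            # values in {"high", "low"}
    tie_policy: str = TIE_POLICY

    @property
    def n_high(self) -> int:
        return int((self.labels == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum())


@dataclass(frozen=True)
class AssociationReport:
    """Per-variable group comparison results, serialisable to TSV/JSON."""

    table: pd.DataFrame
    strata: StratifiedCohort
    notes: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "tie_policy": self.strata.tie_policy,
            "threshold": self.strata.threshold,
            "n_high": self.strata.n_high,
            "n_low": self.strata.n_low,
            "variables": self.table.where(pd.notna(self.table), None).to_dict(orient="records"),
            **self.notes,
        }


def median_split(values: pd.Series) -> StratifiedCohort:
    """Split samples at the median: strictly below -> "low", at or above
    -> "high". For odd n with distinct values this yields (n+1)/2 high
    and (n-1)/2 low samples (e.g. 28 vs 27 for n = 55)."""
    v = values.astype(float)
    if len(v) < 2:
        raise ValueError("median split needs at least 2 samples")
    if not np.all(np.isfinite(v.to_numpy())):
        raise ValueError("median split requires finite values")
    if v.nunique() == 1:
        raise ValueError("all marker values identical: median split is degenerate")
    med = float(v.median())
    labels = pd.Series(np.where(v.to_numpy() >= med, "high", "low"), index=v.index, name="stratum")
    return StratifiedCohort(threshold=med, labels=labels)


def mann_whitney(
    x,
    y,
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U test (midranks for ties).

    ``method="auto"`` uses exact enumeration when both samples have
    at most 8 observations and the pooled data are tie-free, otherwise
    the normal approximation with tie and continuity corrections.
    Returns (U for x, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        tie_free = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
        method = "exact" if (x.size <= 8 and y.size <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_or(
    table,
    alternative: str = "two-sided",
    ci_level: float = 0.95,
) -> dict:
    """Fisher's exact test on a 2x2 table with the sample odds ratio.

    OR = (a*d)/(b*c); a zero denominator is reported as ``inf`` and a
    zero numerator as ``0.0``, flagged in the result. The confidence
    interval uses the Woolf log method (undefined when any cell is zero).
    The two-sided p sums hypergeometric probabilities no larger than
    the observed table's.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table entries must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("2x2 table has a zero margin; the test is undefined")
    a, b, c, d = t.ravel()
    degenerate = (b * c == 0) or (a * d == 0)
    if b * c == 0:
        oddsratio = float("inf") if a * d > 0 else float("nan")
    else:
        oddsratio = (a * d) / (b * c)
    _, p = stats.fisher_exact(t, alternative=alternative)
    if degenerate:
        ci = (float("nan"), float("nan"))
    else:
        log_or = np.log(oddsratio)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        zcrit = stats.norm.ppf(0.5 + ci_level / 2)
        ci = (float(np.exp(log_or - zcrit * se)), float(np.exp(log_or + zcrit * se)))
    return {
        "odds_ratio": float(oddsratio),
        "pvalue": float(p),
        "ci": ci,
        "ci_method": "woolf-log",
        "ci_level": ci_level,
        "degenerate_or": bool(degenerate),
    }


def spearman_matrix(variables: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rank correlations with t-approximation p-values.

    Constant variables have undefined correlations; their pairs are
    reported as NaN. The diagonal is exactly 1 (p = 0 by convention).
    """
    if variables.shape[0] < 3:
        raise ValueError("Spearman correlation needs at least 3 observations")
    names = list(variables.columns)
    k = len(names)
    rho = pd.DataFrame(np.eye(k), index=names, columns=names)
    pmat = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    constant = {n for n in names if variables[n].nunique() <= 1}
    for i, j in combinations(range(k), 2):
        ni, nj = names[i], names[j]
        if ni in constant or nj in constant:
            r, p = np.nan, np.nan
        else:
            r, p = stats.spearmanr(variables[ni], variables[nj])
        rho.iloc[i, j] = rho.iloc[j, i] = r
        pmat.iloc[i, j] = pmat.iloc[j, i] = p
    for n in constant:
        rho.loc[n, n] = np.nan
        pmat.loc[n, n] = np.nan
    return rho, pmat


def _percent(count: int, total: int) -> float:
    """Percentage rounded half-up to 1 decimal (clinical-table style)."""
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_cohort(
    meta: pd.DataFrame,
    strata: StratifiedCohort,
    continuous: list | None = None,
    binary: list | None = None,
) -> AssociationReport:
    """Clinical-characteristics table comparing the high and low strata.

    Continuous variables get per-group mean ± SD and a Mann-Whitney p;
    binary flags get per-group counts, percentages and a Fisher exact
    odds ratio and p. Variables are auto-typed from dtypes when not
    listed explicitly.
    """
    if not strata.labels.index.equals(meta.index):
        raise ValueError("stratification labels must cover exactly the metadata samples")
    if continuous is None:
        continuous = [c for c in meta.columns if pd.api.types.is_float_dtype(meta[c])]
    if binary is None:
        binary = [c for c in meta.columns if pd.api.types.is_bool_dtype(meta[c])]
    hi = strata.labels == "high"
    lo = ~hi
    rows = []
    for var in continuous:
        v = meta[var]
        if v.isna().all():
            raise ValueError(f"variable {var!r} has no observed values")
        xhi, xlo = v[hi].dropna(), v[lo].dropna()
        u, p = mann_whitney(xhi, xlo)
        rows.append(
            {
                "variable": var,
                "type": "continuous",
                "test": "mann-whitney",
                "high_summary": f"{xhi.mean():.2f} ± {xhi.std(ddof=1):.2f}",
                "low_summary": f"{xlo.mean():.2f} ± {xlo.std(ddof=1):.2f}",
                "statistic": u,
                "pvalue": p,
                "odds_ratio": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
            }
        )
    for var in binary:
        v = meta[var].astype(bool)
        a = int((v & hi).sum())   # flag+ in high
        b = int((~v & hi).sum())
        c = int((v & lo).sum())   # flag+ in low
        d = int((~v & lo).sum())
        fr = fisher_exact_or(np.array([[a, b], [c, d]]))
        rows.append(
            {
                "variable": var,
                "type": "binary",
                "test": "fisher-exact",
                "high_summary": f"{a} ({_percent(a, int(hi.sum()))}%)",
                "low_summary": f"{c} ({_percent(c, int(lo.sum()))}%)",
                "statistic": np.nan,
                "pvalue": fr["pvalue"],
                "odds_ratio": fr["odds_ratio"],
                "ci_low": fr["ci"][0],
                "ci_high": fr["ci"][1],
            }
        )
    table = pd.DataFrame(rows, columns=[
        "variable", "type", "test", "high_summary", "low_summary",
        "statistic", "pvalue", "odds_ratio", "ci_low", "ci_high",
    ])
    dup = table["variable"].duplicated()
    if dup.any():
        raise ValueError(f"variables listed twice: {table['variable'][dup].tolist()}")
    return AssociationReport(table=table, strata=strata)


def score_by_group(scores: pd.Series, labels: pd.Series) -> dict:
    """Median score per group plus pairwise Mann-Whitney comparisons.

    Groups are ordered by ascending median score; the result notes
    whether the medians are strictly monotone in that order and which
    group is lowest.
    """
    if not scores.index.equals(labels.index):
        raise ValueError("scores and group labels must share one sample index")
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    per_group = {}
    for g in groups:
        vals = scores[labels == g]
        if len(vals) == 0:
            raise ValueError(f"group {g!r} has zero members")
        per_group[g] = vals
    medians = {g: float(v.median()) for g, v in per_group.items()}
    order = sorted(medians, key=medians.get)
    pairwise = {}
    for g1, g2 in combinations(order, 2):
        _, p = mann_whitney(per_group[g1], per_group[g2])
        pairwise[f"{g1} vs {g2}"] = p
    meds_sorted = [medians[g] for g in order]
    return {
        "medians": medians,
        "order": order,
        "lowest": order[0],
        "monotone": all(a < b for a, b in zip(meds_sorted, meds_sorted[1:])),
        "pairwise_p": pairwise,
        "group_sizes": {g: int(len(v)) for g, v in per_group.items()},
    }
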