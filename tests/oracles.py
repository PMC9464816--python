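"""Independent brute-force oracles for the statistical primitives.

Each function here re-derives a quantity straight from its textbook
definition, without touching the package implementation or scipy's
corresponding routine, so tests can compare the two routes.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, lgamma

import numpy as np

__all__ = [
    "bh_brute_force",
    "fisher_two_sided_enumeration",
    "mann_whitney_exact_enumeration",
    "spearman_rank_then_pearson",
]


def bh_brute_force(pvalues) -> np.ndarray:
    """Benjamini-Hochberg from the definition:
    q_(i) = min_{k >= i} min(1, m * p_(k) / k) in sorted order."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(1.0, m * p[order[k]] / (k + 1)) for k in range(i, m))
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _hypergeom_pmf_vector(r1: int, r2: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """PMF of cell a over its support for fixed margins (r1, r2) x (c1, .)."""
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = np.array(
        [
            lgamma(r1 + 1) - lgamma(a + 1) - lgamma(r1 - a + 1)
            + lgamma(r2 + 1) - lgamma(c1 - a + 1) - lgamma(r2 - (c1 - a) + 1)
            - (lgamma(n + 1) - lgamma(c1 + 1) - lgamma(n - c1 + 1))
            for a in support
        ]
    )
    return support, np.exp(logp)


def fisher_two_sided_enumeration(table) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the observed margins that are no more probable than the
    observed one."""
    a, b, c, d = np.asarray(table).ravel()
    support, pmf = _hypergeom_pmf_vector(a + b, c + d, a + c)
    p_obs = pmf[support == a][0]
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


_U_DIST_CACHE: dict = {}


def mann_whitney_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of U (counts over 0..n1*n2) by enumerating
    all rank assignments of the pooled tie-free sample."""
    key = (n1, n2)
    if key not in _U_DIST_CACHE:
        n = n1 + n2
        base = n1 * (n1 + 1) // 2
        counts = np.zeros(n1 * n2 + 1, dtype=np.int64)
        for ranks in combinations(range(1, n + 1), n1):
            counts[sum(ranks) - base] += 1
        _U_DIST_CACHE[key] = counts
    return _U_DIST_CACHE[key]


def mann_whitney_exact_enumeration(n1: int, n2: int, u: float) -> float:
    """Exact two-sided Mann-Whitney p for tie-free samples:
    P(|U' - n1*n2/2| >= |u - n1*n2/2|) under full enumeration."""
    counts = mann_whitney_u_distribution(n1, n2)
    mu = n1 * n2 / 2.0
    dev = abs(u - mu)
    support = np.arange(counts.size)
    hits = counts[np.abs(support - mu) >= dev - 1e-9].sum()
    return float(hits / counts.sum())


def spearman_rank_then_pearson(x, y) -> float:
    """Spearman rho as the Pearson correlation of midranks."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(v.size)
        i = 0
        sv = v[order]
        while i < v.size:
            j = i
            while j + 1 < v.size and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
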