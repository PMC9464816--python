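"""Scikit-learn-style estimators over the functional kernels.

These classes follow the sklearn convention (samples in rows, genes in
columns; ``fit``/``transform``; fitted attributes with a trailing
underscore; ``get_params``/``set_params`` via :class:`BaseEstimator`)
and compose with :class:`sklearn.pipeline.Pipeline`. They delegate the
numerics to the genes-in-rows kernel functions used by the file-level
pipeline, so both surfaces compute identical numbers.

Inputs are pandas DataFrames so that gene identifiers travel with the
data; plain arrays are accepted where gene names are not needed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import de as _de
from . import preprocess as _pp
from . import score as _score
from .de import SignedGeneSet

__all__ = [
    "LowCountGeneFilter",
    "MedianOfRatiosNormalizer",
    "Log2Transformer",
    "GeneZScorer",
    "IGF1SignatureScorer",
]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"g{i}" for i in range(X.shape[1])])


class LowCountGeneFilter(BaseEstimator, TransformerMixin):
    """Drop genes without more than ``min_count`` counts in at least
    ``ceil(min_fraction * n_samples)`` of the fitted samples."""

    def __init__(self, min_count: int = 5, min_fraction: float = 1.0 / 3.0):
        self.min_count = min_count
        self.min_fraction = min_fraction

    def fit(self, X, y=None):
        Xf = _as_frame(X)
        rule = _pp.FilterRule(self.min_count, self.min_fraction)
        kept = _pp.filter_genes(Xf.T, rule).index
        self.feature_names_in_ = np.asarray(Xf.columns)
        self.support_ = Xf.columns.isin(kept)
        self.n_features_in_ = Xf.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        Xf = _as_frame(X)
        return Xf.loc[:, self.support_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "support_")
        return self.feature_names_in_[self.support_]


class MedianOfRatiosNormalizer(BaseEstimator, TransformerMixin):
    """Median-of-ratios depth normalisation.

    ``fit`` learns the per-gene log geometric mean over the fitted
    samples (the pseudo-reference), restricted to genes positive in all
    of them; ``transform`` computes each sample's size factor as the
    median count-to-reference ratio and divides the counts by it. On the
    data it was fitted on this reproduces the classical estimator.
    """

    def fit(self, X, y=None):
        Xf = _as_frame(X)
        arr = Xf.to_numpy(dtype=float)
        positive = (arr > 0).all(axis=0)
        if not positive.any():
            raise ValueError("no gene has strictly positive counts in every fitted sample")
        self.reference_mask_ = positive
        self.log_reference_ = np.log(arr[:, positive]).mean(axis=0)
        self.n_features_in_ = Xf.shape[1]
        self.feature_names_in_ = np.asarray(Xf.columns)
        return self

    def size_factors(self, X) -> pd.Series:
        check_is_fitted(self, "log_reference_")
        Xf = _as_frame(X)
        arr = Xf.to_numpy(dtype=float)[:, self.reference_mask_]
        with np.errstate(divide="ignore"):
            logratio = np.log(arr) - self.log_reference_[None, :]
        if not np.all(np.isfinite(logratio)):
            raise ValueError("a sample has zero counts on a reference gene; refit or refilter")
        return pd.Series(np.exp(np.median(logratio, axis=1)), index=Xf.index, name="size_factor")

    def transform(self, X):
        Xf = _as_frame(X)
        s = self.size_factors(Xf)
        return Xf.div(s, axis=0)


class Log2Transformer(BaseEstimator, TransformerMixin):
    """Stateless log2(x + pseudocount)."""

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        self.n_features_in_ = _as_frame(X).shape[1]
        return self

    def transform(self, X):
        Xf = _as_frame(X)
        return _pp.log_transform(Xf.T, self.pseudocount).values.T


class GeneZScorer(BaseEstimator, TransformerMixin):
    """Per-gene standardisation across samples (sample SD, ddof=1).

    Zero-variance genes in the fitted data are dropped from the output,
    mirroring the scoring pipeline's behaviour.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        Xf = _as_frame(X)
        z = _score.zscore_genes(Xf.T, ddof=self.ddof)
        self.mean_ = z.gene_means
        self.scale_ = z.gene_sds
        self.keep_ = ~Xf.columns.isin(z.zero_variance_genes)
        self.n_features_in_ = Xf.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        Xf = _as_frame(X).loc[:, self.keep_]
        return (Xf - self.mean_[self.keep_]) / self.scale_[self.keep_]


class IGF1SignatureScorer(BaseEstimator, TransformerMixin):
    """Learn a signed stimulation signature, score cohorts with it.

    ``fit(X, y)`` takes the reference experiment (samples × genes counts,
    ``y`` the two-level stimulation labels) and runs low-count filtering,
    median-of-ratios size factors, moment dispersion estimates, the NB
    Wald test with BH adjustment, and keeps the genes with
    ``padj < alpha`` signed by fold-change direction.

    ``transform(X)`` takes a cohort count matrix and returns the
    per-sample signature score: the cohort is filtered, normalised,
    log2-transformed and gene-z-scored *within itself* (single-sample
    scores are cohort-relative by construction), then averaged over the
    sign-oriented signature genes. Output shape is (n_samples, 1);
    ``score_samples`` returns the same numbers as a named Series.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        min_count: int = 5,
        min_fraction: float = 1.0 / 3.0,
        pseudocount: float = 1.0,
        min_overlap: float = 0.5,
        treatment: str | None = None,
    ):
        self.alpha = alpha
        self.min_count = min_count
        self.min_fraction = min_fraction
        self.pseudocount = pseudocount
        self.min_overlap = min_overlap
        self.treatment = treatment

    def fit(self, X, y):
        Xf = _as_frame(X)
        counts = Xf.T
        groups = pd.Series(np.asarray(y), index=counts.columns, name="group")
        rule = _pp.FilterRule(self.min_count, self.min_fraction)
        filtered = _pp.filter_genes(counts, rule)
        s = _pp.estimate_size_factors(filtered)
        disp = _de.estimate_dispersions(filtered, groups, s)
        res = _de.wald_de(
            filtered, groups, s, disp, self.pseudocount, treatment=self.treatment
        )
        self.size_factors_ = s
        self.dispersions_ = disp
        self.de_results_ = res
        self.signature_ = _de.build_signature(res, self.alpha)
        self.n_features_in_ = Xf.shape[1]
        self.feature_names_in_ = np.asarray(Xf.columns)
        return self

    def score_samples(self, X) -> pd.Series:
        check_is_fitted(self, "signature_")
        Xf = _as_frame(X)
        sv = _score.compute_igf1_score(
            Xf.T,
            self.signature_,
            rule=_pp.FilterRule(self.min_count, self.min_fraction),
            pseudocount=self.pseudocount,
            min_overlap=self.min_overlap,
        )
        self.last_score_vector_ = sv
        return sv.scores

    def transform(self, X):
        return self.score_samples(X).to_numpy()[:, None]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["igf1_score"])

    def set_signature(self, signature: SignedGeneSet) -> "IGF1SignatureScorer":
        """Install an externally computed signed gene set (e.g. from a
        published DE table) instead of fitting one."""
        self.signature_ = signature
        return self
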