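# Methods

`igf1score` implements a two-stage transcriptomic analysis: learn a
*signed* pathway signature from a controlled stimulation experiment,
then project that signature onto an independent patient cohort as a
single number per sample, and test whether that number separates
clinically defined patient groups. The concrete use case it was built
around is IGF1-receptor signalling in circulating CD14+ monocytes of
rheumatoid-arthritis patients, but every stage is generic over the gene
set and marker.

## Model and procedure

**Counts.** All stages consume a genes × samples matrix of non-negative
integer read counts. Counts for gene *g* in sample *j* are modelled as
negative binomial with mean `mu_gj = s_j * q_g * 2^(x_j * beta_g)` and
variance `mu + phi_g * mu^2`, where `s_j` is a sample depth (size)
factor, `q_g` a baseline expression level, `beta_g` a signed log2 fold
change, `x_j` the condition covariate (0/1 in the reference experiment,
a continuous latent activity `a_j` in the cohort), and `phi_g` the NB
dispersion.

**Preprocessing.** Genes are kept when more than `min_count` (default 5,
strict inequality) counts are observed in at least
`ceil(min_fraction * n_samples)` samples (default fraction 1/3). Size
factors use the median-of-ratios estimator: `s_j` is the median over
reference genes (those positive in every sample) of
`K_gj / exp(mean_j log K_gj)`, with the geometric mean computed on the
log scale. Filtering precedes size-factor estimation. Normalised counts
are `K_gj / s_j`; the log transform is `log2(x + pseudocount)` with
pseudocount 1 by default, both recorded as provenance.

**Differential expression.** The DE stage is an intentionally simple
two-group NB Wald test. Per-gene dispersions come from the method of
moments on normalised counts, pooling within-group variances:
`phi = max(1e-8, (var - mean) / mean^2)`. The log2 fold change is the
ratio of pseudocounted normalised group means; its standard error comes
from the delta method under the NB variance function, propagating each
sample's `mu/s_j^2 + phi * (mu/s_j)^2`. The Wald statistic is referred
to a **t distribution with n1 + n2 − 2 degrees of freedom**. This is a
deliberate design choice: moment dispersion estimates at the group
sizes this test targets (3–10 per arm) are noisy, and a plug-in normal
reference inflates the type-I error to roughly `P(|t_df| > 1.96)`
(≈ 0.083 at 5 vs 5, measured by simulation); shrinkage-based DE tools
solve the same problem by pooling dispersions across genes, which is
out of scope here. With the t reference the measured null type-I error
at 5 vs 5 is ≈ 0.05, and the reference converges to the normal as
groups grow. There is no dispersion shrinkage, outlier replacement or
independent filtering; the DE table is a plain TSV
(`gene, log2fc, se, stat, pvalue, padj`), so an externally computed
table can be substituted wholesale.

Multiple testing uses Benjamini–Hochberg (delegated to
`statsmodels.stats.multitest`; an independent brute-force implementation
of the step-up definition lives in the test suite as an oracle).

**Signature.** All genes with BH-adjusted p < alpha (default 0.05,
strict) form the signed gene set, oriented +1 when up-regulated with
stimulation and −1 when down-regulated; genes with a fold change of
exactly zero are excluded. Ties at exactly alpha are excluded.

**Score.** Given a cohort count matrix and a signed gene set, the
pipeline filters, normalises and log-transforms the cohort, z-scores
each gene across *all cohort samples jointly* (sample SD, n−1
denominator), multiplies down-regulated genes by −1 so that a positive
score always means more signalling, and averages the oriented z-scores
over the signature genes with equal weights. Scores are therefore
cohort-relative: the cohort mean score is 0 by construction, and the
score is invariant to per-gene affine transformations of the log
matrix. Signature genes absent from the cohort matrix (filtered or
zero-variance) are dropped with recorded reasons; scoring refuses when
fewer than `min_overlap` (default 50%) of the signature remains.

**Cohort association.** The cohort is stratified at the median of a
marker variable; samples at or above the median are "high", strictly
below are "low" (for odd n with distinct values: (n+1)/2 high,
(n−1)/2 low — 28/27 at n = 55). Continuous variables are compared
between strata with the Mann–Whitney U test (exact enumeration when
both groups have ≤ 8 observations and no ties, otherwise the normal
approximation with tie and continuity corrections); binary flags with
Fisher's exact test, reporting the sample odds ratio `ad/bc` and a
Woolf log-interval; correlations use Spearman's rank coefficient.
Percentages in the report are rounded half-up to one decimal. No
multiple-testing correction is applied across report rows (BH is used
only in the DE stage). Score-by-group comparisons report per-group
medians, their ordering and pairwise Mann–Whitney p-values.

The Mann–Whitney "auto" rule exists because the normal approximation
is genuinely coarse at the exact-enumeration sizes: its worst-case
absolute error against full enumeration is 0.011 at n1=n2=8 and grows
to 0.088 at n1=n2=2, so the exact path is used there instead.

## Synthetic data

The generator emulates the two data sets the analysis needs, with
negative-binomial counts (gamma–Poisson mixture) and full ground truth:

* **Reference experiment**: `n_per_group_ref` control and stimulated
  samples; a fraction `frac_responsive` of genes carries a signed log2
  fold change of magnitude `lfc_magnitude` (random sign).
* **Cohort**: each sample draws a latent activity
  `a_j ~ N(0.5, activity_sd)`, so the cohort spans control-like (a ≈ 0)
  to stimulated-like (a ≈ 1) states and the reference fold changes act
  directly as the cohort effect (`mu = s_j * q_g * 2^(a_j * beta_g)`).
  The marker measurement is `a_j + N(0, marker_noise_sd)`; two binary
  autoantibody flags (RF-like and anti-CCP-like) are independent
  Bernoulli draws with `P = invlogit(intercept − slope * a_j)`, so low
  activity raises positivity; a four-level pattern label
  (none / rf_only / ccp_only / double_positive) is derived from them.

Defaults (chosen once as a realistic small bulk study, then left
alone): 2000 genes with baselines log-uniform over 10^0.5–10^3.5 mean
counts, dispersion 0.1, 5 samples per reference arm, a 60-sample
cohort, 10% responsive genes at |log2FC| = 2, activity SD 0.3, marker
noise SD 0.3, log-normal depth factors with log-SD 0.2 (centred at
geometric mean 1), outcome intercept 1.7 and slope 3.0. The outcome
link was set so overall flag prevalence lands near 55–65%, the typical
seropositivity range in rheumatoid-arthritis cohorts, while keeping a
strong negative activity coupling. Reference and cohort use separate
deterministic random streams derived from one seed; identical config
and seed reproduce bit-identical outputs.

What the generator does **not** emulate: read-level artefacts (GC and
length bias, mapping error), batch structure (off by default; the
pipeline expects externally batch-corrected matrices when batches
exist), gene–gene correlation beyond the shared activity factor, and
outlier samples. Passing tests on this generator therefore demonstrate
internal correctness and statistical calibration of the pipeline, not
robustness to those real-data complications.

## Numerical choices and edge cases

* Dispersion floor 1e-8; genes with zero or sub-Poisson variance sit at
  the floor. All-zero genes report LFC 0, p 1 by convention.
* Geometric means on the log scale; samples with zero counts on a
  reference gene make size factors undefined and raise with advice to
  filter first.
* Constant (zero-variance) genes are excluded from z-scoring with a
  warning naming them, and count as "dropped" for signature overlap.
* Median-split tie policy "at or above → high" is recorded on the
  result object; all identical marker values raise rather than produce
  a degenerate split.
* Odds ratios with a zero denominator report `inf` (zero numerator:
  0 or NaN) with a `degenerate_or` flag; Woolf intervals are undefined
  when any cell is zero.
* Re-estimating size factors on an already-normalised matrix returns a
  constant vector equal to the geometric mean of the original factors;
  that constant deviates from 1 by the skewness of the count log-noise
  (≈ 1.5% at dispersion 0.05, ≈ 2.5% at 0.1 on default simulations).

## Problem sizes used in the shipped checks

Simulation-based tests and the acceptance script use the default
generator (2000 genes, 5 vs 5 reference, 60-sample cohort), 20 null
replicates for type-I calibration, 5 replicates for power, and 200
cohort replicates for the group-ordering property; oracle equivalences
enumerate all 2×2 tables with margins ≤ 15 and all balanced tie-free
Mann–Whitney cases up to n = 8.

## Known limitations

* The DE stage is a simplified Wald test; it is calibrated under the
  simulator's NB model but lacks the robustness machinery of mature DE
  tools (shrinkage, outlier handling). For publication-grade DE, feed
  an external DE table into `build_signature`.
* Single-sample scores are cohort-relative; a sample's score changes
  when the surrounding cohort changes. Comparing scores across cohorts
  requires a shared reference cohort.
* The estimator classes re-fit cohort-internal statistics inside
  `transform` (by design — the score is defined within-cohort), which
  departs from the strict sklearn contract that `transform` applies
  only fitted state.
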