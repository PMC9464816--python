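# igf1score

Signed pathway signatures and single-sample signature scores for bulk
RNA-seq cohorts, built around one question from rheumatoid-arthritis
immunology: do patients whose circulating CD14+ monocytes show weak
IGF1-receptor signalling produce more autoantibodies?

The package turns that analysis into a tested, reusable pipeline:

1. **Learn a signed signature** from a two-arm stimulation experiment
   (IGF1-stimulated vs vehicle-control macrophages): filter low-count
   genes (> 5 counts in at least a third of samples), normalise by
   median-of-ratios size factors, run a negative-binomial Wald test,
   and keep every gene with Benjamini–Hochberg adjusted p < 0.05,
   signed +1 (up with stimulation) or −1 (down).
2. **Score a cohort**: log2-transform the normalised cohort counts,
   z-score each gene across all samples, flip the down-regulated genes
   so a positive value always means more signalling, and average over
   the signature — the per-sample *IGF1-score*
   `S_j = (1/|G|) * sum_{g in G} w_g * z_gj`, with `w_g ∈ {+1, −1}`.
3. **Associate**: split the cohort at the median of a marker (e.g.
   IGF1R expression or the score itself), compare continuous variables
   with Mann–Whitney U tests and binary flags with Fisher's exact test
   (odds ratios with confidence intervals), correlate with Spearman's
   rank coefficient, and compare score distributions across
   autoantibody patterns (none / RF-only / CCP-only / double-positive).

Because the underlying patient data live in controlled-access GEO
accessions (GSE201670 — cited once as GSE201370 in the source — for the
patient CD14+ RNA-seq, GSE202515 for the IGF1-stimulated macrophage
reference), the package ships a negative-binomial simulator that
reproduces the statistical structure of both data sets with known
ground truth (per-gene signed fold changes, per-sample latent pathway
activity, activity-linked autoantibody flags), so every stage is
testable end to end. See `docs/methods.md` for the model, defaults and
limitations.

## Worked example

The estimator API follows scikit-learn conventions (samples × genes,
`fit`/`transform`); lower-level functions operate on genes × samples
DataFrames and give identical numbers.

```python
from igf1score import (SimulationConfig, simulate_reference, simulate_cohort,
                       IGF1SignatureScorer, median_split, summarize_cohort)

cfg = SimulationConfig(seed=1)                       # 2000 genes, 5v5 reference, 60 patients
ref_counts, groups, truth = simulate_reference(cfg)
cohort_counts, meta, _ = simulate_cohort(cfg, truth)

scorer = IGF1SignatureScorer(alpha=0.05).fit(ref_counts.T, groups)
print(f"signature: {len(scorer.signature_)} genes "
      f"({len(scorer.signature_.up)} up, {len(scorer.signature_.down)} down)")
# signature: 173 genes (94 up, 79 down)

meta["igf1_score"] = scorer.score_samples(cohort_counts.T)
strata = median_split(meta["igf1_score"])
report = summarize_cohort(meta, strata)
print(report.table[["variable", "high_summary", "low_summary", "pvalue", "odds_ratio"]])
```

which prints (seed 1):

```
             variable  high_summary  low_summary  pvalue  odds_ratio
    marker_expression   0.73 ± 0.39  0.22 ± 0.38  0.0000         NaN
            age_years 58.85 ± 11.03 57.87 ± 9.53  0.8418         NaN
           igf1_score   0.58 ± 0.42 -0.58 ± 0.34  0.0000         NaN
          rf_positive     9 (30.0%)   25 (83.3%)  0.0001      0.0857
         ccp_positive    13 (43.3%)   24 (80.0%)  0.0073      0.1912
autoantibody_positive    19 (63.3%)   28 (93.3%)  0.0102      0.1234
```

Reading the table: of the 173 signature genes learned from the
stimulation experiment, the score they induce separates the simulated
cohort as designed — score-high patients carry RF-like autoantibodies
in 30% of cases against 83% among score-low patients (Fisher odds
ratio 0.086 for high-vs-flag, i.e. flags are enriched roughly 12-fold
in the low stratum), while a covariate unrelated to pathway activity
(age) shows no group difference. The marker row confirms the split
tracks the latent activity the simulator planted.

The same stages are available as a CLI
(`igf1score simulate | preprocess | de | signature | score | associate | run`);
`igf1score run --seed 1 --outdir out/` executes the whole pipeline and
writes every intermediate artifact plus a checksummed run manifest.

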