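# Methods

This note records the statistical models implemented in protosig, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions at edge cases.

## Data model

The central object is a proteins × samples matrix of log2
(tumour / internal standard) ratios with an explicit missing mask.  Log
base 2 is used throughout: fold statements convert cleanly (a "fivefold
range" is ±log2(5) ≈ ±2.32) and effects add in log space while acting
multiplicatively on raw ratios.  On disk, missing values are empty cells
or `NaN`; zeros in ratio columns are treated as missing, because a zero
spike-in ratio is a non-detection artifact, not a measurement.  Ratio
orientation is explicit: readers accept either sample/standard or
standard/sample and normalize to sample/standard by negating after the log
transform.  The protein-groups dialect defaults to standard/sample
(the heavy channel is the spiked-in standard) — overridable, since export
conventions vary.  Identifiers are taken verbatim; any mapping between
identifier universes (e.g. gene symbols to protein groups) is the
caller's responsibility.

## Valid-value filtering

`filter_min_valid` keeps proteins whose fraction of observed values
*strictly* exceeds the threshold, either over all samples or within at
least one class.  The strict inequality is deliberate: a protein observed
in exactly 70% of samples does not pass a ">70%" filter.  The filter is
idempotent and never changes the sample set.

## Downshift imputation

Missing values are assumed to arise from low-abundance proteins
(missing-not-at-random).  Per sample s with observed mean m_s and
standard deviation sd_s, each missing entry is drawn independently from

    Normal(m_s − d·sd_s, (w·sd_s)²),   d = 1.8, w = 0.3 by default.

These defaults are the long-standing convention for downshift imputation
in proteomics software; they place imputed values in the lower tail of
the observed distribution with a narrow spread.  Observed entries are
never altered, and a fixed seed gives bit-identical output.  Imputation
is performed once on the full matrix before classification; this leaks a
small amount of information across cross-validation splits (the
imputation model sees all samples), which is the standard practice the
framework mirrors.  Per-split imputation can be performed manually by
imputing inside a custom loop; the accuracy curves reported here use the
single-pass mode.

## Sample similarity

Pairwise Pearson correlations use pairwise-complete observations so the
analysis runs on unimputed data; pairs sharing fewer than 3 proteins are
undefined and the offending samples are greedily removed from clustering
(most-undefined first) with a warning.  Clustering is agglomerative on
the distance 1 − r with average linkage by default.

## 1D annotation enrichment

Per-protein values (one-vs-rest mean differences Δ) are ranked ascending
with average ranks for ties; proteins without a value are dropped from
the ranking rather than midrank-assigned.  A category with n_in members
among n ranked proteins gets

    s = 2 · (meanRank_in − (n+1)/2) / (n − n_in),

a range-normalized Wilcoxon shift: +1 iff the members hold exactly the
n_in top ranks, −1 for the bottom, 0 in expectation under random
assignment.  Significance is the two-sided Wilcoxon–Mann–Whitney test:

* n ≤ 12 — exhaustive enumeration of all C(n, n_in) placements of the
  member set over the realized rank multiset (exact under ties);
* n > 12 — normal approximation with tie correction
  Var = n_in·n_out/12 · ((n+1) − Σ(t³−t)/(n(n−1))) and a 0.5 continuity
  correction toward the mean.

Categories with n_in below `min_size` (default 5) or covering all ranked
proteins are skipped.  BH correction runs across all tested categories at
FDR 5% by default; an additional raw-p threshold parameter exists for
analyses that filter on the unadjusted p-value.  In two-level
hierarchies, each parent is the deduplicated union of its leaves'
members, leaf and parent levels are corrected independently, and
categories without a parent link are tested at the leaf level labelled
`none`.

## Differential expression and permutation FDR

One-vs-rest t-tests use the pooled-variance two-sample statistic (sign
positive when the target class mean is higher); one-way ANOVA is the
fixed-effects F with (k−1, N−k) degrees of freedom on observed values.
Conventions at degenerate inputs: zero within- and between-group variance
gives F = 0, p = 1 (non-significant); zero within- with positive
between-variance gives an infinite statistic with the smallest
representable p.  Proteins with insufficient data (fewer than 2 observed
values on a side, or per class) are reported with empty statistic fields
rather than silently dropped.

Permutation FDR: observed statistics once, then `n_permutations`
(default 250) random relabelings preserving class sizes, recomputing the
full statistic vector each time.  For a threshold c,

    FDR(c) = median over permutations of #{perm ≥ c} / #{observed ≥ c},

capped at 1; a protein's q is the minimum of FDR(c) over thresholds at or
below its own statistic, which is non-increasing in the statistic by
construction.  Counts use ≥ on both sides.  The median (rather than
mean) numerator is a robustness choice; its price is quantization — the
median of an integer count moves in unit steps, so q-values are resolved
only to 1/#{observed ≥ c} at each threshold.  Two independent
1,000-permutation runs therefore agree on the significant set and on q up
to that granularity, not to arbitrary precision.  An optional s0 offset
can be added to the t-statistic denominator (default 0).

## Classification framework

One-vs-rest linear SVMs (libsvm backend, C = 1 by default) on
per-feature standardized training data; the standardization constants are
part of the stored decision function, and zero-variance features are
dropped before scaling.  A linear kernel is the deliberate choice: the
object of interest is a ranked list of individual proteins, and only a
linear decision function attributes a signed weight to each.

Feature ranking sorts proteins by ascending one-vs-rest t-test p-value,
breaking ties by |t| descending then identifier — fully deterministic.
Cross-validation draws `round(test_fraction · n_c)` test samples per
class (stratified; an unstratified mode exists), re-ranks on the training
split only, and records test accuracy for every feature count in the
grid.  Accuracy is the fraction of correct binary one-vs-rest calls of
the class's own model; the multi-class prediction (argmax of decision
scores, ties broken by class order) is available separately via
`predict`.  The optimal feature count per class is the smallest g
attaining the maximum mean accuracy — the minimum panel with the smallest
estimated error.  The final signature re-ranks on the full data (the
split rankings exist to estimate accuracy, not to name features), takes
the top-g proteins per class with direction = sign of the class mean
difference, and trains final models on those features.  A protein may
mark more than one class.  ROC curves sweep the decision threshold; AUC
equals the pairwise Mann–Whitney probability with ties counted ½.
Resubstitution ROC (full-data models scored on the same data) and
held-out ROC are both supported and must be labelled as such — on small
cohorts resubstitution AUC is optimistic.

## Synthetic data generator

Value model for protein p in sample s of class c:

    x_ps = b_p + effect_p(c) + ε,  ε ~ N(0, noise_sd²),  b_p ~ N(0, baseline_sd²).

Markers receive ±marker_effect in their class (random recorded sign);
members of a planted category receive +category_shift in its class.
Missingness is value-dependent: an entry is censored with probability
logistic(k·(τ − x)), with τ solved (Brent) so the expected missing
fraction matches the target; k = 0 degenerates to uniform missingness.
The complete pre-censoring matrix is retained in the truth object —
essential for testing imputation and MNAR behaviour, impossible with real
data.

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| samples_per_class | (14, 15, 11) | a realistic 40-sample three-subtype cohort |
| n_proteins | 7,000 (default study) | typical per-sample quantification depth |
| marker_effect | 0.8 log2 | sub-twofold, as inter-subtype protein differences tend to be |
| noise_sd | 0.5 log2 | within-class measurement + biological scatter; with baseline_sd = 1 it yields inter-sample r ≈ 0.7 and a ratio spread mostly within fivefold |
| protein_baseline_sd | 1.0 log2 | between-protein abundance spread dominates between-sample scatter |
| category_shift | 0.5 log2 | a coherent but individually weak pathway-level shift |
| missing_target_fraction | 0.15 | ~6,000 of 7,000 proteins observed per sample |
| mnar_steepness | 2.0 | missingness concentrated on low-abundance proteins without a hard cutoff |

What the generator does **not** emulate: peptide-level quantification and
protein inference, correlated noise between co-regulated proteins,
batch/run-order effects, heavy-tailed outliers, and class-dependent
missingness beyond what the value model induces.  Passing recovery tests
on this generator therefore demonstrates the statistical machinery is
correct and calibrated — not that real cohorts of this size always yield
signatures this clean.

A consequence of MNAR worth knowing: markers sitting on low-abundance
proteins can be censored so heavily that downshift imputation erases
their class contrast; such planted markers are unrecoverable by any
ranking on the imputed matrix.  Recovery rates below 100% in the tests
are this mechanism, not a defect of the selection procedure.

## Problem sizes used in the test suite

The statistical acceptance tests run the marker-recovery scenario at
2,000 proteins with the full cross-validation protocol (250 resamplings,
grid 1..30) over 25 generator seeds; null calibration uses 10,000 null
proteins for uniformity checks and 50 seeds of 300-protein instances for
permutation-FDR false-positive rates; exactness oracles enumerate all
instances up to n = 12.  These sizes were chosen so the whole suite
completes in well under half an hour on a single core while keeping every
estimate's Monte-Carlo error far below the asserted margins.

## Known limitations

* Imputation before (not inside) cross-validation mildly flatters
  accuracy estimates; see above.
* The earliest-maximum rule for the optimal feature count is noisy when
  the accuracy curve is flat near its peak; signature sizes can vary
  between reruns with different CV seeds even when accuracy hardly does.
* Permutation-FDR q-values are quantized (median numerator); report the
  significant set, not fine q differences.
* The exact enrichment p-value is limited to n ≤ 12 by combinatorics;
  at n slightly above 12 the normal approximation is weakest for very
  small categories.
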