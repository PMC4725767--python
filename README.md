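# protosig

Quantitative proteome subtype analysis: from a spike-in-ratio expression
matrix to a minimal protein signature that separates tumour subtypes.

## The problem

Deep quantitative proteomics of tumour cohorts (e.g. super-SILAC
quantification of breast cancer FFPE samples) yields a matrix of log2
(tumour / internal standard) ratios for thousands of proteins over a few
dozen samples, each labelled with a clinical subtype such as ERPR, Her2 or
triple-negative.  Three questions follow:

1. **Which biological processes differ between subtypes?**  For each
   subtype, every protein gets a one-vs-rest mean difference
   Δ_p = mean(in subtype) − mean(others).  A category (gene set, pathway)
   is *enriched* when the Δ values of its members are shifted relative to
   the global distribution.  protosig tests this with the
   Wilcoxon–Mann–Whitney rank-sum test and summarizes it with the score

       s = 2 · (meanRank_in − (n+1)/2) / (n − n_in)  ∈  [−1, 1],

   +1 when the members occupy exactly the n_in highest ranks (enriched for
   high expression), −1 for the lowest.  Two-level category hierarchies
   (KEGG BRITE style) are tested at both levels with independent
   Benjamini–Hochberg correction.

2. **Which individual proteins change significantly?**  One-way ANOVA
   across subtypes, with the false discovery rate estimated by permutation:
   the full F-statistic vector is recomputed under random relabelings of
   the samples, and FDR(c) = median_perm #{perm F ≥ c} / #{observed F ≥ c}.

3. **What is the smallest protein panel that predicts the subtype?**
   One-vs-rest linear SVMs with t-test feature ranking, embedded in
   random-sampling cross-validation (15% test fraction, 250 resamplings):
   features are ranked on each training split only, classifiers are trained
   on the top-g features for g = 1..30, and the per-class accuracy curve
   (mean over runs) determines the optimal g as its earliest maximum.  The
   final signature is the top-g proteins per class from a full-data
   ranking, each tagged positive/negative by the sign of its mean
   difference.

Missing values are missing-not-at-random (low-abundance proteins drop
out), so before classification they are imputed per sample from a
downshifted Gaussian: Normal(m_s − 1.8·sd_s, (0.3·sd_s)²) where m_s, sd_s
describe that sample's observed values.

A synthetic-data generator (`protosig.synthetic`) produces cohorts with
planted markers, planted enriched categories and abundance-dependent
missingness — with the complete pre-censoring matrix retained — so every
stage is testable against known ground truth.

## Worked example

Generate the default synthetic cohort (3 subtypes of 14/15/11 samples,
7,000 proteins, 5 planted markers per class at 0.8 log2 units, 10 enriched
categories, 15% MNAR missingness) and run the stages:

```sh
python analysis/01_simulate_study.py --seed 1
python analysis/02_quality_control.py
python analysis/03_enrichment.py
python analysis/04_differential_expression.py --seed 1
python analysis/05_classification.py --seed 1
```

which prints (seed 1):

```
cohort: 7000 proteins x 40 samples ({'Her2': 15, 'ERPR': 14, 'TN': 11})
missing fraction: 0.150 (target 0.15)
97.6% of observed log2 ratios within a fivefold range
proteins quantified per sample: median 5944, range 5907-6021
inter-sample Pearson r: mean 0.73, range 0.72-0.75
36 significant (class, category, level) records at FDR 0.05
planted-category recovery: 10/10 significant with s > 0
input: unimputed; tested 6883 proteins, 5 significantly changing at FDR 0.05
optimal feature counts: {'ERPR': 30, 'Her2': 30, 'TN': 2} (signature of 62 proteins total)
  ERPR: resubstitution AUC 1.00
  Her2: resubstitution AUC 1.00
  TN: resubstitution AUC 1.00
planted-marker recovery: 8/15
```

Reading this: the ratio distribution is narrow (the premise of accurate
spike-in quantification), samples correlate at r ≈ 0.7, all ten planted
categories are found enriched in the right subtype with a positive score,
and the cross-validated feature selection builds a signature whose
one-vs-rest models separate each subtype perfectly on resubstitution.
At the default sub-twofold marker effect only a third of the ANOVA
single-protein calls survive permutation FDR — individual weak markers are
much harder to certify than category-level shifts, which is exactly why
the rank-based enrichment and the multivariate classifier exist.

The same stages are available as a CLI (`protosig simulate | preprocess |
enrich | diffexpr | classify | run`); `protosig run` executes the whole
pipeline from a JSON config and writes a manifest that reproduces the run
byte-for-byte.

## Layout

```
src/protosig/       library: io, preprocess, enrichment, diffexpr,
                    classify, synthetic, pipeline, cli
analysis/           numbered narrative drivers (simulate → QC → enrich →
                    differential expression → classification)
tests/              pytest suite incl. statistical acceptance checks
scripts/            acceptance.py
docs/methods.md     model, assumptions, parameter choices, limitations
```
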