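# Methods

## Scope and data model

The pipeline consumes a gene × sample matrix of raw integer counts, a
sample annotation table (cohort, subject, draw index, GA at collection and
delivery, outcome, BMI, maternal age, race, QC metrics), a gene annotation
(biotype), and gene sets in GMT. All modelling happens in log₂(CPM + 1)
space; partition scores are computed in CPM space. The `ExpressionMatrix`
container carries a space tag (`raw_counts → cpm → log2cpm1 → corrected`)
and every operation checks it, so a stage cannot silently receive data in
the wrong scale.

## Synthetic cohort generator

The generator emulates the structure of a multi-site pregnancy cfRNA
study; it is the test bed for every downstream stage and returns a
`TruthRecord` of all generating parameters.

Generating model, per gene g, sample j in cohort c with GA t_j:

    μ_gj = b_g + s_g·t_j + δ_gc + β·1[case_j ∧ g ∈ panel]   (log₂-CPM)

CPM weights 2^μ − 1 are renormalized per sample, scaled by a lognormal
library size N_j, and counts drawn negative-binomial with fixed
dispersion φ (variance μ + φμ²) — the standard overdispersed RNA count
model.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| cohorts × samples | 8 × 150 | exercises all code paths; full 13k-gene scale is unnecessary |
| GA windows | distinct per cohort (4.9–40.2 wk) | cohorts occupy different GA ranges, so cohort offsets are *partially confounded* with GA — the confound the correction must untangle |
| genes | 2,000 (70% coding) | desk scale |
| trend_frac / slope_scale | 0.1 / 0.05 log₂CPM·wk⁻¹ | a minority of genes track gestation with modest slopes |
| trending slopes | sign ± magnitude \|N(0.05, 0.025)\| floored at 0.0125 | every "trending" gene has a recoverable sign |
| cohort_offset_sd | 0.3 log₂CPM | comparable to GA signal over a window — a real confound, not a nuisance epsilon |
| library size | lognormal(14.5, 0.4) ≈ 2M reads | plasma RNA-seq depth |
| dispersion φ | 0.1 | typical bulk RNA-seq overdispersion |
| PE panel | 7 coding genes, +1.0 log₂CPM in cases | a compact, dominant case signature |
| pe_prevalence | 0.137 | the case fraction of a 72/452 case–control design |
| longitudinal | 93 subjects × 4 non-overlapping windows (11.4–14, 18–21, 22.8–27.8, 29.2–34.8 wk) | serial-sampling design |
| delivery GA | 40 − Exp(1.5) wk, truncated [24, 42]; cases earlier by Exp(2.5) | right-skewed delivery timing enabling the survival stage |
| covariates | BMI, age, race independent of expression | the null the ANOVA stage should report |

What the generator does **not** emulate: read-level artifacts (GC bias,
duplication structure), fragment-length or capture bias, correlated
gene–gene noise, population structure in race, gene-specific dispersions,
or longitudinal within-subject autocorrelation beyond the shared GA trend.
Passing recovery tests therefore shows the *statistical machinery* is
correct under the stated generating model — not that real cfRNA data meet
that model.

## QC outliers

A sample is removed when any configured QC metric (default: total reads,
duplication rate, ACTB Ct) deviates more than k = 3 sample standard
deviations (ddof = 1) from that metric's mean. Zero-variance metrics are
skipped with a warning.

## Depth and cohort correction

1. **Depth**: per gene, OLS of log₂(CPM+1) on total counts in training;
   corrected value = residual + training gene mean (values stay on the
   log₂-CPM scale so CPM-space partition scores remain meaningful).
2. **Cohort**: per gene, residualize training expression on the variable
   of interest (GA); cohort offsets = per-cohort means of those
   residuals; subtract offsets everywhere. Only cohort structure
   orthogonal to GA is removed, so a gene whose apparent cohort difference
   is purely its GA trend is left intact.

Apply-time inputs are cohort labels and totals only — the function
signature has no variable-of-interest argument, making held-out GA leakage
structurally impossible (verified by a permutation-invariance test).
Cohorts with fewer than 2 training samples get offset 0 with a warning;
unseen cohorts at apply time are left uncorrected with a warning. Depth
and cohort fits are re-learned per training split.

## Gestational-age clock

Features: protein-coding genes with median expression > 0 in training.
Standardization uses training means/scales (zero-variance scales replaced
by 1). The penalty grid is 100 log-spaced values from the data-driven
λ_max down to 10⁻³·λ_max; CV uses K = 10 shuffled folds and MAE loss
reported in days (weeks × 7). The one-SE rule takes the largest λ with
mean CV error ≤ min + SE(argmin); because the grid is descending, the
first qualifying index is the answer, and the argmin always qualifies.
`refit_top_k` retains the k largest-|weight| standardized coefficients and
refits at the same λ. The learning curve repeats split → CV → fit → test
over shrinking train fractions with independent split seeds.

The ANOVA is sequential (type-I) with the cfRNA prediction entered first,
then BMI, maternal age, race (indicator contrasts, most frequent level as
reference). It is computed by explicit incremental least squares rather
than a formula interface so the entry order is exactly as stated; entering
the prediction first matches the scientific claim being tested (the clock,
not clinical factors, carries the signal), and the order can be changed by
argument. `compare_models` is a paired bootstrap (B = 1,000) over test
samples of the MAE difference between two predictors.

## Gene-set trends and monotonicity

Cumulative CPM scores are exact sums over member genes present in the
matrix (absent members contribute 0 and are logged; fully unresolvable
sets are dropped with a warning). Trends are OLS of score on GA per
(set, cohort), two-sided slope p and 95% CI. Discovery selection applies
BH across sets at adjusted p < 0.01; the scramble control permutes GA
labels (p with add-one correction, ≥ 99 permutations); confirmation
requires per-cohort unadjusted p < 0.05 with matching sign in ≥ 2
non-discovery cohorts, and the reported cohort count includes discovery.

Monotonicity: a subject with four draws is monotone-up iff scores strictly
increase along draw order. Strictness matches the 1/24 combinatorial null
(ties are measure-zero for continuous scores; observed ties count as
non-monotone and are logged). The observed count per direction is compared
to expectation n/24 with a 1-df χ² goodness-of-fit (monotone vs not); an
exact binomial p is reported alongside, and `enumerate_orderings` exposes
the exhaustive 24-permutation null. Per-window summaries use mean ±
1.96·SE.

## Pre-eclampsia classifier

Inside every LOOCV fold: (1) optional nuisance correction re-learned on
the fold's training samples; (2) vectorized average-rank Spearman
correlation of each gene against the binary label, two-sided p via the
t-approximation, BH across genes, retain adjusted p < 0.05; (3)
unpenalized logistic regression on retained genes standardized by fold
statistics. When no gene survives screening the fold emits the constant
0.5 — deliberately *not* the fold's training prevalence, which varies with
the held-out label and would anti-predict it (the classical LOOCV
prevalence artifact, which biases null AUC toward 0).

The operating threshold is the largest probability cut-off achieving the
target sensitivity (default 75%) on out-of-fold probabilities; PPV follows
the closed-form identity with sensitivity, specificity and prevalence
(algebraically equal to TP/(TP+FP) when all three come from the same
confusion matrix). Bootstrap CIs are percentile intervals over B = 1,000
class-stratified resamples. The learning curve runs the identical pipeline
at k = 2…9 stratified folds with LOOCV as the terminal point. Survival
comparison: Kaplan–Meier curves of GA at delivery for test-positive vs
test-negative samples (sPTB excluded by default), two-group log-rank, no
censoring (all deliveries observed; a censoring argument exists).
Subtype specificity screens chronic-/gestational-hypertension vs
normotensive contrasts at unadjusted p < 0.05 and reports overlap with the
PE gene list; contrasts with < 5 samples are skipped.

## Orchestration and reproducibility

`RunConfig` is a flat YAML-serializable record; one global seed expands to
per-stage seeds by fixed offsets, so identical configs give byte-identical
metrics JSON. Every stage logs filter before/after counts. Disabled
upstream stages cause explicit dependency errors downstream.

## Problem sizes

Tests and the acceptance script run the pipeline at reduced scale chosen
to keep each check sharp while remaining quick on one CPU: 6 cohorts ×
100 samples × 700 genes for the clock-recovery comparison (means over 3
fixed seeds), 2 × 130 samples × 300 genes for the case–control classifier
(20 seeds for panel-recovery frequency), 60-subject × 4-cohort
longitudinal sets for trend confirmation, and 2,000 × 93 null simulations
for monotonicity calibration. These sizes are the package's desk-scale
defaults; the same code runs unchanged at larger scales.

## Known limitations

- Corrections are linear; nonlinear (spline) depth effects, empirical-
  Bayes batch methods and per-flowcell effects are out of scope.
- The clock is a plain lasso; elastic-net or nonlinear clocks are not
  implemented.
- The classifier assumes a shared case signature across cohorts; the
  generator plants one, real heterogeneity may be larger.
- Synthetic covariates are independent of expression by default, so the
  <1% covariate-variance result on simulated data is a calibration of the
  machinery, not evidence about any real population.
- The survival stage treats all deliveries as observed events.
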