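# Methods

This note documents the models, estimators and numerical choices behind the
package: a synthetic electronic-health-record (EHR) cohort generator with
censored time-to-readmission outcomes, a derivation engine for parsimonious
integer point-score survival models, exact calculators for the published
SERAP, LACE and HOSPITAL readmission scores, and the time-to-event
evaluation suite used to compare them.

## The scoring model

A point-based survival score assigns each predictor to one of a small
number of ordered categories and each category a non-negative integer
number of points; the per-episode total

S(x) = Σ_v points_v(x_v)

stratifies time-to-event risk. Interval predictors use closed-open bins on
the left boundary (`65-104` means 65 ≤ x < 105), so printed contiguous
integer intervals are reproduced without gaps. Every variable has at least
one zero-point category, the achievable range is the sum of per-variable
minima/maxima, and applying a table is permutation-equivariant and additive
by construction.

The packaged SERAP table covers six variables — prior-year ED admissions
(0–19 points), age (0–5), malignancy history (0–7), renal disease (0–2),
serum creatinine in µmol/L (0–2, with a 1-point penalty *below* 65), and
serum albumin in g/L (0–5) — totalling 0–40. LACE (length of stay, acuity,
Charlson index, prior-six-month ED visits; 0–19) and HOSPITAL (hemoglobin,
oncology discharge, sodium, procedure, admission type, prior-year
admissions, length of stay; 0–13) are encoded from their original
publications (van Walraven et al. 2010; Donzé et al. 2013), which print the
full point tables; they carry citation metadata and are covered by schema
and invariant tests rather than value tests against any particular cohort.

## Synthetic cohort generator

The generator emulates episode-level data from a tertiary-hospital
emergency-admission cohort. Covariates (≈35 columns) cover demographics,
triage class, Charlson-style comorbidity flags, labs and vitals with
missingness, and prior-utilization counts; prevalences and moments follow
values typical of such cohorts (e.g. age ~ N(63, 17²) years, renal disease
21.9%, metastatic malignancy 5.7%). Three columns are *deliberately
correlated* with others for realism: creatinine is multiplied by 1.8 for
episodes with the renal-disease flag, all-cause prior admissions and
prior-six-month ED visits are derived from prior-year ED admissions by
thinning/superposition, and oncology discharge depends on malignancy
status.

Outcomes follow a proportional-hazards exponential law driven by a known
ground-truth point score S:

h(t | x) = λ₀ · exp(β · S(x)),   T ~ Exp(h),

administratively censored at 90 days, with event times reported in whole
days (ceiling), as EHR systems record them. Missingness (MCAR; ~1% for
vitals, up to 22% for some labs) and out-of-range outliers (0.2% of
continuous cells) are injected *after* outcome generation, so corruption
never feeds back into the hazard. The truth table defaults to the SERAP
table itself, making ranking recovery, point recovery and evaluation
testable end to end.

Defaults β = 0.18 per point and λ₀ = 3.99·10⁻⁴/day were calibrated once
(by bisection at n = 100,000) so the generated data reproduce two study
conditions — a 27.3% 90-day readmission fraction and truth-score
discrimination of C ≈ 0.75 — and then frozen as named constants.

What the generator does **not** emulate: a constant baseline hazard spreads
events almost uniformly over the 90-day window, so the conditional median
time to readmission is ≈ 40 days, not the ≈ 22 days seen in real cohorts
whose readmission hazard is front-loaded; covariate correlations beyond the
three pairs above are absent; missingness is MCAR, whereas real lab
missingness is informative; deaths and non-ED readmissions are not
modeled (single-event right censoring). Passing tests therefore certify
the *mechanics* of derivation and evaluation, not clinical performance on
real data.

An optional uniform dropout rate (default 0) censors episodes before the
horizon; the administrative 90-day cut is otherwise the only censoring
mechanism.

## Derivation engine

The engine derives a score in five stages, all reproducible from one seed:

1. **Ranking.** A random survival forest (scikit-survival, log-rank split
   criterion, 100 trees, √p features per split, minimum leaf size 20) is
   fit to the training cohort; each tree grows on a bootstrap subsample of
   at most 1,000 episodes, which keeps single-CPU fits at n ≥ 20,000 in
   seconds without changing what the forest estimates. Importance of a
   variable is the mean drop in Harrell's C on a fixed evaluation subsample
   (default 2,000 episodes) when that variable's column is permuted
   (default 3 repeats). Ties break by training-column order, so rankings
   are deterministic.
2. **Parsimony.** For each model size m, a tentative score from the top-m
   variables is built on the training cohort and measured by integrated
   AUC on the validation cohort. The default selection rule takes the
   smallest m within 0.005 iAUC of the curve's maximum; a fixed m can be
   forced.
3. **Categorization.** Continuous and count variables are binned at the
   training quantiles (0, 0.05, 0.2, 0.8, 0.95, 1); duplicate boundaries
   collapse, boundaries at or below the observed minimum are dropped, and
   integer-valued variables get integer (ceiling) boundaries. Binary and
   categorical variables pass through.
4. **Fine-tuning.** Boundaries can be replaced by clinician-friendly round
   numbers (e.g. age 30/50/80); overrides are re-validated for strict
   monotonicity and non-empty bins.
5. **Point assignment.** Categories are dummy-coded against each variable's
   first category and fed to a Cox proportional-hazards fit (lifelines).
   Coefficients are divided by the smallest positive coefficient magnitude
   (configurable), rounded half away from zero, and shifted so each
   variable's minimum category scores 0. There is no global rescaling to a
   fixed total.

Numerical choices: the Cox fit uses a ridge penalizer of 10⁻⁴ — at strong
effects rare high-risk categories approach separation and the unpenalized
Newton-Raphson diverges; 10⁻⁴ is small enough to leave recovered points
unchanged (Spearman 0.996 against ground truth at n = 20,000) while larger
values (10⁻³) visibly distort them. Because the Cox partial likelihood
depends on times only through their order, derived points are invariant to
the time unit.

The `ScoreDeriver` estimator wraps the same flow behind the scikit-learn
protocol (`fit(X, y)` with a scikit-survival structured target,
`predict`, `get_params`/`set_params`), holding out a random 20% validation
fraction when no explicit validation cohort is passed.

On ranking recovery: prior-year ED admissions drives 19 of 40 truth
points, and its two derived proxies (all-cause admissions, six-month ED
visits) carry nearly the same information, so any importance measure may
legitimately swap them. Exact top-6 recovery is therefore only a
well-posed property over the menu of six informative variables plus
*independent* noise covariates; recovery tests exclude the three
correlated proxies from the candidate set.

## Preprocessing

Out-of-range values (strictly outside inclusive plausible bounds, e.g.
SpO₂ > 100%, negative labs) are nulled; the shipped range table is a set of
deliberately wide implementation defaults, with only the SpO₂ ceiling and
non-negativity externally fixed. Remaining missing values are imputed with
training-cohort medians (even counts: mean of the two central order
statistics); outcome and identifier columns are never imputed. Splitting is
either random (80/20) or temporal+random, where a holdout stratum (e.g.
the last calendar year) forms the test set and the remainder splits
randomly; splits are pure partitions, reproducible from the seed. The
Charlson index uses the classic 1/2/3/6-tier weights over condition flags,
with diabetes (0/1/2) and malignancy (0/2/6) graded.

## Evaluation suite

* **Harrell's C**: exact chunked pair enumeration. A pair (i, j) is
  comparable when tᵢ < tⱼ with i an event, or tᵢ = tⱼ with i an event and
  j censored; score ties count ½. Sums accumulate in ½ steps, so the
  estimate is exact (tests require equality with a brute-force oracle to
  1e-12).
* **AUC(t)** (cumulative/dynamic): cases are episodes with an event by t;
  controls are episodes followed event-free through t (time > t, or
  censored exactly at t — under the 90-day administrative cut this makes
  AUC(90) well defined); episodes censored strictly before t are excluded.
  Computed by the midrank Mann-Whitney identity, which equals case/control
  pair enumeration exactly. Under pure administrative censoring this
  coincides with KM-plug-in estimators; with heavy pre-horizon dropout it
  is a complete-case estimator, which is the one limitation of this choice.
* **iAUC**: the event-count-weighted average of AUC(t) over the grid of
  observed event times in [1, 90]; always within [min AUC(t), max AUC(t)].
  The weighting (empirical event-time distribution) is configurable in
  principle via the window arguments.
* **Bootstrap**: percentile method over episode-level resampling, default
  B = 1,000 (pipeline default 200 for runtime); refuses to report an
  interval if the metric is undefined on more than 10% of resamples.
  Paired comparisons of several score tables share one resample-index
  matrix whose SHA-256 digest is logged.
* **Kaplan-Meier and log-rank** come from lifelines; percentile readmission
  times are infimum times at which the KM cumulative incidence 1 − S(t)
  reaches the percentile, with times beyond the horizon reported as the
  ">90" sentinel.
* **30-day classification**: outcomes dichotomized at the horizon
  (censored-before-horizon excluded and counted), cut-off chosen as the
  score threshold minimizing the Euclidean distance to the (0,1) ROC
  corner over distinct observed scores (ties → lowest threshold;
  predict-positive convention: score ≥ cut-off), then sensitivity,
  specificity, PPV, NPV and likelihood ratios with bootstrap CIs;
  zero-denominator ratios are reported as undefined rather than silently
  dropped.

## Pipeline

`run_pipeline` fans one global seed out to independent per-stage child
seeds (SeedSequence), runs simulate → clean → split → impute → derive →
score → evaluate → report, and writes CSV/JSON artifacts plus a run log
containing every parameter, child seed, partition row-id digest and the
bootstrap resample digest — but no timestamps, so identical configurations
produce byte-identical artifacts. The test partition is formed before any
derivation and never touched by it (auditable from the digests).

## Test problem sizes

The suite exercises statistical properties at sizes chosen to run
comfortably on one CPU: null calibration on five cohorts of n = 5,000;
ranking recovery over 20 seeds at n = 3,000 (requiring ≥ 90% exact top-6
recovery) with point recovery checked once at n = 20,000 (Spearman ≥ 0.8);
the parsimony plateau over 20 seeds at n = 3,000 (the third, uninformative
variable must add < 25% of the second variable's validation-iAUC gain);
bootstrap coverage over 1,000 replications (n = 100, B = 500, nominal
93–97% band); and byte-level pipeline determinism at n = 2,000. Metric
implementations are checked against brute-force pair enumeration (100
random instances, tolerance 1e-12) and against scikit-survival's
concordance implementation as an independent cross-check.

## Known limitations

* The exponential baseline hazard cannot reproduce front-loaded readmission
  timing (real cohorts: median ≈ 3 weeks); a Weibull baseline with shape
  < 1 would, and is a natural extension.
* LACE and HOSPITAL are applied to synthetic covariates whose joint
  distribution was not designed to reproduce those scores' published
  operating points; their evaluation here demonstrates the comparison
  mechanism, not their clinical performance.
* The AUC(t) estimator is complete-case with respect to pre-horizon
  dropout (see above); with the default dropout rate of 0 this is exact.
* Multiple imputation and missing-not-at-random mechanisms are out of
  scope; the median-imputation default matches the hypothesis that missing
  labs are near-normal, which does not hold in every setting.
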