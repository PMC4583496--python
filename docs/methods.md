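# Methods

`imputebench` benchmarks how the handling of missing data changes the
apparent external-validation performance of logistic risk prediction
models.  The package has three scientific layers: a synthetic cohort
generator with a known outcome-generating model and controlled
missingness mechanisms; five missing-data strategies; and a validation
metric suite with Rubin's-rules pooling for multiple imputation.  This
note records the models, the defaults and why, and the design choices
made where more than one defensible option existed.

## The problem setting

A published logistic risk model predicts prevalent undiagnosed diabetes
as `p = expit(b0 + sum_j b_j * f_j(x))`, where each `f_j` is an identity,
category-indicator or banding transform of a cohort variable.  External
validation scores such a model, as published, on a new cohort and
reports discrimination (C-statistic), overall accuracy (Brier score,
Yates slope) and calibration (E/O ratio), optionally after recalibrating
the intercept so expected events match observed events.  Real validation
cohorts have missing data, and the choice of missing-data strategy is
part of the analysis pipeline being benchmarked.

## Synthetic cohort generator

The generator emulates a cross-sectional urban South African cohort of
adults screened for undiagnosed diabetes (n = 1083 after excluding 173
previously diagnosed participants from 1256 recruited).  Defaults:

| variable | kind | marginal | units |
|---|---|---|---|
| age | truncated normal on [18, 95] | 51.9 (15.0) | years |
| bmi | truncated normal on [12, 70] | 29.7 (7.2) | kg/m² |
| waist | truncated normal on [40, 200] | 95.8 (15.5) | cm |
| sbp | truncated normal on [70, 260] | 124.3 (20.2) | mmHg |
| dbp | truncated normal on [40, 160] | 76.0 (12.9) | mmHg |
| sex (female = 1) | Bernoulli | 0.765 | — |
| bp_meds | Bernoulli | 0.354 | — |
| corticosteroids | Bernoulli | 0.0116 | — |
| fh_mother / father / sister / brother | Bernoulli | 0.153 / 0.075 / 0.127 / 0.083 | — |
| smoking | categorical current/past/no | 0.426 / 0.103 / 0.471 | — |

Notes on the continuous marginals:

* **Moment matching.** The configured (mean, sd) are the moments of the
  *truncated* law; parent normal parameters are solved for numerically
  (`scipy.optimize.root` on the truncated mean and sd), so generated
  marginals hit their targets however hard the bounds bite.  A target sd
  at or above the uniform sd `(hi − lo)/√12` is rejected as infeasible.
* **Age bounds.** The cohort targeted ages 35–65, but no distribution on
  a 30-year interval can carry an SD of 15 years, and the emulated
  study's own dispersion implies participants outside the target band
  (community members outside the sampling frame were allowed to join).
  Age is therefore truncated at [18, 95].
* **Correlation.** Continuous variables share a Gaussian copula.  The
  only non-zero defaults are BMI–waist 0.5 and SBP–DBP 0.6: the source
  tables give no correlation structure, and these pairs are
  physiologically coupled.  Binary and categorical variables are drawn
  independently.

The outcome is generated *after* the predictors from a known logistic
model (age 0.045/yr, BMI 0.06 per kg/m², maternal family history 0.6,
antihypertensive treatment 0.4).  Its intercept (−6.3149) was calibrated
once, by large-sample Monte-Carlo integration over the default
marginals, so that outcome prevalence equals the emulated study's
162/1075 ≈ 15.1%; the resulting model discriminates at C ≈ 0.75 on its
own cohorts.  Because the generating model is known, recovery of its
coefficients and of mean calibration is directly testable — the central
advantage of the synthetic design, and the reason the generator is
first-class tested code rather than a fixture.

### Amputation

Missingness is introduced per variable with mechanism MCAR, MAR or MNAR
and a target rate.  MCAR masks cells independently.  MAR masks with
probability `expit(a + Σ w_d z_d)` over standardised fully observed
drivers; MNAR uses the variable's own standardised value.  The intercept
`a` is calibrated by root-finding so the *expected* marginal rate equals
the target exactly; the realised rate then deviates only by binomial
noise.  MAR drivers may not themselves be amputed in the same pass
(enforced), since the mechanism would otherwise be conditioned on
unobserved values.  Amputation never alters values — unmasking
reproduces the pre-amputation table bit for bit.

Default rates mirror the emulated study's missingness analysis: the four
family-history indicators ≈ 25% each, smoking status 6.1%, everything
else (including the outcome, 0.7%) below 5%, all MCAR and independent
across variables.  Two caveats about what this does *not* emulate: in
the real cohort the family-history indicators were plausibly co-missing
(its any-missing share was 30.4%, far below what independent 25% rates
produce, ≈ 76%), and real missingness is rarely purely MCAR.  Tests that
pass under the default mechanism therefore demonstrate correctness of
the machinery and MCAR behaviour, not robustness to the real cohort's
dependence structure; MAR/MNAR configurations exist for that purpose.

## The five strategies

All conditional models use **every other variable plus the outcome** as
predictors of the variable being imputed; the outcome itself is
imputable.  Categorical predictors are one-hot encoded against the first
category.  Continuous targets use least-squares regression; binary and
categorical targets use unpenalised logistic/multinomial regression
(scikit-learn, `C=inf`).  Any unfittable conditional (too few complete
rows, a single observed class, solver failure) falls back to an
unconditional mean/mode fill (or an observed-distribution draw in
stochastic contexts) and is logged — benchmark sweeps must complete, and
a logged fallback is more informative than a crash.

* **deletion** — listwise complete-case analysis.  The label follows the
  common loose usage "pairwise deletion" found in applied reports, but
  the behaviour implemented (and the single reduced n it produces) is
  listwise.
* **simple** — column mean for continuous targets (preserves the column
  mean exactly, never increases the sd), observed mode for binary and
  categorical targets, ties broken toward the earliest code/category in
  schema order.
* **conditional** — conditional-mean fills from models fitted on rows
  complete in every variable; only cells whose row is complete on all
  predictors are filled, so residual missingness ("varied length" per
  variable) is expected and reported via per-variable effective n.
* **stochastic** — conditional prediction plus noise: continuous fills
  add `N(0, σ̂²)` with σ̂² the residual variance of the fit and *no*
  parameter-uncertainty draw (the classical stochastic-regression
  semantics); discrete fills are draws from the fitted class
  probabilities.  Rows incomplete on predictors — which the first pass
  cannot fill — are completed by one chained sweep seeded from
  unconditional draws, so the method always returns a full table.
* **mice** — fully conditional specification: m independent chains, each
  initialised with random observed-value draws and cycled through the
  variables in schema order for a fixed number of sweeps, refitting the
  stochastic conditional each visit on rows where the target is
  originally observed and redrawing its originally-missing cells.
  Continuous conditionals additionally draw σ² from its scaled inverse
  chi-square posterior and the coefficients from their normal
  conditional before adding residual noise.  Without these parameter
  draws between-imputation variance is understated and pooled intervals
  undercover; with them the MAR recovery experiment attains nominal
  coverage.  Discrete conditionals draw from maximum-likelihood class
  probabilities without a parameter draw — a documented approximation.
  Defaults: m = 5 (matching the emulated study's five imputed
  datasets), 10 sweeps (a conventional FCS default; the scenarios here
  mix in a handful of sweeps), visit order = schema order.

## Pooling

`rubin_pool` combines m estimates q_i with variances v_i as
q̄ = mean(q_i), W = mean(v_i), B = var(q_i) (divisor m−1),
T = W + (1 + 1/m)·B, with the classic large-sample degrees of freedom
ν = (m−1)(1 + W/((1+1/m)B))², infinite when B = 0.  The small-sample
Barnard–Rubin correction is out of scope.

`pool_reports` pools whole performance reports: point estimates as
plain means; interval half-widths through Rubin total variance on each
metric's working scale — logit for the C-statistic (per-dataset SEs
recovered from the CI half-width by the delta method) and log for E/O
(per-dataset log-scale SE = 1/√O) — mapped back around the pooled point
estimate with z = 1.96.  When all m reports are identical (B = 0 on
every metric) the pooled report is returned unchanged, so on complete
data multiple imputation degenerates exactly to single analysis.  Brier
score and Yates slope are pooled as means.

## Metrics and numerical choices

* **C-statistic** via midranks (Mann–Whitney), exactly equal to
  exhaustive pair enumeration with ties counting one half; 95% CI from
  the DeLong structural-components variance (Hanley–McNeil behind a
  flag), clipped to [0, 1].
* **E/O** with the log-scale Poisson CI `ratio · exp(±1.96/√O)`, chosen
  because it keeps both bounds positive and is the standard construction
  for standardised-ratio intervals.
* **Yates slope** is mean(p | event) − mean(p | non-event), bounded in
  [−1, 1] by construction.
* **Linear predictors** are clamped to ±35 before `expit`, keeping
  probabilities strictly inside (0, 1) in double precision.
* **Intercept recalibration** solves `Σ expit(lp_i + δ) = O` by Brent
  root-finding on δ ∈ [−20, 20] (the expected count is continuous and
  strictly increasing in δ), to |E − O| ≤ 10⁻⁶·O.  Being a rank-
  preserving shift it leaves the C-statistic bit-identical.
* **Unscorable rows** (missing a required predictor after deletion or
  conditional imputation) are skipped and counted, with the effective n
  reported per cell; metrics for a cell are always computed on that
  cell's scored subset.
* **Degenerate cells** (no events or no non-events) raise typed errors;
  the pipeline records them as explicit NA with a reason and completes
  the remaining cells.

## Reproducibility

Every stochastic component takes an explicit seed.  The pipeline derives
sub-seeds by hashing the master seed with a label tuple (method name,
replicate index, ...), so adding a method or model to a run never
perturbs another's random stream; all derived seeds stay below 2³¹.
Identical configuration and seed give bit-identical cohorts, masks,
imputations and reports (verified by dataset checksums in the run
manifest).

## Problem sizes

The shipped experiments use cohorts of n = 1083 (the emulated study
size) for the benchmark grid and the deletion-penalty comparison
(50 replicates), and n = 2000 with 100 replicates for the MAR
parameter-recovery experiment (m = 5, 5 sweeps — a single amputed
continuous covariate reaches its stationary distribution in very few
sweeps).  These sizes give Monte-Carlo error comfortably below the
effects being measured.

## Known limitations

* The five shipped risk-model specs carry placeholder coefficients
  (flagged `placeholder_coefficients: true`): the predictor sets match
  the published models but the numeric values must be transcribed from
  the original publications by the user.  All engine behaviour is
  independent of the specific values.
* Discrete MICE conditionals omit the parameter-uncertainty draw.
* Predictive-mean matching, hot-deck, indicator-method, EM and
  joint-model MI are out of scope, as are calibration plots,
  Hosmer–Lemeshow tests and decision-curve analysis.
* The E/O Poisson CI and the pooling scales (logit for C, log for E/O)
  are standard but not the only defensible constructions; both are
  isolated behind the metric functions.
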