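# Methods

## The problem

After an ischaemic stroke, recovery of upper-limb capacity — measured with
the Action Research Arm Test (ARAT, integer 0–57) — is highly heterogeneous
and nonlinear over the first six months. Some patients never regain
function, some reach the ceiling within weeks, and early voluntary shoulder
abduction (SA) and finger extension (FE) are the strongest known clinical
predictors (the "SAFE" covariates). `dynarat` implements a dynamic,
patient-specific prediction pipeline: a population linear mixed-effects
model of the recovery time course is fitted once, and each individual
patient's forecast is updated from whatever measurements they happen to
have, at whatever irregular times they were taken.

## The model

For subject *i* with ARAT values *y_i* at days post-stroke *t_i*:

```
y_i = X_i β + Z_i b_i + ε_i,   b_i ~ N(0, G),   ε_i ~ N(0, σ² I)
```

* **Time course.** The fixed-effect time trend is a natural cubic spline of
  days post-stroke: piecewise cubic, C², linear outside the boundary knots,
  so extrapolation is tame. Quartile-based placement supports the 1/2/3-knot
  structures used in model comparison; the final model uses six manual knots
  at days {5, 9, 14, 21, 42, 91} (boundaries 0 and 200), concentrating
  flexibility in the first weeks where most change happens. Basis columns
  are rescaled by powers of the boundary span — an affine reparameterization
  of the same function space chosen purely for numerical conditioning.
* **Five fixed-effect structures.** model1: every candidate covariate (age,
  sex, affected/dominant side, Bamford class, rt-PA, NIHSS and its items 8
  and 11, neglect, FM-UE, FE, SA), each with a main effect and an
  interaction with the spline of time; model2/model3: significance-pruned
  versions (block-wise Wald tests, backward elimination to convergence, α =
  0.05); model4 ("SAFE"): SA and FE only, with time interactions; model5:
  time only. Categorical covariates are dummy-coded against their first
  level; time-varying covariates enter either as measured per visit
  (`last_observed`, the default — each new assessment refreshes them) or
  frozen at baseline (`baseline`).
* **Random effects.** Random intercept plus a smaller natural-spline of
  time (2 internal knots at days 14 and 42 by default → 4 correlated random
  effects, unstructured G). `re_knots=None` gives a random-intercept-only
  model.

## Estimation

β and σ² are profiled out in closed form (GLS), leaving an optimization
over the log-Cholesky factor of the *relative* covariance Ψ = G/σ² — the
same profiling nlme-style software uses. Per-subject Woodbury identities
keep every solve at the random-effects dimension, so one likelihood
evaluation is O(Σᵢ p²q). The profiled gradient is analytic (envelope
theorem; verified against central differences), which matters: with
finite-difference gradients the optimizer reliably stalled far from the
optimum on the 64-parameter SAFE structure. Optimization uses L-BFGS-B with
a method-of-moments start (per-subject ridge estimates of the random
effects), one flat fallback start, and jittered restarts; non-convergence
is flagged, never silent. REML is the default criterion (ML for comparing
fixed-effect structures). Convergence tolerance 1e-8 on the relative
log-likelihood change.

Fitting-set filters mirror the study protocol: subjects need ≥3
measurements spanning ≥84 days; subjects whose FM-UE drops by strictly more
than 7.25 points (the clinically important difference) within the first 182
days are excluded from fitting but retained for cross-validation.

## Dynamic prediction

Given a fitted model and a partial history (X_h, Z_h, y_h), the random
effects have the conditional-normal (empirical-Bayes/BLUP) distribution

```
b̂   = G Z_h' V_h⁻¹ (y_h − X_h β),    Σ_b = G − G Z_h' V_h⁻¹ Z_h G,
V_h = Z_h G Z_h' + σ² I.
```

The predicted trajectory is X(t)β̂ + Z(t)b̂; the analytic interval for a
*new measurement* at t has variance

```
Z(t) Σ_b Z(t)' + σ²  +  X_adj(t) Cov(β̂) X_adj(t)'  +  delta-method term,
```

with two refinements over the naive formula:

1. **Adjusted fixed-effect propagation.** Because b̂ is computed from
   residuals against X_h β̂, an error in β̂ is partially compensated by the
   empirical-Bayes mean. The β̂-uncertainty therefore propagates through
   `X_adj = X(t) − P X_h` with `P = Z(t) G Z_h' V_h⁻¹`, not through X(t)
   alone. With the naive term the 68% band over-covered by ~3 points in
   model-faithful simulations.
2. **Variance-parameter uncertainty.** A Kackar–Harville-type delta-method
   term `∇_η ŷ · Cov(η̂) · ∇_η ŷ` accounts for estimation error in
   η = (log-Cholesky(Ψ), log σ²), with Cov(η̂) taken from the numerically
   differenced observed information at the optimum (pseudo-inverse restricted
   to the identified eigendirections, so weakly identified variance
   directions contribute nothing rather than exploding).

A Monte-Carlo interval mode (default 5,000 seeded draws of β-deviation,
random effects, and residual noise, propagated through the same adjusted
design) cross-checks the analytic bands. Intervals are for a new noisy
measurement by default; `include_residual=False` gives the noiseless latent
trajectory. Points and bands are truncated to [0, 57] as presentation-layer
clamping — the model itself is Gaussian on the raw scale.

Remaining limitation: these are plug-in frequentist intervals; the
correction terms are first-order, so a small residual coverage error of
order 1/√n_subjects persists (a fully Bayesian treatment would integrate
over the variance-parameter posterior instead).

## Cross-validated accuracy protocol

Fivefold cross-validation (folds stratified by baseline-ARAT stratum;
plain random folds available), repeated; fitting filters and pruning touch
training folds only. For each held-out subject the "6-month assessment" is
the last measurement in the 150–230-day window (real 26-week visits
jitter); conditioning on the first m = 1, 2, … measurements (never the
target itself), the absolute error of the predicted 6-month ARAT is
recorded. Summaries are box statistics with the whisker outlier rule:
quartiles by linear interpolation, values strictly outside
(Q1 − 1.5·IQR, Q3 + 1.5·IQR) removed and counted, remaining values
summarized. Removal is symmetric two-sided and precedes all reported
statistics; `n_removed` is always reported. Stratification uses baseline
bins 0–10 / 11–40 / 41–57 and last-observation windows
[0,7], (7,21], (21,42], (42,91], (91,182] days. Model comparison reuses
identical fold assignments across structures (paired design).

## Synthetic cohorts

No public serially-measured ARAT dataset exists, so the pipeline runs on
simulated cohorts in two modes.

**Realistic mode** emulates the published cohort's statistical structure;
it is calibrated, not fitted to any real data:

* Latent baseline ARAT from a two-component normal mixture — weights
  0.52/0.48, components N(−10, 6²) and N(30, 19²) — censored to [0, 57].
  The components correspond to the severe (floor) and moderate subgroups;
  defaults were set once by simulated-moment matching so first-assessment
  ARAT reproduces mean ≈ 14, SD ≈ 19, median ≈ 1, Q3 ≈ 29.
* Baseline FE (3 levels) and SA (6 levels) drawn conditionally on the
  mixture component, with conditional tables chosen so the marginals match
  the published 54/20/26% and 33/10/22/5/21/9% distributions while poor
  grades co-occur with low baselines.
* Recovery mean μ(t) = y0 + f·(57 − y0)·(1 − exp(−(t − t0)/τ)): exponential
  approach to ceiling after an onset delay t0 ~ U(2, 10) days. Favourable
  prognosis (FE ≥ 1): recovered fraction f ~ Beta(6, 2) (mean 0.75), τ ~
  U(20, 40) days. Unfavourable: f bimodal (65% mass near 0.05, else near
  0.5), τ ~ U(40, 80) — low-baseline patients may or may not recover.
* Observations: μ(t) plus a subject-level offset (SD 2) and visit noise
  (SD 3), both attenuated within ~10 points of the scale bounds (a patient
  at the floor scores 0 again), rounded and censored to [0, 57]. SA/FE
  grades ratchet upward as achieved recovery crosses fixed thresholds;
  FM-UE tracks a concave transform of μ(t) with a subject offset.
* Visit schedules: four templates mirroring the pooled study designs
  (weekly early visits + weeks 5/12/26; or days 2/5/9 + 6 months), mixed
  35/25/20/20%, with per-visit jitter and top-up visits in weeks 2–10 so
  the cohort visit-count distribution has median 6 and quartiles ≈ 4/8.
* Demographics per the published table: age N(64.8, 14²), 52% male,
  Bamford 48/34/18%, rt-PA 23%, NIHSS ≈ N(8, 5²) clipped to 0–42, etc.

What realistic mode does **not** emulate: treatment-arm effects, measurement
floor/ceiling psychometrics beyond simple censoring, missing visits
correlated with severity, or any neurophysiological markers. Passing tests
on it therefore demonstrate that the *pipeline* behaves as specified under
plausible data, not that the published clinical error levels are
reproduced — those depend on the unavailable patient data.

**Model-faithful mode** draws data exactly from a specified LMM (no
rounding or censoring) and stores the true random effects and noiseless
trajectories; it backs parameter-recovery and interval-coverage tests where
the estimand must be known exactly.

## Experiment design choices

* **Coverage experiment** (the t1/t2 reproduction quantities): truth
  parameters are the SAFE REML fit to one default realistic cohort
  (computed at run time); 5 replicates of (simulate 450 subjects → fit →
  440 new subjects with measurements at days 3/14/35 and a day-182 target)
  give 2,200 pooled prediction events. Replicate fits are pooled because a
  single fit leaves the coverage estimate dominated by one realization of
  the estimation error.
* **Recovery experiment** uses a random-intercept structure. This is
  deliberate: over realistic visit schedules the natural-spline
  random-effects columns are collinear (pairwise correlation ≥ 0.97), so
  pointwise entries of an unstructured spline-G are not estimable to tight
  relative error at n = 450 — only their predictive combination Z G Z' is,
  and that functional is what the coverage experiment exercises. Chasing
  20% errors on individually unidentified G entries would test sampling
  noise, not the estimator.
* **Problem sizes** in the test-suite (cohorts of 60–450, 2 CV repetitions,
  2,200 coverage events) are chosen as the smallest sizes at which the
  statistical assertions have comfortable Monte-Carlo margins.

## Numerical choices

* Log-Cholesky bounds: log-diagonal in ±8, off-diagonal in ±30; RSS floored
  at 1e-12 so perfect-fit degenerate data (σ² → 0) remain finite.
* Quantiles everywhere use the linear-interpolation convention
  ((k−1)/(n−1) plotting positions), matching the stated box-plot rule.
* Wald pruning: per-covariate joint χ² blocks (all interaction columns,
  then main columns if the interactions were dropped), iterated to
  convergence; an empty pruned model degrades to the time-only structure.
* Decliner rule: "beyond 7.25" read as strictly greater; drops are assessed
  between any earlier/later visit pair within the first 182 days.
* Seeds: every stochastic routine takes an explicit seed; pipeline stages
  derive named SHA-256 substreams (< 2³¹) from the single master seed.
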