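# dynarat

Dynamic, patient-specific prediction of upper-limb capacity recovery after
stroke.

Upper-limb capacity in the first six months post-stroke — measured with the
Action Research Arm Test (ARAT, integer 0–57) — recovers along highly
heterogeneous, nonlinear trajectories: some patients stay at the floor,
others reach the ceiling within weeks. Clinicians and trialists need a
forecast of an *individual* patient's 6-month capacity that can be updated
every time a new assessment arrives, at whatever irregular day it was
taken. `dynarat` is a tested Python implementation of that pipeline for
biostatisticians and rehabilitation researchers:

* **Recovery model** — linear mixed-effects models
  `y_i = X_i β + Z_i b_i + ε_i` with a natural-cubic-spline time course,
  candidate clinical covariates interacted with time, and subject-level
  random effects (`b_i ~ N(0, G)`, unstructured). Five fixed-effect
  structures are supported, from the full covariate model down to
  time-only; the final "SAFE" model uses shoulder abduction and finger
  extension, the two strongest early predictors. Fitting is profiled
  ML/REML over the log-Cholesky factor of `G/σ²` with analytic gradients.
* **Dynamic prediction** — the conditional (empirical-Bayes/BLUP)
  distribution of a subject's random effects given their partial history
  yields a personal trajectory with 68%/95% prediction intervals that
  narrow as measurements accrue.
* **Accuracy protocol** — repeated fivefold cross-validation of the
  absolute 6-month prediction error as a function of the number of
  conditioning measurements, with box-plot summaries under a whisker-based
  outlier-removal rule, stratified by baseline severity or time of last
  observation.
* **Synthetic cohorts** — since no public serially-measured ARAT dataset
  exists, a calibrated generator emulates a 450-patient acute-stroke
  cohort (floor-skewed baseline, prognosis-dependent exponential recovery
  to the ceiling, four visit-schedule designs), and a model-faithful mode
  draws data exactly from a known mixed model for recovery and coverage
  testing.

See `docs/methods.md` for the model, the generator's assumptions and the
design decisions.

## Worked example

```python
import numpy as np
from dynarat import (
    CohortConfig, generate_cohort, cohort_summary,
    fit_lmm, model_spec, predict_trajectory, crossvalidate, summarize_errors,
)

# a default synthetic cohort of 450 patients
cohort = generate_cohort(CohortConfig(n_subjects=450, seed=11))
s = cohort_summary(cohort)["baseline_arat"]
print(f"baseline ARAT mean {s['mean']:.1f}, SD {s['sd']:.1f}, median {s['median']:.0f}")

# fit the SAFE model and forecast one patient from their first two visits
fitted = fit_lmm(cohort, model_spec("model4_safe"))
sid = cohort.subject_ids[0]
history = cohort.subject_measurements(sid).iloc[:2]
pred = predict_trajectory(fitted, history, grid=np.arange(0, 183, 7),
                          covariates=cohort.subject_covariates(sid))
lo, hi = pred.band95
print(f"day-182 prediction {pred.point[-1]:.1f} ARAT points "
      f"(95% band {lo[-1]:.1f}-{hi[-1]:.1f})")
```

```
baseline ARAT mean 14.8, SD 18.8, median 2
day-182 prediction 3.5 ARAT points (95% band 0.0-12.6)
```

The cohort reproduces the severity profile of an acute stroke population
(mean baseline ARAT ~15 but median ~2: half the patients start near the
floor). The forecast patient scored 0 at both early visits with no
voluntary finger extension — an unfavourable prognosis — so the model
predicts little recovery, with a band acknowledging that some such
patients do improve. Each added measurement narrows the forecast, which
the cross-validated 6-month error quantifies:

```python
rec = crossvalidate(cohort, model_spec("model4_safe"), k=5, repetitions=1, seed=1)
print(summarize_errors(rec, group_by="m")[["m", "median", "q1", "q3"]].head(5))
```

```
   m    median        q1         q3
0  1  6.528087  2.601406  15.988547
1  2  4.726678  1.919815  12.631898
2  3  3.149213  1.259329   9.064657
3  4  2.638891  1.160153   7.107057
4  5  1.816651  0.842817   4.398682
```

The median absolute error of the 6-month forecast drops from ~6.5 ARAT
points with a single early measurement to ~1.8 with five, mirroring the
clinical value of serial assessment.

A CLI mirrors the library: `dynarat simulate | fit | predict | cv |
compare | summarize | run` (see `dynarat --help`). `predict` reads a
fitted-model JSON and a patient history CSV and writes the per-day
trajectory with both interval bands — the same text-file contract a
bedside tool would consume.

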