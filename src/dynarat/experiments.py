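"""Study-level experiment protocols: generator calibration readouts,
interval-coverage simulations and parameter recovery.

These functions wire the library modules into the reproducible experiments
the test-suite and the reproduction script both run; each takes a master
seed and derives named substreams so the protocols are independently
replayable.
"""

from __future__ import annotations

import numpy as np

from .cohort import (
    CohortConfig,
    ScheduleMix,
    generate_cohort,
    generate_model_faithful,
)
from .design import ModelSpec, model_spec
from .lmm import fit_lmm
from .pipeline import substream
from .prediction import predict_trajectory

__all__ = [
    "calibration_summary",
    "safe_truth_parameters",
    "coverage_experiment",
    "recovery_experiment",
    "PROBE_SCHEDULE",
]

#: deterministic probe design: three early measurements (weeks ~0-5) and the
#: 6-month assessment at day 182
PROBE_SCHEDULE = ScheduleMix(
    templates={"probe": (3, 14, 35, 182)},
    weights={"probe": 1.0},
    jitter_sd=0.0,
    jitter_rel=0.0,
    target_visit_probs=None,
)


def calibration_summary(seed: int, n_seeds: int = 20, n_subjects: int = 450) -> dict:
    """Baseline descriptives of default realistic cohorts, averaged over
    ``n_seeds`` independent seeds (grand means over subjects and seeds;
    the median is the across-seed median of per-seed medians)."""
    means, sds, medians, q3s, visit_medians = [], [], [], [], []
    fe_none, ages, male = [], [], []
    for i in range(n_seeds):
        cfg = CohortConfig(n_subjects=n_subjects, seed=substream(seed, f"calib{i}"))
        cohort = generate_cohort(cfg)
        base = cohort.baseline()
        arat0 = base["arat"].astype(float)
        means.append(arat0.mean())
        sds.append(arat0.std(ddof=1))
        medians.append(arat0.median())
        q3s.append(arat0.quantile(0.75))
        counts = cohort.measurements.groupby("subject_id").size()
        visit_medians.append(counts.median())
        fe_none.append((base["fe"] == 0).mean())
        ages.append(cohort.covariates["age"].mean())
        male.append((cohort.covariates["sex"] == "male").mean())
    return {
        "baseline_arat_mean": float(np.mean(means)),
        "baseline_arat_sd": float(np.mean(sds)),
        "baseline_arat_median": float(np.median(medians)),
        "baseline_arat_q3": float(np.mean(q3s)),
        "visits_median": float(np.median(visit_medians)),
        "fe_none_pct": float(100 * np.mean(fe_none)),
        "age_mean": float(np.mean(ages)),
        "male_pct": float(100 * np.mean(male)),
        "n_seeds": n_seeds,
        "n_subjects": n_subjects,
    }


def safe_truth_parameters(seed: int):
    """SAFE-structure truth for model-faithful simulations: the SAFE model
    fitted by REML to one default realistic cohort supplies a realistic
    (beta, G, sigma^2) triple."""
    cohort = generate_cohort(CohortConfig(seed=substream(seed, "truth-cohort")))
    spec = model_spec("model4_safe")
    fitted = fit_lmm(cohort, spec, method="REML")
    return fitted.beta_, fitted.G_, fitted.sigma2_, spec


def coverage_experiment(
    seed: int,
    n_train: int = 450,
    n_replicates: int = 5,
    events_per_replicate: int = 440,
    n_condition: int = 3,
    spec: ModelSpec | None = None,
    truth=None,
) -> dict:
    """Empirical coverage of the analytic 68%/95% prediction bands.

    Per replicate: simulate a training cohort of ``n_train`` subjects
    exactly from the SAFE-structure truth, fit it by REML, then for new
    simulated subjects with ``n_condition`` early measurements compute the
    analytic prediction interval of their day-182 measurement and record
    whether it covers.  Percentages pool all replicates (>= 2000 events at
    the defaults).
    """
    if truth is None:
        beta_t, G_t, s2_t, spec = safe_truth_parameters(seed)
    else:
        beta_t, G_t, s2_t = truth
        assert spec is not None
    hits68 = hits95 = n = 0
    for rep in range(n_replicates):
        train = generate_model_faithful(
            beta_t, G_t, s2_t, spec, n_subjects=n_train,
            seed=substream(seed, f"cov-train{rep}"),
        )
        fitted = fit_lmm(train, spec, method="REML")
        new = generate_model_faithful(
            beta_t, G_t, s2_t, spec, n_subjects=events_per_replicate,
            seed=substream(seed, f"cov-events{rep}"), schedule_mix=PROBE_SCHEDULE,
        )
        cov_by = new.covariates.set_index("subject_id")
        for sid, meas in new.measurements.groupby("subject_id"):
            meas = meas.sort_values("t_days")
            hist = meas.iloc[:n_condition]
            target = meas.iloc[n_condition]
            pred = predict_trajectory(
                fitted, hist, [float(target["t_days"])], clamp=False,
                covariates=cov_by.loc[sid],
            )
            y = float(target["arat"])
            lo68, hi68 = pred.band68
            lo95, hi95 = pred.band95
            hits68 += lo68[0] <= y <= hi68[0]
            hits95 += lo95[0] <= y <= hi95[0]
            n += 1
    return {
        "coverage68_pct": 100.0 * hits68 / n,
        "coverage95_pct": 100.0 * hits95 / n,
        "n_events": n,
        "n_replicates": n_replicates,
    }


def recovery_experiment(seed: int, n_subjects: int = 450,
                        spec: ModelSpec | None = None, truth=None) -> dict:
    """Parameter recovery on one model-faithful cohort: z-scores of the
    fixed effects against truth and relative errors of sigma^2 and the
    diagonal of G.

    The default structure uses a random intercept: with realistic visit
    schedules the natural-spline random-effects columns are strongly
    collinear, so pointwise entries of an unstructured spline-G are not
    estimable to tight relative error at this sample size (their predictive
    combination Z G Z' is — that is what the coverage experiment exercises).
    """
    if spec is None:
        from .splines import Knots

        spec = model_spec(
            "model5_time",
            time_knots=Knots(internal=(14.0, 42.0), boundary=(0.0, 200.0)),
            re_knots=None,
        )
    if truth is None:
        beta_t = np.array([12.0, 20.0, 8.0, 5.0])
        G_t = np.array([[36.0]])
        s2_t = 9.0
    else:
        beta_t, G_t, s2_t = truth
    cohort = generate_model_faithful(
        beta_t, G_t, s2_t, spec, n_subjects=n_subjects,
        seed=substream(seed, "recovery"),
    )
    fitted = fit_lmm(cohort, spec, method="REML")
    se = np.sqrt(np.diag(fitted.cov_beta_))
    z = (fitted.beta_ - beta_t) / se
    g_rel = np.abs(np.diag(fitted.G_) - np.diag(G_t)) / np.diag(G_t)
    return {
        "max_abs_beta_z": float(np.abs(z).max()),
        "sigma2_rel_error": float(abs(fitted.sigma2_ - s2_t) / s2_t),
        "max_G_diag_rel_error": float(g_rel.max()),
        "converged": bool(fitted.converged_),
        "n_subjects": n_subjects,
    }
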