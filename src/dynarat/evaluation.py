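"""Cross-validated accuracy protocol for the recovery models.

Fivefold cross-validation, repeated: subjects are partitioned into folds
(stratified by baseline-ARAT stratum by default), the model is fitted on
four folds — with the fitting-set and decliner filters applied to the
training data only — and every held-out subject's 6-month ARAT is predicted
incrementally, conditioning on their first ``m = 1, 2, ...`` measurements.
The error is the absolute difference between predicted and observed ARAT at
the subject's 6-month assessment (the last measurement falling in the
150–230-day window), which is never part of the conditioning set.

Error distributions are summarized as box statistics with the whisker-based
outlier rule: values strictly outside ``(Q1 - 1.5 IQR, Q3 + 1.5 IQR)`` are
removed and reported as outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .design import ModelSpec
from .lmm import filter_decliners, filter_fitting_set, fit_lmm, fit_pruned
from .prediction import predict_trajectory

__all__ = [
    "BoxStats",
    "crossvalidate",
    "summarize_errors",
    "stratify_by_baseline",
    "errors_by_last_observation_time",
    "compare_models",
    "DEFAULT_BASELINE_BINS",
    "DEFAULT_TIME_WINDOWS",
]

logger = logging.getLogger(__name__)

SIX_MONTH_WINDOW = (150.0, 230.0)
DEFAULT_BASELINE_BINS = ((0, 10, "low"), (11, 40, "medium"), (41, 57, "high"))
DEFAULT_TIME_WINDOWS = ((0, 7), (7, 21), (21, 42), (42, 91), (91, 182))

RECORD_COLUMNS = [
    "repetition", "fold", "subject_id", "m", "t_last", "baseline_arat",
    "t_target", "observed", "predicted", "abs_error", "converged",
]


@dataclass(frozen=True)
class BoxStats:
    """Box-plot summary with the whisker outlier rule applied.

    Quartiles and whiskers come from the full input; ``median`` (and the
    other remainder statistics) are computed after removing values strictly
    outside the whiskers.
    """

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    mean: float
    n_removed: int
    n_used: int

    @classmethod
    def from_values(cls, values) -> "BoxStats":
        x = np.asarray(values, dtype=float)
        x = x[~np.isnan(x)]
        if x.size == 0:
            raise ValueError("no values to summarize")
        q1, q3 = float(np.quantile(x, 0.25)), float(np.quantile(x, 0.75))
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        keep = x[(x >= lo) & (x <= hi)]
        return cls(
            median=float(np.median(keep)),
            q1=q1,
            q3=q3,
            whisker_low=lo,
            whisker_high=hi,
            mean=float(keep.mean()),
            n_removed=int(x.size - keep.size),
            n_used=int(keep.size),
        )


def assign_folds(cohort: Cohort, k: int, rng: np.random.Generator,
                 stratify: bool = True) -> dict:
    """Random fold assignment (subject_id -> fold), optionally stratified by
    baseline-ARAT stratum so each fold sees the full severity spectrum."""
    base = cohort.baseline().set_index("subject_id")["arat"]
    ids = np.asarray(cohort.subject_ids)
    folds: dict = {}
    if stratify:
        strata = {}
        for sid in ids:
            label = _baseline_stratum(float(base[sid]), DEFAULT_BASELINE_BINS)
            strata.setdefault(label, []).append(sid)
        groups = [np.asarray(v) for _, v in sorted(strata.items())]
    else:
        groups = [ids]
    offset = 0
    for g in groups:
        g = g[rng.permutation(g.size)]
        for j, sid in enumerate(g):
            folds[sid] = (j + offset) % k
        offset += g.size  # stagger so small strata spread evenly
    return folds


def _baseline_stratum(value: float, bins) -> str:
    """Assign by upper bin edges; continuous (model-faithful) baselines that
    fall between the integer bins, or outside the scale, go to the nearest
    bin."""
    ordered = sorted(bins)
    for _, hi, label in ordered[:-1]:
        if value <= hi:
            return label
    return ordered[-1][2]


def _six_month_assessment(meas: pd.DataFrame, window=SIX_MONTH_WINDOW):
    inwin = meas[(meas["t_days"] >= window[0]) & (meas["t_days"] <= window[1])]
    if inwin.empty:
        return None
    return inwin.sort_values("t_days").iloc[-1]


def fit_for_training(train: Cohort, spec: ModelSpec, method: str = "REML"):
    """Apply the fitting-set filters to the training cohort and fit.

    Pruned structures (model2/model3) run their backward elimination here;
    the pruning itself only ever sees training data.
    """
    included, _ = filter_fitting_set(train)
    retained, _ = filter_decliners(included)
    if retained.n_subjects == 0:
        raise ValueError("no training subjects survive the fitting filters")
    if spec.id == "model2":
        return fit_pruned(retained, spec, stage="interactions_only", method=method)
    if spec.id == "model3":
        return fit_pruned(retained, spec, stage="mains_and_interactions", method=method)
    return fit_lmm(retained, spec, method=method)


def crossvalidate(
    cohort: Cohort,
    spec: ModelSpec,
    k: int = 5,
    repetitions: int = 10,
    seed: int = 0,
    method: str = "REML",
    stratify: bool = True,
    fold_assignments: list | None = None,
    max_m: int | None = None,
) -> pd.DataFrame:
    """Repeated k-fold incremental-measurement cross-validation.

    Returns one record per (repetition, subject, number of conditioning
    measurements m): the absolute error of the predicted 6-month ARAT.
    Subjects without a 6-month assessment are skipped and counted in a log
    message.  ``fold_assignments`` (one dict per repetition) lets callers
    reuse identical folds across model structures for paired comparison.
    """
    rng = np.random.default_rng(seed)
    if fold_assignments is None:
        fold_assignments = [
            assign_folds(cohort, k, rng, stratify=stratify) for _ in range(repetitions)
        ]
    if len(fold_assignments) != repetitions:
        raise ValueError("need one fold assignment per repetition")

    cov_by_id = cohort.covariates.set_index("subject_id")
    records = []
    n_skipped = 0
    for rep, folds in enumerate(fold_assignments):
        for fold in range(k):
            test_ids = [sid for sid, f in folds.items() if f == fold]
            train_ids = [sid for sid, f in folds.items() if f != fold]
            fitted = fit_for_training(cohort.subset(train_ids), spec, method=method)
            for sid in sorted(test_ids):
                meas = cohort.subject_measurements(sid).sort_values("t_days")
                target = _six_month_assessment(meas)
                if target is None:
                    n_skipped += 1
                    logger.warning("subject %s has no 6-month assessment; skipped", sid)
                    continue
                t_target = float(target["t_days"])
                observed = float(target["arat"])
                conditioning = meas[meas["t_days"] < t_target]
                M = len(conditioning)
                if M == 0:
                    n_skipped += 1
                    logger.warning("subject %s has no pre-6-month measurements", sid)
                    continue
                if max_m is not None:
                    M = min(M, max_m)
                baseline_arat = float(meas.iloc[0]["arat"])
                cov = cov_by_id.loc[sid]
                for m in range(1, M + 1):
                    history = conditioning.iloc[:m]
                    pred = predict_trajectory(
                        fitted, history, [t_target], levels=(), clamp=True,
                        covariates=cov,
                    )
                    predicted = float(pred.point[0])
                    records.append(
                        (
                            rep, fold, sid, m, float(history["t_days"].max()),
                            baseline_arat, t_target, observed, predicted,
                            abs(predicted - observed), bool(fitted.converged_),
                        )
                    )
    if n_skipped:
        logger.info("%d subject-instances skipped (no usable 6-month assessment)", n_skipped)
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def summarize_errors(records: pd.DataFrame, group_by: str = "m",
                     value_col: str = "abs_error") -> pd.DataFrame:
    """Box statistics of the absolute errors per group (outliers removed by
    the whisker rule).  ``group_by`` is any record column (``m``,
    ``baseline_stratum``, ``t_last_window``...)."""
    rows = []
    for key, grp in records.groupby(group_by, sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        if vals.size == 0:  # pragma: no cover
            logger.warning("empty group %r omitted", key)
            continue
        bs = BoxStats.from_values(vals)
        rows.append({group_by: key, **bs.__dict__})
    return pd.DataFrame(rows)


def stratify_by_baseline(records: pd.DataFrame,
                         bins=DEFAULT_BASELINE_BINS) -> pd.DataFrame:
    """Label records low/medium/high by the subject's baseline ARAT.

    ``bins`` are inclusive (lo, hi, label) integer ranges that must cover
    0–57 without overlap.
    """
    edges = sorted((lo, hi) for lo, hi, _ in bins)
    for (lo1, hi1), (lo2, hi2) in zip(edges, edges[1:]):
        if lo2 <= hi1:
            raise ValueError("baseline bins overlap")
    covered = set()
    for lo, hi, _ in bins:
        covered.update(range(int(lo), int(hi) + 1))
    if not covered.issuperset(range(58)):
        raise ValueError("baseline bins must cover 0..57")
    out = records.copy()
    out["baseline_stratum"] = [
        _baseline_stratum(v, bins) for v in records["baseline_arat"]
    ]
    return out


def errors_by_last_observation_time(records: pd.DataFrame,
                                    windows=DEFAULT_TIME_WINDOWS) -> pd.DataFrame:
    """Box statistics grouped by the day of the last conditioning
    measurement, in half-open windows ``(lo, hi]`` (the first window is
    closed at 0).  A record outside every window is assigned to the nearest
    one and logged."""
    windows = sorted(tuple(w) for w in windows)
    for (a1, b1), (a2, b2) in zip(windows, windows[1:]):
        if a2 < b1:
            raise ValueError("time windows overlap")

    def label(t: float) -> str:
        for lo, hi in windows:
            if (t > lo or (lo == windows[0][0] and t >= lo)) and t <= hi:
                return f"({lo},{hi}]"
        # outside all windows: snap to nearest
        logger.warning("t_last=%s outside all windows; assigned to nearest", t)
        dists = [min(abs(t - lo), abs(t - hi)) for lo, hi in windows]
        lo, hi = windows[int(np.argmin(dists))]
        return f"({lo},{hi}]"

    out = records.copy()
    out["t_last_window"] = [label(float(t)) for t in records["t_last"]]
    summary = summarize_errors(out, group_by="t_last_window")
    order = {f"({lo},{hi}]": i for i, (lo, hi) in enumerate(windows)}
    return summary.sort_values(by="t_last_window", key=lambda s: s.map(order)).reset_index(drop=True)


def compare_models(
    cohort: Cohort,
    specs,
    k: int = 5,
    repetitions: int = 1,
    seed: int = 0,
    method: str = "REML",
    max_m: int | None = 1,
) -> pd.DataFrame:
    """Paired model comparison: identical fold assignments for every spec,
    mean and median absolute 6-month error using the first measurement
    (``m = 1``) as the predictor."""
    rng = np.random.default_rng(seed)
    fold_assignments = [assign_folds(cohort, k, rng) for _ in range(repetitions)]
    rows = []
    for spec in specs:
        rec = crossvalidate(
            cohort, spec, k=k, repetitions=repetitions, seed=seed,
            method=method, fold_assignments=fold_assignments, max_m=max_m,
        )
        first = rec[rec["m"] == 1]
        converged = first[first["converged"]]
        if len(converged) < len(first):
            logger.warning(
                "%s: %d of %d first-measurement predictions came from "
                "non-converged folds; means use converged folds only",
                spec.id, len(first) - len(converged), len(first),
            )
        use = converged if len(converged) else first
        rows.append(
            {
                "model": spec.id,
                "mean_abs_error_m1": float(use["abs_error"].mean()),
                "median_abs_error_m1": float(use["abs_error"].median()),
                "n_predictions": int(len(use)),
                "all_folds_converged": bool(first["converged"].all()),
            }
        )
    return pd.DataFrame(rows)
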