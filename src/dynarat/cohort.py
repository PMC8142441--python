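"""Synthetic stroke cohorts for the upper-limb recovery pipeline.

No public dataset with serially measured ARAT exists, so the pipeline is
exercised on simulated cohorts in two modes:

``realistic``
    Emulates the statistical structure of a pooled acute-stroke cohort:
    a floor-skewed baseline ARAT (many patients start at 0–1), prognosis
    strata driven by early voluntary finger extension, heterogeneous
    nonlinear recovery towards the 0–57 ceiling, irregular visit schedules
    drawn from four study designs, and co-evolving clinical covariates
    (shoulder abduction, finger extension, FM-UE).

``model_faithful``
    Draws data *exactly* from a specified linear mixed-effects model
    (no rounding, no censoring) and stores each subject's true random
    effects — the harness for parameter-recovery and interval-coverage
    tests.

The recovery mechanism in realistic mode is an exponential approach to
ceiling: ``mu(t) = y0 + f * (57 - y0) * (1 - exp(-(t - t0)/tau))`` with a
prognosis-stratified recovered fraction ``f``, time constant ``tau`` (days)
and onset delay ``t0``.  Patients with voluntary finger extension mostly
recover a large fraction of their deficit quickly; patients without it
either show little recovery or a delayed partial recovery (bimodal ``f``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ScheduleMix",
    "BaselineMixture",
    "RecoveryParams",
    "Demographics",
    "CohortConfig",
    "Cohort",
    "ConfigError",
    "generate_cohort",
    "generate_model_faithful",
    "sample_schedule",
    "cohort_summary",
]

ARAT_MAX = 57
FMUE_MAX = 66


class ConfigError(ValueError):
    """Invalid cohort configuration (bad probabilities, negative SDs...)."""


def _check_probs(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ConfigError(f"{name} must be non-negative and sum to 1, got {p}")
    return p / p.sum()


@dataclass(frozen=True)
class ScheduleMix:
    """Visit-schedule templates (days post-stroke) and their mixing weights.

    The four templates mirror the measurement designs of the pooled studies:
    weekly early visits plus weeks 5/12/26, or a few very early visits plus
    a 6-month follow-up.  ``target_visit_probs`` optionally tops subjects up
    with extra visits (uniform in ``topup_window`` days) so the cohort-level
    visit-count distribution has median 6 and quartiles 4/8.
    """

    templates: dict = field(
        default_factory=lambda: {
            "explicit": (7, 14, 21, 35, 84, 182),
            "epos": (2, 5, 9, 182),
            "fourd_eeg": (5, 35, 84, 182),
            "explore": (5, 35, 84, 182),
        }
    )
    weights: dict = field(
        default_factory=lambda: {
            "explicit": 0.35,
            "epos": 0.25,
            "fourd_eeg": 0.20,
            "explore": 0.20,
        }
    )
    jitter_sd: float = 1.0  # absolute visit-time jitter, days
    jitter_rel: float = 0.04  # relative jitter, fraction of the nominal day
    target_visit_probs: dict | None = field(
        default_factory=lambda: {4: 0.40, 5: 0.05, 6: 0.18, 7: 0.08, 8: 0.16, 9: 0.08, 10: 0.05}
    )
    topup_window: tuple[float, float] = (14.0, 70.0)

    def validate(self) -> None:
        if not self.templates:
            raise ConfigError("templates must be non-empty")
        if set(self.templates) != set(self.weights):
            raise ConfigError("templates and weights must have identical keys")
        _check_probs(list(self.weights.values()), "schedule weights")
        if self.jitter_sd < 0 or self.jitter_rel < 0:
            raise ConfigError("jitter SDs must be >= 0")
        if self.target_visit_probs is not None:
            _check_probs(list(self.target_visit_probs.values()), "target_visit_probs")


@dataclass(frozen=True)
class BaselineMixture:
    """Two-component normal mixture for the latent baseline ARAT, censored
    to [0, 57].  Defaults were calibrated by simulated-moment matching so the
    generated first-assessment ARAT has mean ~14, SD ~19, median ~1, Q3 ~29."""

    weights: tuple[float, ...] = (0.52, 0.48)
    means: tuple[float, ...] = (-10.0, 30.0)
    sds: tuple[float, ...] = (6.0, 19.0)

    def validate(self) -> None:
        _check_probs(self.weights, "baseline mixture weights")
        if len(self.means) != len(self.weights) or len(self.sds) != len(self.weights):
            raise ConfigError("mixture weights/means/sds lengths differ")
        if any(s < 0 for s in self.sds):
            raise ConfigError("mixture SDs must be >= 0")


@dataclass(frozen=True)
class RecoveryParams:
    """Prognosis-stratified recovery dynamics.

    Favourable stratum (voluntary finger extension present): recovered
    fraction ``f ~ Beta(fav_f_a, fav_f_b)`` (mean 0.75), time constant
    ``tau ~ U(20, 40)`` days.  Unfavourable stratum: ``f`` bimodal — with
    probability ``unfav_low_mass`` near 0.05, otherwise near 0.5 — and a
    slower ``tau ~ U(40, 80)`` days.  Recovery starts after an onset delay
    drawn uniformly from ``onset_delay`` days.
    """

    fav_f_a: float = 6.0
    fav_f_b: float = 2.0
    fav_tau: tuple[float, float] = (20.0, 40.0)
    unfav_low_mass: float = 0.65
    unfav_f_low: tuple[float, float] = (2.0, 38.0)  # Beta params, mean ~0.05
    unfav_f_high: tuple[float, float] = (10.0, 10.0)  # Beta params, mean 0.5
    unfav_tau: tuple[float, float] = (40.0, 80.0)
    onset_delay: tuple[float, float] = (2.0, 10.0)
    subject_sd: float = 2.0  # subject-level vertical perturbation, ARAT points

    def validate(self) -> None:
        if not 0 <= self.unfav_low_mass <= 1:
            raise ConfigError("unfav_low_mass must be in [0, 1]")
        if self.subject_sd < 0:
            raise ConfigError("subject_sd must be >= 0")


@dataclass(frozen=True)
class Demographics:
    """Baseline demographic and clinical covariate distributions.

    ``fe_probs_by_component`` / ``sa_probs_by_component`` condition the
    finger-extension (0/1/2) and shoulder-abduction (0–5) categories on the
    baseline-mixture component, so that poor-prognosis categories co-occur
    with the low-baseline component while the cohort-level marginals match
    the published descriptives (FE none/partial/full 54/20/26%; SA levels
    33/10/22/5/21/9%).
    """

    age_mean: float = 64.8
    age_sd: float = 14.0
    prop_male: float = 0.52
    fe_probs_by_component: tuple = ((0.92, 0.06, 0.02), (0.128, 0.352, 0.520))
    sa_probs_by_component: tuple = (
        (0.58, 0.14, 0.20, 0.03, 0.04, 0.01),
        (0.059, 0.057, 0.242, 0.072, 0.393, 0.177),
    )
    bamford_probs: tuple[float, ...] = (0.48, 0.34, 0.18)  # LACI, PACI, TACI
    rtpa_prob: float = 0.23
    nihss_mean: float = 8.0
    nihss_sd: float = 5.0
    nihss8_probs: tuple[float, ...] = (0.445, 0.416, 0.139)  # sensory: normal/reduced/absent
    nihss11_probs: tuple[float, ...] = (0.62, 0.17, 0.21)  # extinction/inattention
    neglect_prob: float = 0.37
    affected_right_prob: float = 0.39
    dominant_right_prob: float = 0.92

    def validate(self) -> None:
        for name, p in [
            ("bamford_probs", self.bamford_probs),
            ("nihss8_probs", self.nihss8_probs),
            ("nihss11_probs", self.nihss11_probs),
        ]:
            _check_probs(p, name)
        for comp_p in self.fe_probs_by_component:
            _check_probs(comp_p, "fe_probs_by_component")
        for comp_p in self.sa_probs_by_component:
            _check_probs(comp_p, "sa_probs_by_component")
        for name, pr in [
            ("prop_male", self.prop_male),
            ("rtpa_prob", self.rtpa_prob),
            ("neglect_prob", self.neglect_prob),
            ("affected_right_prob", self.affected_right_prob),
            ("dominant_right_prob", self.dominant_right_prob),
        ]:
            if not 0 <= pr <= 1:
                raise ConfigError(f"{name} must be a probability, got {pr}")
        if self.age_sd < 0 or self.nihss_sd < 0:
            raise ConfigError("SDs must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 450
    mode: str = "realistic"
    seed: int = 0
    baseline_mixture: BaselineMixture = field(default_factory=BaselineMixture)
    recovery_params: RecoveryParams = field(default_factory=RecoveryParams)
    schedule_mix: ScheduleMix = field(default_factory=ScheduleMix)
    residual_sd: float = 3.0
    demographics: Demographics = field(default_factory=Demographics)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.mode not in ("realistic", "model_faithful"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.residual_sd < 0:
            raise ConfigError("residual_sd must be >= 0")
        self.baseline_mixture.validate()
        self.recovery_params.validate()
        self.schedule_mix.validate()
        self.demographics.validate()

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


BAMFORD_LEVELS = ("LACI", "PACI", "TACI")

MEASUREMENT_COLUMNS = ["subject_id", "t_days", "arat", "sa", "fe", "fmue"]
COVARIATE_COLUMNS = [
    "subject_id", "age", "sex", "affected_side", "dominant_side", "bamford",
    "rtpa", "nihss", "nihss_item8", "nihss_item11", "neglect", "cohort_design",
]


@dataclass
class Cohort:
    """Long-format cohort: one measurements row per visit, one covariates row
    per subject; ``truth`` holds the true random effects in model-faithful
    mode."""

    measurements: pd.DataFrame
    covariates: pd.DataFrame
    truth: pd.DataFrame | None = None

    @property
    def subject_ids(self) -> list:
        return list(self.covariates["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    def subject_measurements(self, subject_id) -> pd.DataFrame:
        return self.measurements[self.measurements["subject_id"] == subject_id]

    def subject_covariates(self, subject_id) -> pd.Series:
        rows = self.covariates[self.covariates["subject_id"] == subject_id]
        if rows.empty:
            raise KeyError(f"unknown subject {subject_id!r}")
        return rows.iloc[0]

    def subset(self, subject_ids) -> "Cohort":
        ids = set(subject_ids)
        meas = self.measurements[self.measurements["subject_id"].isin(ids)]
        cov = self.covariates[self.covariates["subject_id"].isin(ids)]
        truth = None
        if self.truth is not None:
            truth = self.truth[self.truth["subject_id"].isin(ids)].reset_index(drop=True)
        return Cohort(meas.reset_index(drop=True), cov.reset_index(drop=True), truth)

    def baseline(self) -> pd.DataFrame:
        """First measurement per subject, in subject order."""
        return (
            self.measurements.sort_values(["subject_id", "t_days"])
            .groupby("subject_id", sort=False)
            .first()
            .reset_index()
        )

    def validate(self) -> None:
        meas, cov = self.measurements, self.covariates
        if meas.empty or cov.empty:
            raise ConfigError("cohort must be non-empty")
        if not set(meas["subject_id"]).issubset(set(cov["subject_id"])):
            raise ConfigError("measurements reference unknown subjects")
        if ((meas["arat"] < 0) | (meas["arat"] > ARAT_MAX)).any():
            raise ConfigError("ARAT values outside [0, 57]")
        for sid, grp in meas.groupby("subject_id"):
            t = grp["t_days"].to_numpy()
            if not (np.diff(t) > 0).all():
                raise ConfigError(f"non-increasing times for subject {sid}")


def sample_schedule(schedule_mix: ScheduleMix, rng: np.random.Generator) -> np.ndarray:
    """Draw one subject's visit days: template choice, per-visit jitter,
    optional top-up visits, clipped to >= 1 day and strictly increasing."""
    return _sample_schedule_named(schedule_mix, rng)[1]


def _sample_schedule_named(
    schedule_mix: ScheduleMix, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    names = sorted(schedule_mix.templates)
    weights = np.asarray([schedule_mix.weights[n] for n in names], dtype=float)
    weights = weights / weights.sum()
    name = names[rng.choice(len(names), p=weights)]
    days = np.asarray(schedule_mix.templates[name], dtype=float)
    sd = schedule_mix.jitter_sd + schedule_mix.jitter_rel * days
    days = days + rng.normal(0.0, 1.0, size=days.size) * sd
    if schedule_mix.target_visit_probs is not None:
        counts = sorted(schedule_mix.target_visit_probs)
        probs = _check_probs(
            [schedule_mix.target_visit_probs[c] for c in counts], "target_visit_probs"
        )
        target = counts[rng.choice(len(counts), p=probs)]
        n_extra = max(0, target - days.size)
        if n_extra:
            lo, hi = schedule_mix.topup_window
            days = np.concatenate([days, rng.uniform(lo, hi, size=n_extra)])
    days = np.unique(np.maximum(np.round(days), 1.0).astype(int))
    return name, days


def _mean_trajectory(t, y0, f, tau, t0):
    t = np.asarray(t, dtype=float)
    return y0 + f * (ARAT_MAX - y0) * (1.0 - np.exp(-np.maximum(t - t0, 0.0) / tau))


# recovery (mu(t) - y0) thresholds that pull the FE / SA grades up over time
_FE_DELTA_THRESHOLDS = (15.0, 30.0)
_SA_DELTA_THRESHOLDS = (8.0, 16.0, 24.0, 32.0, 40.0)


def _edge_scale(mu: np.ndarray) -> np.ndarray:
    """Noise attenuation near the ARAT floor and ceiling: a patient scoring
    0 scores 0 again, so measurement scatter shrinks towards the bounds."""
    return np.clip(np.minimum(mu, ARAT_MAX - mu) / 10.0, 0.05, 1.0)


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a realistic-mode synthetic cohort.

    Per subject: a latent baseline is drawn from the censored two-component
    mixture; finger-extension and shoulder-abduction baseline grades are
    drawn conditionally on the mixture component; the prognosis stratum
    (favourable iff FE >= 1) selects the recovered-fraction and
    time-constant distributions; visits come from a sampled schedule
    template; ARAT observations are the mean trajectory plus subject- and
    visit-level noise, rounded and censored to [0, 57]; SA/FE/FM-UE
    co-evolve monotonically with the mean trajectory.
    """
    if config is None:
        config = CohortConfig()
    config.validate()
    if config.mode != "realistic":
        raise ConfigError("generate_cohort handles mode='realistic' only")
    rng = np.random.default_rng(config.seed)
    mix, rec, demo = config.baseline_mixture, config.recovery_params, config.demographics

    meas_rows, cov_rows = [], []
    mix_w = _check_probs(mix.weights, "baseline mixture weights")
    for i in range(config.n_subjects):
        sid = f"S{i + 1:04d}"
        comp = int(rng.choice(len(mix_w), p=mix_w))
        y0 = float(np.clip(rng.normal(mix.means[comp], mix.sds[comp]), 0, ARAT_MAX))
        fe0 = int(rng.choice(3, p=_check_probs(demo.fe_probs_by_component[comp], "fe")))
        sa0 = int(rng.choice(6, p=_check_probs(demo.sa_probs_by_component[comp], "sa")))
        favourable = fe0 >= 1
        if favourable:
            f = float(rng.beta(rec.fav_f_a, rec.fav_f_b))
            tau = float(rng.uniform(*rec.fav_tau))
        else:
            if rng.random() < rec.unfav_low_mass:
                f = float(rng.beta(*rec.unfav_f_low))
            else:
                f = float(rng.beta(*rec.unfav_f_high))
            tau = float(rng.uniform(*rec.unfav_tau))
        t0 = float(rng.uniform(*rec.onset_delay))
        u_subj = float(rng.normal(0.0, rec.subject_sd))
        fm_offset = float(rng.normal(0.0, 4.0))

        design, days = _sample_schedule_named(config.schedule_mix, rng)
        mu = _mean_trajectory(days, y0, f, tau, t0)
        scale = _edge_scale(mu)
        noise = scale * (u_subj + rng.normal(0.0, config.residual_sd, size=days.size))
        arat = np.clip(np.round(mu + noise), 0, ARAT_MAX).astype(int)
        delta = mu - y0  # recovery achieved so far drives the grade evolution
        fe_gain = np.searchsorted(_FE_DELTA_THRESHOLDS, delta, side="right")
        fe = np.maximum.accumulate(np.maximum(fe0, fe_gain)).astype(int)
        sa_gain = np.searchsorted(_SA_DELTA_THRESHOLDS, delta, side="right")
        sa = np.minimum(np.maximum.accumulate(sa0 + sa_gain), 5).astype(int)
        fm_latent = FMUE_MAX * (mu / ARAT_MAX) ** 0.75
        fmue = np.clip(
            np.round(fm_latent + fm_offset + rng.normal(0.0, 2.0, size=days.size)),
            0, FMUE_MAX,
        ).astype(int)
        for j, day in enumerate(days):
            meas_rows.append((sid, int(day), int(arat[j]), int(sa[j]), int(fe[j]), int(fmue[j])))

        cov_rows.append(
            (
                sid,
                float(np.clip(rng.normal(demo.age_mean, demo.age_sd), 18, 100)),
                "male" if rng.random() < demo.prop_male else "female",
                "right" if rng.random() < demo.affected_right_prob else "left",
                "right" if rng.random() < demo.dominant_right_prob else "left",
                BAMFORD_LEVELS[int(rng.choice(3, p=_check_probs(demo.bamford_probs, "bamford")))],
                bool(rng.random() < demo.rtpa_prob),
                int(np.clip(np.round(rng.normal(demo.nihss_mean, demo.nihss_sd)), 0, 42)),
                int(rng.choice(3, p=_check_probs(demo.nihss8_probs, "nihss8"))),
                int(rng.choice(3, p=_check_probs(demo.nihss11_probs, "nihss11"))),
                bool(rng.random() < demo.neglect_prob),
                design,
            )
        )

    measurements = pd.DataFrame(meas_rows, columns=MEASUREMENT_COLUMNS)
    covariates = pd.DataFrame(cov_rows, columns=COVARIATE_COLUMNS)
    return Cohort(measurements, covariates)


def generate_model_faithful(
    beta,
    G,
    sigma2: float,
    spec,
    n_subjects: int = 450,
    seed: int = 0,
    schedule_mix: ScheduleMix | None = None,
    demographics: Demographics | None = None,
) -> Cohort:
    """Draw a cohort exactly from the LMM ``y_i = X_i beta + Z_i b_i + eps_i``.

    ``spec`` is a :class:`~dynarat.design.ModelSpec`; covariates needed by the
    spec (SA/FE grades) are drawn from the demographic marginals and held
    constant within subject.  No rounding or censoring is applied.  The true
    random-effect vectors are stored in ``cohort.truth`` and the noiseless
    values in a ``mu`` column of ``cohort.measurements``.
    """
    from .design import build_subject_design  # local import: avoids cycle

    beta = np.asarray(beta, dtype=float)
    G = np.asarray(G, dtype=float)
    if not np.allclose(G, G.T):
        raise ConfigError("G must be symmetric")
    eigmin = float(np.linalg.eigvalsh(G).min()) if G.size else 0.0
    if eigmin < -1e-10 * max(1.0, abs(G).max()):
        raise ConfigError("G must be positive semi-definite")
    if sigma2 < 0:
        raise ConfigError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    if schedule_mix is None:
        schedule_mix = ScheduleMix()
    if demographics is None:
        demographics = Demographics()

    q = G.shape[0]
    if q != spec.n_random:
        raise ConfigError(f"G is {q}x{q} but spec has {spec.n_random} random effects")
    if beta.size != spec.n_fixed:
        raise ConfigError(f"beta has {beta.size} entries but spec has {spec.n_fixed}")
    G_chol = _psd_cholesky(G)
    fe_marg = _component_marginal(demographics.fe_probs_by_component)
    sa_marg = _component_marginal(demographics.sa_probs_by_component)

    meas_rows, cov_rows, truth_rows = [], [], []
    for i in range(n_subjects):
        sid = f"S{i + 1:04d}"
        fe0 = int(rng.choice(3, p=fe_marg))
        sa0 = int(rng.choice(6, p=sa_marg))
        days = sample_schedule(schedule_mix, rng)
        cov = {
            "subject_id": sid,
            "age": float(rng.normal(demographics.age_mean, demographics.age_sd)),
            "sex": "male" if rng.random() < demographics.prop_male else "female",
            "affected_side": "right" if rng.random() < demographics.affected_right_prob else "left",
            "dominant_side": "right" if rng.random() < demographics.dominant_right_prob else "left",
            "bamford": BAMFORD_LEVELS[int(rng.choice(3, p=_check_probs(demographics.bamford_probs, "bamford")))],
            "rtpa": bool(rng.random() < demographics.rtpa_prob),
            "nihss": int(np.clip(np.round(rng.normal(demographics.nihss_mean, demographics.nihss_sd)), 0, 42)),
            "nihss_item8": int(rng.choice(3, p=_check_probs(demographics.nihss8_probs, "n8"))),
            "nihss_item11": int(rng.choice(3, p=_check_probs(demographics.nihss11_probs, "n11"))),
            "neglect": bool(rng.random() < demographics.neglect_prob),
            "cohort_design": "model_faithful",
        }
        meas = pd.DataFrame(
            {
                "subject_id": sid,
                "t_days": days.astype(int),
                "arat": 0.0,
                "sa": np.full(days.size, sa0, dtype=int),
                "fe": np.full(days.size, fe0, dtype=int),
                "fmue": np.nan,
            }
        )
        X, Z = build_subject_design(meas, pd.Series(cov), spec)
        b = G_chol @ rng.normal(size=q) if q else np.zeros(0)
        mu = X @ beta + (Z @ b if q else 0.0)
        y = mu + rng.normal(0.0, np.sqrt(sigma2), size=days.size)
        for j, day in enumerate(days):
            meas_rows.append(
                {
                    "subject_id": sid,
                    "t_days": int(day),
                    "arat": float(y[j]),
                    "sa": sa0,
                    "fe": fe0,
                    "fmue": np.nan,
                    "mu": float(mu[j]),
                }
            )
        cov_rows.append(cov)
        truth_rows.append({"subject_id": sid, **{f"b{k}": float(b[k]) for k in range(q)}})

    measurements = pd.DataFrame(meas_rows)
    covariates = pd.DataFrame(cov_rows, columns=COVARIATE_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return Cohort(measurements, covariates, truth)


def _psd_cholesky(G: np.ndarray) -> np.ndarray:
    """Cholesky-like factor valid for singular PSD matrices."""
    if G.size == 0:
        return G
    try:
        return np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(G)
        w = np.clip(w, 0.0, None)
        return V @ np.diag(np.sqrt(w))


def _component_marginal(probs_by_component, weights=(0.52, 0.48)) -> np.ndarray:
    p = np.zeros(len(probs_by_component[0]))
    for w, comp in zip(weights, probs_by_component):
        p += w * np.asarray(comp, dtype=float)
    return p / p.sum()


def cohort_summary(cohort: Cohort) -> dict:
    """Baseline descriptives mirroring a patient-characteristics table.

    Returns means/SDs/quartiles of first-assessment ARAT, age and FM-UE,
    category proportions for sex, FE, SA and Bamford, and visit-count
    quartiles.  Proportions within each categorical sum to 1.
    """
    if cohort.covariates.empty:
        raise ConfigError("empty cohort")
    base = cohort.baseline()
    cov = cohort.covariates
    counts = cohort.measurements.groupby("subject_id").size()

    def _props(series, levels):
        vc = series.value_counts(normalize=True)
        return {lvl: float(vc.get(lvl, 0.0)) for lvl in levels}

    arat0 = base["arat"].astype(float)
    return {
        "n_subjects": cohort.n_subjects,
        "baseline_arat": {
            "mean": float(arat0.mean()),
            "sd": float(arat0.std(ddof=1)) if len(arat0) > 1 else 0.0,
            "q1": float(arat0.quantile(0.25)),
            "median": float(arat0.median()),
            "q3": float(arat0.quantile(0.75)),
        },
        "age": {"mean": float(cov["age"].mean()),
                "sd": float(cov["age"].std(ddof=1)) if len(cov) > 1 else 0.0},
        "baseline_fmue": {
            "mean": float(base["fmue"].mean()),
            "sd": float(base["fmue"].std(ddof=1)) if len(base) > 1 else 0.0,
        },
        "sex": _props(cov["sex"], ["male", "female"]),
        "baseline_fe": _props(base["fe"], [0, 1, 2]),
        "baseline_sa": _props(base["sa"], list(range(6))),
        "bamford": _props(cov["bamford"], list(BAMFORD_LEVELS)),
        "visits": {
            "q1": float(counts.quantile(0.25)),
            "median": float(counts.median()),
            "q3": float(counts.quantile(0.75)),
        },
    }
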