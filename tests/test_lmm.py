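"""Mixed-model estimation: closed-form oracles, reference-implementation
parity, degenerate limits, filters and significance pruning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dynarat.cohort import Cohort, generate_model_faithful
from dynarat.design import ModelSpec, build_design, model_spec
from dynarat.lmm import (
    filter_decliners,
    filter_fitting_set,
    fit_lmm,
    fit_pruned,
    marginal_loglik,
    prune_by_significance,
)
from dynarat.splines import Knots


def _balanced_random_intercept_cohort(n_subj=20, times=(10, 20, 30, 40, 50),
                                      g=16.0, sigma2=4.0, seed=0):
    """Balanced one-way layout: fixed time means plus subject intercepts."""
    rng = np.random.default_rng(seed)
    rows = []
    mu_t = {t: 5.0 + 0.2 * t for t in times}
    for i in range(n_subj):
        b = rng.normal(0, np.sqrt(g))
        for t in times:
            y = mu_t[t] + b + rng.normal(0, np.sqrt(sigma2))
            rows.append((f"s{i:02d}", t, y, 0, 0, np.nan))
    meas = pd.DataFrame(rows, columns=["subject_id", "t_days", "arat", "sa", "fe", "fmue"])
    cov = pd.DataFrame({"subject_id": sorted(meas["subject_id"].unique())})
    return Cohort(meas, cov)


@pytest.fixture(scope="module")
def intercept_spec():
    """Random intercept only; the 3-knot spline saturates the 5 time points
    so the fixed effects absorb the time means exactly."""
    return model_spec(
        "model5_time",
        time_knots=Knots(internal=(20.0, 30.0, 40.0), boundary=(10.0, 50.0)),
        re_knots=None,
    )


class TestClosedFormOracle:
    def test_reml_matches_balanced_anova_estimators(self, intercept_spec):
        """On a balanced one-way design the REML variance components have
        closed forms: sigma^2 = interaction mean square, g = (MSB - MSE)/J."""
        cohort = _balanced_random_intercept_cohort(seed=3)
        fitted = fit_lmm(cohort, intercept_spec, method="REML", tol=1e-12)
        y = (
            cohort.measurements.pivot(index="subject_id", columns="t_days", values="arat")
            .to_numpy()
        )
        I, J = y.shape
        resid = y - y.mean(1, keepdims=True) - y.mean(0, keepdims=True) + y.mean()
        mse = (resid**2).sum() / ((I - 1) * (J - 1))
        msb = J * ((y.mean(1) - y.mean()) ** 2).sum() / (I - 1)
        assert fitted.sigma2_ == pytest.approx(mse, abs=1e-6)
        assert fitted.G_[0, 0] == pytest.approx((msb - mse) / J, abs=1e-6)

    def test_fit_is_invariant_to_subject_order(self, intercept_spec):
        cohort = _balanced_random_intercept_cohort(seed=4)
        shuffled = Cohort(
            cohort.measurements.sample(frac=1.0, random_state=1).reset_index(drop=True),
            cohort.covariates.sample(frac=1.0, random_state=2).reset_index(drop=True),
        )
        f1 = fit_lmm(cohort, intercept_spec)
        f2 = fit_lmm(shuffled, intercept_spec)
        assert f1.loglik_ == pytest.approx(f2.loglik_, abs=1e-6)
        assert np.allclose(f1.beta_, f2.beta_, atol=1e-6)


class TestMarginalLoglik:
    def test_single_observation_zero_G_is_univariate_normal(self, intercept_spec):
        meas = pd.DataFrame(
            {"subject_id": ["a"], "t_days": [25.0], "arat": [17.0],
             "sa": [0], "fe": [0], "fmue": [np.nan]}
        )
        cohort = Cohort(meas, pd.DataFrame({"subject_id": ["a"]}))
        beta = np.array([10.0, 2.0, 1.0, 0.5, 0.2])
        dm = build_design(cohort, intercept_spec)
        mean = float((dm.X @ beta).item())
        ll = marginal_loglik(beta, np.zeros((1, 1)), 4.0, cohort, intercept_spec)
        assert ll == pytest.approx(stats.norm.logpdf(17.0, mean, 2.0), abs=1e-10)

    def test_matches_dense_stacked_multivariate_normal(self, tiny_spec, tiny_truth):
        """Three-subject toy: per-subject decomposition equals one dense
        block-diagonal multivariate normal evaluation."""
        beta, G, sigma2 = tiny_truth
        cohort = generate_model_faithful(beta, G, sigma2, tiny_spec, n_subjects=3, seed=12)
        ll = marginal_loglik(beta, G, sigma2, cohort, tiny_spec, method="ML")
        dm = build_design(cohort, tiny_spec)
        n = dm.y.size
        V = np.zeros((n, n))
        for gi in np.unique(dm.groups):
            m = dm.groups == gi
            V[np.ix_(m, m)] = dm.Z[m] @ G @ dm.Z[m].T + sigma2 * np.eye(m.sum())
        dense = stats.multivariate_normal.logpdf(dm.y, mean=dm.X @ beta, cov=V)
        assert ll == pytest.approx(dense, abs=1e-8)

    def test_location_invariance(self, tiny_spec, tiny_truth):
        beta, G, sigma2 = tiny_truth
        cohort = generate_model_faithful(beta, G, sigma2, tiny_spec, n_subjects=4, seed=13)
        ll0 = marginal_loglik(beta, G, sigma2, cohort, tiny_spec)
        shifted = Cohort(
            cohort.measurements.assign(arat=cohort.measurements["arat"] + 100.0),
            cohort.covariates,
            cohort.truth,
        )
        beta_shift = beta.copy()
        beta_shift[0] += 100.0
        assert marginal_loglik(beta_shift, G, sigma2, shifted, tiny_spec) == pytest.approx(
            ll0, abs=1e-8
        )

    def test_profiled_optimum_consistent_with_direct_evaluation(self, faithful_fit, faithful_cohort):
        ll = marginal_loglik(
            faithful_fit.beta_, faithful_fit.G_, faithful_fit.sigma2_,
            faithful_cohort, faithful_fit.spec_, method="REML",
        )
        assert ll == pytest.approx(faithful_fit.loglik_, abs=1e-6)


class TestReferenceParity:
    def test_agrees_with_statsmodels_mixedlm(self, intercept_spec):
        """Random-intercept REML fit agrees with statsmodels MixedLM to
        4 significant figures in loglik, beta, sigma^2 and G."""
        mlm = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        cohort = _balanced_random_intercept_cohort(n_subj=25, seed=7)
        ours = fit_lmm(cohort, intercept_spec, method="REML", tol=1e-12)
        dm = build_design(cohort, intercept_spec)
        ref = mlm.MixedLM(dm.y, dm.X, groups=dm.groups).fit(reml=True)
        assert ours.loglik_ == pytest.approx(ref.llf, rel=1e-4)
        assert np.allclose(ours.beta_, ref.fe_params, rtol=1e-4)
        assert ours.sigma2_ == pytest.approx(ref.scale, rel=1e-4)
        # statsmodels cov_re is on the outcome scale (already includes scale)
        assert ours.G_[0, 0] == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), rel=1e-3)


class TestDegenerateLimits:
    def test_zero_noise_recovers_ols(self, tiny_spec, tiny_truth):
        beta, G, _ = tiny_truth
        cohort = generate_model_faithful(
            beta, np.zeros_like(G), 0.0, tiny_spec, n_subjects=30, seed=6
        )
        fitted = fit_lmm(cohort, tiny_spec)
        dm = build_design(cohort, tiny_spec)
        ols = np.linalg.lstsq(dm.X, dm.y, rcond=None)[0]
        assert np.allclose(fitted.beta_, ols, atol=1e-6)
        assert fitted.sigma2_ < 1e-6

    def test_ml_loglik_nested_specs_ordered(self, small_realistic_cohort):
        """The SAFE model nests the time-only model, so its ML likelihood
        cannot be lower."""
        f_safe = fit_lmm(small_realistic_cohort, model_spec("model4_safe"), method="ML")
        f_time = fit_lmm(small_realistic_cohort, model_spec("model5_time"), method="ML")
        assert f_safe.loglik_ >= f_time.loglik_ - 1e-6


class TestRecoverySmoke:
    def test_parameters_recovered_at_moderate_n(self, faithful_fit, tiny_truth, tiny_spec):
        """Fixed effects, sigma^2 and the *predictive* random-effect
        variance are recovered.  Individual entries of a spline-basis G are
        strongly collinear and not pointwise estimable at this n, so the
        identifiable functional Z G Z' + sigma^2 is checked instead."""
        from dynarat.splines import ns_eval

        beta, G, sigma2 = tiny_truth
        se = np.sqrt(np.diag(faithful_fit.cov_beta_))
        assert np.all(np.abs(faithful_fit.beta_ - beta) < 4 * se)
        assert faithful_fit.sigma2_ == pytest.approx(sigma2, rel=0.35)
        for t in (30.0, 84.0, 182.0):
            z = np.concatenate([[1.0], ns_eval([t], tiny_spec.re_knots)[0]])
            v_true = float(z @ G @ z) + sigma2
            v_fit = float(z @ faithful_fit.G_ @ z) + faithful_fit.sigma2_
            assert v_fit == pytest.approx(v_true, rel=0.4)
        assert faithful_fit.converged_


class TestFilters:
    def _cohort_from_visits(self, visits: dict, fmue: dict | None = None):
        rows = []
        for sid, days in visits.items():
            fm = (fmue or {}).get(sid, [np.nan] * len(days))
            for t, f in zip(days, fm):
                rows.append((sid, t, 10, 0, 0, f))
        meas = pd.DataFrame(rows, columns=["subject_id", "t_days", "arat", "sa", "fe", "fmue"])
        cov = pd.DataFrame({"subject_id": sorted(visits)})
        return Cohort(meas, cov)

    def test_fitting_set_rule(self):
        cohort = self._cohort_from_visits(
            {"in": [3, 10, 90], "short": [3, 10, 80], "few": [3, 185]}
        )
        included, excluded = filter_fitting_set(cohort)
        assert included.subject_ids == ["in"]  # 87-day span, 3 visits
        assert sorted(excluded.subject_ids) == ["few", "short"]

    def test_decliner_rule_strict_threshold(self):
        cohort = self._cohort_from_visits(
            {"drop10": [5, 40], "edge": [5, 40], "up": [5, 40]},
            fmue={"drop10": [40, 30], "edge": [40, 32.75], "up": [20, 30]},
        )
        retained, declined = filter_decliners(cohort)
        assert declined.subject_ids == ["drop10"]  # drop of 10 > 7.25
        assert sorted(retained.subject_ids) == ["edge", "up"]  # 7.25 exactly retained

    def test_decline_after_six_months_ignored(self):
        cohort = self._cohort_from_visits(
            {"late": [5, 40, 250]}, fmue={"late": [40, 42, 20]}
        )
        retained, declined = filter_decliners(cohort)
        assert retained.subject_ids == ["late"]


@pytest.fixture(scope="module")
def pruning_spec():
    return ModelSpec(
        id="custom",
        covariates=(("fe", "main+time_interaction"),),
        time_knots=Knots(internal=(30.0,), boundary=(0.0, 200.0)),
        re_knots=None,
    )


class TestPruning:
    def test_alpha_one_keeps_spec_unchanged(self, faithful_cohort, tiny_spec):
        spec = tiny_spec.with_(covariates=(("fe", "main+time_interaction"),))
        fitted = fit_lmm(faithful_cohort, spec, method="ML")
        assert prune_by_significance(fitted, "mains_and_interactions", alpha=1.0).covariates == spec.covariates

    def test_strong_interaction_retained(self, pruning_spec):
        """A large FE-by-time effect survives pruning in almost every
        simulation."""
        p = pruning_spec.n_fixed
        beta = np.zeros(p)
        beta[0], beta[1] = 5.0, 10.0
        beta[-2:] = [25.0, 30.0]  # fe interactions with the spline of time
        kept = 0
        n_sim = 20
        for s in range(n_sim):
            cohort = generate_model_faithful(
                beta, np.array([[9.0]]), 9.0, pruning_spec, n_subjects=60, seed=100 + s
            )
            fitted = fit_pruned(cohort, pruning_spec, stage="interactions_only", method="ML")
            if any(role == "main+time_interaction" for _, role in fitted.spec_.covariates):
                kept += 1
        assert kept >= n_sim - 1

    def test_null_effect_pruned_at_nominal_rate(self, pruning_spec):
        """With no covariate effect the interaction block survives at about
        the nominal alpha level."""
        p = pruning_spec.n_fixed
        beta = np.zeros(p)
        beta[0], beta[1] = 5.0, 10.0  # time trend only, fe irrelevant
        kept = 0
        n_sim = 40
        for s in range(n_sim):
            cohort = generate_model_faithful(
                beta, np.array([[9.0]]), 9.0, pruning_spec, n_subjects=60, seed=500 + s
            )
            fitted = fit_lmm(cohort, pruning_spec, method="ML")
            reduced = prune_by_significance(fitted, "interactions_only", alpha=0.05)
            if any(role == "main+time_interaction" for _, role in reduced.covariates):
                kept += 1
        # binomial(40, 0.05): >= 9 retentions has probability < 1e-4
        assert kept <= 8

    def test_empty_model_after_pruning_is_time_only(self, pruning_spec):
        beta = np.zeros(pruning_spec.n_fixed)
        beta[0], beta[1] = 5.0, 10.0
        cohort = generate_model_faithful(
            beta, np.array([[9.0]]), 9.0, pruning_spec, n_subjects=80, seed=9
        )
        fitted = fit_pruned(cohort, pruning_spec, stage="mains_and_interactions", method="ML")
        assert fitted.spec_.covariates == ()
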