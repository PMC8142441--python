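"""Dynamic prediction: conditional-normal identities, interval semantics,
Monte-Carlo agreement, sequential updating and clamping."""

import numpy as np
import pandas as pd
import pytest

from dynarat.cohort import generate_model_faithful
from dynarat.design import model_spec
from dynarat.lmm import ArmRecoveryModel
from dynarat.prediction import (
    posterior_random_effects,
    predict_trajectory,
    update_prediction,
)
from dynarat.splines import Knots, ns_eval


def make_fitted(spec, beta, G, sigma2, cov_beta=None):
    """Assemble a fitted-model object directly from known parameters."""
    m = ArmRecoveryModel(spec=spec)
    m.spec_ = spec
    m.beta_ = np.asarray(beta, dtype=float)
    m.G_ = np.asarray(G, dtype=float)
    m.sigma2_ = float(sigma2)
    p = m.beta_.size
    m.cov_beta_ = np.zeros((p, p)) if cov_beta is None else np.asarray(cov_beta)
    m.converged_ = True
    return m


@pytest.fixture
def intercept_model():
    """Random-intercept model with known parameters."""
    spec = model_spec(
        "model5_time",
        time_knots=Knots(internal=(30.0,), boundary=(0.0, 200.0)),
        re_knots=None,
    )
    beta = np.array([10.0, 15.0, 4.0])
    return make_fitted(spec, beta, [[25.0]], 9.0)


def hist_frame(times, values, sa=1, fe=1):
    return pd.DataFrame(
        {"t_days": times, "arat": values, "sa": sa, "fe": fe, "fmue": np.nan}
    )


class TestPosterior:
    def test_empty_history_returns_prior(self, intercept_model):
        post = posterior_random_effects(intercept_model, None)
        assert np.allclose(post.mean, 0.0)
        assert np.allclose(post.cov, intercept_model.G_)

    def test_scalar_shrinkage_closed_form(self, intercept_model):
        """One observation, random intercept: the conditional mean is the
        classic shrinkage g/(g+sigma^2) times the residual."""
        t, y = 40.0, 30.0
        x = np.concatenate([[1.0], ns_eval([t], intercept_model.spec_.time_knots)[0]])
        resid = y - float(x @ intercept_model.beta_)
        g, s2 = 25.0, 9.0
        post = posterior_random_effects(intercept_model, hist_frame([t], [y]))
        assert post.mean[0] == pytest.approx(g / (g + s2) * resid, abs=1e-10)
        assert post.cov[0, 0] == pytest.approx(g - g**2 / (g + s2), abs=1e-10)

    def test_information_never_increases_covariance(self, faithful_fit, faithful_cohort):
        """Appending an observation shrinks the conditional covariance in
        the Loewner order."""
        rng = np.random.default_rng(2)
        ids = rng.choice(faithful_cohort.subject_ids, size=5, replace=False)
        for sid in ids:
            meas = faithful_cohort.subject_measurements(sid).sort_values("t_days")
            if len(meas) < 3:
                continue
            before = posterior_random_effects(faithful_fit, meas.iloc[:2])
            after = posterior_random_effects(faithful_fit, meas.iloc[:3])
            diff = before.cov - after.cov
            assert np.linalg.eigvalsh(diff).min() > -1e-8


class TestIntervals:
    def test_zero_level_band_is_point(self, intercept_model):
        pred = predict_trajectory(
            intercept_model, hist_frame([10.0], [12.0]), [30.0, 90.0], levels=(0.0,)
        )
        lo, hi = pred.band(0.0)
        assert np.allclose(lo, pred.point) and np.allclose(hi, pred.point)

    def test_bands_nested_and_ordered(self, intercept_model):
        pred = predict_trajectory(
            intercept_model, hist_frame([10.0], [12.0]), np.arange(0, 183, 14.0)
        )
        lo68, hi68 = pred.band68
        lo95, hi95 = pred.band95
        assert np.all(lo95 <= lo68) and np.all(hi68 <= hi95)
        assert np.all(lo68 <= pred.point) and np.all(pred.point <= hi68)

    def test_monte_carlo_agrees_with_analytic(self, intercept_model):
        hist = hist_frame([5.0, 30.0], [10.0, 20.0])
        grid = [90.0, 182.0]
        kw = dict(clamp=False, include_variance_uncertainty=False)
        analytic = predict_trajectory(intercept_model, hist, grid, **kw)
        mc = predict_trajectory(
            intercept_model, hist, grid, interval_mode="monte_carlo",
            n_draws=20000, seed=11, **kw,
        )
        width = analytic.band95[1] - analytic.band95[0]
        for band in (0.68, 0.95):
            for side in (0, 1):
                assert np.allclose(
                    analytic.bands[band][side], mc.bands[band][side],
                    atol=0.02 * width.max(),
                )

    def test_clamping_contract(self, intercept_model):
        """A prediction exceeding the scale maximum is reported at 57."""
        high = make_fitted(intercept_model.spec_, [80.0, 0.0, 0.0], [[25.0]], 9.0)
        pred = predict_trajectory(high, None, [10.0], clamp=True)
        assert pred.point[0] == 57.0
        assert pred.band95[1][0] == 57.0
        unclamped = predict_trajectory(high, None, [10.0], clamp=False)
        assert unclamped.point[0] == pytest.approx(80.0 * 1.0, abs=20)

    def test_latent_band_narrower_than_measurement_band(self, intercept_model):
        hist = hist_frame([10.0], [12.0])
        meas = predict_trajectory(intercept_model, hist, [100.0], clamp=False)
        latent = predict_trajectory(
            intercept_model, hist, [100.0], clamp=False, include_residual=False
        )
        assert (latent.band95[1] - latent.band95[0])[0] < (
            meas.band95[1] - meas.band95[0]
        )[0]

    def test_unknown_level_rejected(self, intercept_model):
        with pytest.raises(ValueError):
            predict_trajectory(intercept_model, None, [10.0], levels=(1.5,))


class TestUpdating:
    def test_sequential_equals_batch(self, intercept_model):
        hist = hist_frame([5.0, 20.0], [8.0, 14.0])
        new = {"t_days": 60.0, "arat": 25.0, "sa": 1, "fe": 1, "fmue": np.nan}
        grid = np.arange(0.0, 183.0, 7.0)
        seq = update_prediction(intercept_model, hist, new, grid, clamp=False)
        batch = predict_trajectory(
            intercept_model,
            pd.concat([hist, pd.DataFrame([new])], ignore_index=True),
            grid, clamp=False,
        )
        assert np.allclose(seq.point, batch.point, atol=1e-10)
        assert np.allclose(seq.band95[0], batch.band95[0], atol=1e-10)

    def test_confirming_measurement_narrows_band_keeps_point(self, intercept_model):
        hist = hist_frame([5.0, 20.0], [8.0, 14.0])
        t_star = 100.0
        before = predict_trajectory(intercept_model, hist, [t_star], clamp=False)
        new = {"t_days": t_star, "arat": float(before.point[0]), "sa": 1, "fe": 1,
               "fmue": np.nan}
        after = predict_trajectory(
            intercept_model,
            pd.concat([hist, pd.DataFrame([new])], ignore_index=True),
            [t_star], clamp=False,
        )
        assert after.point[0] == pytest.approx(before.point[0], abs=1e-8)
        assert (after.band95[1] - after.band95[0])[0] < (
            before.band95[1] - before.band95[0]
        )[0]

    def test_out_of_order_measurement_rejected(self, intercept_model):
        hist = hist_frame([5.0, 20.0], [8.0, 14.0])
        new = {"t_days": 10.0, "arat": 9.0, "sa": 1, "fe": 1, "fmue": np.nan}
        with pytest.raises(ValueError):
            update_prediction(intercept_model, hist, new, [100.0])

    def test_band_width_shrinks_with_more_measurements(
        self, faithful_fit, faithful_cohort
    ):
        """Average day-182 95%-band width is non-increasing in the number of
        conditioning measurements."""
        widths = {m: [] for m in (1, 2, 3)}
        for sid in faithful_cohort.subject_ids[:25]:
            meas = faithful_cohort.subject_measurements(sid).sort_values("t_days")
            if len(meas) < 3:
                continue
            for m in widths:
                pred = predict_trajectory(
                    faithful_fit, meas.iloc[:m], [182.0], clamp=False
                )
                widths[m].append((pred.band95[1] - pred.band95[0])[0])
        means = [np.mean(widths[m]) for m in (1, 2, 3)]
        assert means[0] >= means[1] >= means[2]


class TestInterpolationLimit:
    def test_tiny_noise_interpolates_history(self, tiny_spec, tiny_truth):
        """As sigma^2 -> 0 the subject-specific prediction passes through
        the observed measurements."""
        beta, G, _ = tiny_truth
        sigma2 = 1e-6
        cohort = generate_model_faithful(beta, G, sigma2, tiny_spec, n_subjects=5, seed=3)
        fitted = make_fitted(tiny_spec, beta, G, sigma2)
        sid = cohort.subject_ids[0]
        meas = cohort.subject_measurements(sid).sort_values("t_days")
        pred = predict_trajectory(
            fitted, meas.iloc[:3], meas["t_days"].to_numpy()[:3], clamp=False
        )
        assert np.allclose(pred.point, meas["arat"].to_numpy()[:3], atol=1e-2)
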