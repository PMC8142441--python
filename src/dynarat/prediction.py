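"""Dynamic subject-specific prediction from a fitted recovery model.

Given a fitted mixed model and a subject's partial measurement history, the
random effects have a closed-form conditional (empirical-Bayes) distribution:
with ``V_h = Z_h G Z_h' + sigma^2 I`` built from the history,

    b_hat   = G Z_h' V_h^{-1} (y_h - X_h beta)
    Sigma_b = G - G Z_h' V_h^{-1} Z_h G.

The predicted trajectory is ``X(t) beta + Z(t) b_hat`` with prediction
intervals for a *new noisy measurement*: variance
``Z(t) Sigma_b Z(t)' + sigma^2`` plus (by default) the fixed-effect
estimation uncertainty ``X(t) Cov(beta_hat) X(t)'``.  Each new measurement
tightens the conditional distribution, so the bands shrink as data accrue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ARAT_MAX
from .design import DataError, build_subject_design
from .lmm import _theta_to_lambda

__all__ = [
    "PosteriorRE",
    "SubjectPrediction",
    "posterior_random_effects",
    "predict_trajectory",
    "update_prediction",
]


@dataclass
class PosteriorRE:
    """Conditional distribution of one subject's random effects."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)


@dataclass
class SubjectPrediction:
    """Predicted trajectory on a time grid with central prediction bands."""

    grid: np.ndarray
    point: np.ndarray
    bands: dict  # level -> (lower, upper) arrays
    history_used: pd.DataFrame
    clamped: bool

    def band(self, level: float):
        return self.bands[level]

    @property
    def band68(self):
        return self.bands[0.68]

    @property
    def band95(self):
        return self.bands[0.95]

    def to_frame(self) -> pd.DataFrame:
        out = {"t_days": self.grid, "point": self.point}
        for level in sorted(self.bands):
            lo, hi = self.bands[level]
            pct = int(round(level * 100))
            out[f"lo{pct}"] = lo
            out[f"hi{pct}"] = hi
        return pd.DataFrame(out)


def _history_frame(history) -> pd.DataFrame:
    if history is None:
        return pd.DataFrame(columns=["t_days", "arat", "sa", "fe", "fmue"])
    if isinstance(history, pd.DataFrame):
        return history.sort_values("t_days").reset_index(drop=True)
    raise DataError("history must be a measurements DataFrame")


def _conditional(fitted, hist: pd.DataFrame, covariates=None):
    """Conditional moments of the random effects plus the conditioning
    matrices (``X_h``, ``Z_h`` and the Cholesky factor of ``V_h``)."""
    G = fitted.G_
    if hist.empty:
        return PosteriorRE(np.zeros(G.shape[0]), G.copy()), None, None, None
    X_h, Z_h = build_subject_design(hist, covariates, fitted.spec_)
    y_h = hist["arat"].to_numpy(dtype=float)
    V_h = Z_h @ G @ Z_h.T + fitted.sigma2_ * np.eye(len(hist))
    try:
        cf = np.linalg.cholesky(V_h)
    except np.linalg.LinAlgError as exc:
        raise DataError("singular conditioning covariance V_h") from exc

    def vinv(B):
        return np.linalg.solve(cf.T, np.linalg.solve(cf, B))

    resid = y_h - X_h @ fitted.beta_
    GZt = G @ Z_h.T
    mean = GZt @ vinv(resid)
    cov = G - GZt @ vinv(Z_h @ G)
    cov = 0.5 * (cov + cov.T)
    return PosteriorRE(mean=mean, cov=cov), X_h, Z_h, cf


def posterior_random_effects(fitted, history, covariates=None) -> PosteriorRE:
    """Empirical-Bayes conditional distribution of the random effects.

    With an empty history this returns the prior ``N(0, G)``; otherwise the
    conditional-normal identities above.  ``covariates`` is the subject's
    baseline covariate row (needed only for specs with baseline covariates).
    """
    hist = _history_frame(history)
    post, *_ = _conditional(fitted, hist, covariates)
    return post


def _grid_frame(hist: pd.DataFrame, grid: np.ndarray, policy: str,
                covariates=None) -> pd.DataFrame:
    """Measurement-like frame at the grid times, with time-varying covariate
    values resolved per the covariate policy (carried from the history)."""
    if not hist.empty:
        src = hist.iloc[0] if policy == "baseline" else hist.iloc[-1]
        sa, fe, fmue = src.get("sa"), src.get("fe"), src.get("fmue")
    elif covariates is not None:
        sa = covariates.get("sa", np.nan)
        fe = covariates.get("fe", np.nan)
        fmue = covariates.get("fmue", np.nan)
    else:
        sa = fe = fmue = np.nan
    return pd.DataFrame(
        {"t_days": grid, "arat": np.nan, "sa": sa, "fe": fe, "fmue": fmue}
    )


def _point_at_params(beta, G, sigma2, X_g, Z_g, X_h, Z_h, y_h) -> np.ndarray:
    """Point prediction recomputed at alternative variance parameters."""
    V = Z_h @ G @ Z_h.T + sigma2 * np.eye(len(y_h))
    cf = np.linalg.cholesky(V)
    b = G @ Z_h.T @ np.linalg.solve(cf.T, np.linalg.solve(cf, y_h - X_h @ beta))
    return X_g @ beta + Z_g @ b


def _variance_uncertainty_term(fitted, X_g, Z_g, X_h, Z_h, y_h) -> np.ndarray:
    """Kackar-Harville-style inflation: variance contributed by estimation
    error in the variance parameters ``eta = (theta, log sigma^2)``, via the
    delta method on the point predictor (whose shrinkage depends on G and
    sigma^2)."""
    cov_eta = getattr(fitted, "cov_eta_", None)
    theta = getattr(fitted, "theta_", None)
    if cov_eta is None or theta is None or not np.any(cov_eta):
        return np.zeros(X_g.shape[0])
    eta = np.concatenate([theta, [np.log(fitted.sigma2_)]])
    k = eta.size
    q = fitted.G_.shape[0]
    grads = np.zeros((k, X_g.shape[0]))
    h = 1e-4 * (1.0 + np.abs(eta))
    for j in range(k):
        pts = []
        for sign in (+1.0, -1.0):
            e = eta.copy()
            e[j] += sign * h[j]
            s2 = float(np.exp(e[-1]))
            L = _theta_to_lambda(e[:-1], q)
            G = s2 * (L @ L.T)
            pts.append(_point_at_params(fitted.beta_, G, s2, X_g, Z_g, X_h, Z_h, y_h))
        grads[j] = (pts[0] - pts[1]) / (2 * h[j])
    return np.einsum("ji,jk,ki->i", grads, cov_eta, grads)


def predict_trajectory(
    fitted,
    history,
    grid,
    levels=(0.68, 0.95),
    interval_mode: str = "analytic",
    clamp: bool = True,
    covariates=None,
    include_fixed_uncertainty: bool = True,
    include_variance_uncertainty: bool = True,
    include_residual: bool = True,
    n_draws: int = 5000,
    seed: int = 0,
) -> SubjectPrediction:
    """Predicted ARAT trajectory with central prediction bands.

    Parameters
    ----------
    history : DataFrame
        The subject's conditioning measurements (may be empty).
    grid : array-like of days
        Sorted evaluation times.
    levels : iterable of float in [0, 1)
        Central band levels; 0 gives a zero-width band at the point.
    interval_mode : {"analytic", "monte_carlo"}
        Analytic Gaussian bands, or empirical quantiles over joint draws of
        (beta, b, eps).
    clamp : bool
        Truncate point and band endpoints to the ARAT range [0, 57]
        (presentation-layer truncation; the model itself is Gaussian).
    include_residual : bool
        Include sigma^2 (interval for a new noisy measurement).  Set False
        for a band on the noiseless latent trajectory.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0 or (np.diff(grid) < 0).any():
        raise ValueError("grid must be non-empty and sorted")
    levels = tuple(float(l) for l in levels)
    for l in levels:
        if not 0.0 <= l < 1.0:
            raise ValueError(f"interval level must be in [0, 1), got {l}")
    if interval_mode not in ("analytic", "monte_carlo"):
        raise ValueError(f"unknown interval_mode {interval_mode!r}")

    hist = _history_frame(history)
    post, X_h, Z_h, cf = _conditional(fitted, hist, covariates)
    gframe = _grid_frame(hist, grid, fitted.spec_.covariate_policy, covariates)
    X_g, Z_g = build_subject_design(gframe, covariates, fitted.spec_)
    point = X_g @ fitted.beta_ + Z_g @ post.mean

    # uncertainty in beta_hat propagates through the *adjusted* design
    # X_adj = X_g - P X_h with P = Z_g G Z_h' V_h^{-1}: the empirical-Bayes
    # mean partially compensates a fixed-effect error, so the naive
    # X_g Cov(beta) X_g' term would overstate the width.
    if hist.empty:
        X_adj = X_g
    else:
        P = Z_g @ fitted.G_ @ np.linalg.solve(cf.T, np.linalg.solve(cf, Z_h)).T
        X_adj = X_g - P @ X_h

    bands = {}
    if interval_mode == "analytic":
        var = np.einsum("ij,jk,ik->i", Z_g, post.cov, Z_g)
        if include_fixed_uncertainty:
            var = var + np.einsum("ij,jk,ik->i", X_adj, fitted.cov_beta_, X_adj)
        if include_variance_uncertainty and levels and not hist.empty:
            y_h = hist["arat"].to_numpy(dtype=float)
            var = var + _variance_uncertainty_term(fitted, X_g, Z_g, X_h, Z_h, y_h)
        if include_residual:
            var = var + fitted.sigma2_
        sd = np.sqrt(np.maximum(var, 0.0))
        for level in levels:
            z = stats.norm.ppf(0.5 + level / 2.0)
            bands[level] = (point - z * sd, point + z * sd)
    else:
        rng = np.random.default_rng(seed)
        sims = np.tile(point, (n_draws, 1))
        if include_fixed_uncertainty:
            beta_dev = rng.multivariate_normal(
                np.zeros(fitted.beta_.size), fitted.cov_beta_, size=n_draws
            )
            sims = sims + beta_dev @ X_adj.T
        b_dev = rng.multivariate_normal(np.zeros(post.mean.size), post.cov, size=n_draws)
        sims = sims + b_dev @ Z_g.T
        if include_residual:
            sims = sims + rng.normal(0.0, np.sqrt(fitted.sigma2_), size=sims.shape)
        for level in levels:
            lo = np.quantile(sims, 0.5 - level / 2.0, axis=0)
            hi = np.quantile(sims, 0.5 + level / 2.0, axis=0)
            bands[level] = (np.minimum(lo, point), np.maximum(hi, point))

    if clamp:
        point = np.clip(point, 0, ARAT_MAX)
        bands = {
            lv: (np.clip(lo, 0, ARAT_MAX), np.clip(hi, 0, ARAT_MAX))
            for lv, (lo, hi) in bands.items()
        }
    return SubjectPrediction(
        grid=grid, point=point, bands=bands, history_used=hist, clamped=clamp
    )


def update_prediction(fitted, previous_history, new_measurement, grid,
                      **kwargs) -> SubjectPrediction:
    """Extend the history with one new measurement and re-predict.

    Sequential updating is exactly equivalent to batch conditioning on the
    extended history; this helper enforces chronological order and, under
    the last-observed covariate policy, refreshes the covariate values used
    across the grid from the newest measurement.
    """
    prev = _history_frame(previous_history)
    new_row = pd.DataFrame([dict(new_measurement)])
    if not prev.empty and float(new_row["t_days"].iloc[0]) <= float(prev["t_days"].max()):
        raise ValueError(
            "new measurement must be later than the existing history "
            f"(t={float(new_row['t_days'].iloc[0])} <= {float(prev['t_days'].max())})"
        )
    extended = pd.concat([prev, new_row], ignore_index=True)
    return predict_trajectory(fitted, extended, grid, **kwargs)
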