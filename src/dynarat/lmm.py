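"""Linear mixed-effects estimation for ARAT recovery trajectories.

The model for subject ``i`` with measurement times ``t_{i1} < ... < t_{in_i}``
is

    y_i = X_i beta + Z_i b_i + eps_i,   b_i ~ N(0, G),  eps_i ~ N(0, sigma^2 I),

where ``X_i`` carries the spline-of-time fixed effects with covariate mains
and time interactions, and ``Z_i`` a random intercept plus a smaller random
spline of time (see :mod:`dynarat.design`).

Estimation maximizes the (restricted) marginal likelihood with ``beta`` and
``sigma^2`` profiled out in closed form (GLS), leaving an optimization over
the log-Cholesky factor of the *relative* random-effects covariance
``Psi = G / sigma^2``.  The log-Cholesky parameterization keeps ``G``
positive semi-definite throughout; the per-subject Woodbury identity keeps
every solve at the (small) random-effects dimension.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_solve
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort
from .design import (
    MAIN,
    MAIN_AND_INTERACTION,
    DesignMatrices,
    ModelSpec,
    build_design,
)

__all__ = [
    "ArmRecoveryModel",
    "FitError",
    "fit_lmm",
    "marginal_loglik",
    "prune_by_significance",
    "fit_pruned",
    "filter_fitting_set",
    "filter_decliners",
]

LOG_DIAG_BOUND = 8.0
OFFDIAG_BOUND = 30.0


class FitError(RuntimeError):
    """Numerical failure during mixed-model estimation."""


# ---------------------------------------------------------------------------
# log-Cholesky parameterization of Psi = Lambda Lambda'


def _theta_to_lambda(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.diag_indices(q)] = np.exp(theta[:q])
    if q > 1:
        L[np.tril_indices(q, k=-1)] = theta[q:]
    return L


def _lambda_to_theta(L: np.ndarray) -> np.ndarray:
    q = L.shape[0]
    theta = np.empty(q * (q + 1) // 2)
    theta[:q] = np.log(np.maximum(np.diag(L), 1e-12))
    if q > 1:
        theta[q:] = L[np.tril_indices(q, k=-1)]
    return theta


# ---------------------------------------------------------------------------
# sufficient statistics per subject


class _Blocks:
    """Per-subject cross-product matrices; everything the profiled
    likelihood needs, computed once."""

    def __init__(self, dm: DesignMatrices):
        self.n_total = dm.y.size
        self.p = dm.X.shape[1]
        self.q = dm.Z.shape[1]
        self.subjects = []
        for gi in np.unique(dm.groups):
            m = dm.groups == gi
            X, Z, y = dm.X[m], dm.Z[m], dm.y[m]
            self.subjects.append(
                {
                    "XtX": X.T @ X,
                    "Xty": X.T @ y,
                    "ZtZ": Z.T @ Z,
                    "ZtX": Z.T @ X,
                    "Zty": Z.T @ y,
                    "yty": float(y @ y),
                    "n": y.size,
                }
            )


def _initial_theta(blocks: _Blocks) -> np.ndarray:
    """Method-of-moments starting value: OLS residuals, per-subject ridge
    estimates of the random effects, and their sample second moment as Psi."""
    q, N = blocks.q, blocks.n_total
    S_xx = sum(s["XtX"] for s in blocks.subjects)
    S_xy = sum(s["Xty"] for s in blocks.subjects)
    beta0 = np.linalg.lstsq(S_xx, S_xy, rcond=None)[0]
    rss = sum(
        s["yty"] - 2 * float(s["Xty"] @ beta0) + float(beta0 @ s["XtX"] @ beta0)
        for s in blocks.subjects
    )
    sigma2_0 = max(rss / N, 1e-8)
    B = np.zeros((q, q))
    for s in blocks.subjects:
        ridge = 1e-3 * np.trace(s["ZtZ"]) / q + 1e-8
        rhs = s["Zty"] - s["ZtX"] @ beta0
        b_i = np.linalg.solve(s["ZtZ"] + ridge * np.eye(q), rhs)
        B += np.outer(b_i, b_i)
    Psi0 = B / len(blocks.subjects) / sigma2_0
    Psi0 = Psi0 + 1e-3 * np.eye(q)
    try:
        L = np.linalg.cholesky(Psi0)
    except np.linalg.LinAlgError:
        L = np.diag(np.sqrt(np.maximum(np.diag(Psi0), 1e-3)))
    theta = _lambda_to_theta(L)
    theta[:q] = np.clip(theta[:q], -LOG_DIAG_BOUND + 1, LOG_DIAG_BOUND - 1)
    theta[q:] = np.clip(theta[q:], -OFFDIAG_BOUND + 1, OFFDIAG_BOUND - 1)
    return theta


def _profiled(blocks: _Blocks, theta: np.ndarray, method: str,
              with_grad: bool = False):
    """Profiled (RE)ML log-likelihood and the implied (beta, sigma2, Psi).

    With ``with_grad`` also returns the analytic gradient with respect to
    ``theta``.  Writing ``W_i = (I + Z_i Psi Z_i')^{-1}`` and using the
    envelope theorem (``beta`` and ``sigma^2`` are inner optimizers), the
    gradient with respect to the symmetric ``Psi`` is

        dl/dPsi = -1/2 [ C - A / sigma^2 - (REML) D ],

    with ``A = sum_i a_i a_i'`` (``a_i = Z_i' W_i r_i``, ``r_i`` the GLS
    residuals), ``C = sum_i Z_i' W_i Z_i`` and
    ``D = sum_i (Z_i'W_iX_i) S_xx^{-1} (X_i'W_iZ_i)``; the chain rule
    through the log-Cholesky factor gives ``dl/dLambda = 2 (dl/dPsi) Lambda``.
    """
    q, p, N = blocks.q, blocks.p, blocks.n_total
    L = _theta_to_lambda(theta, q)
    S_xx = np.zeros((p, p))
    S_xy = np.zeros(p)
    S_yy = 0.0
    logdet = 0.0
    eye_q = np.eye(q)
    cache = [] if with_grad else None
    for s in blocks.subjects:
        M = eye_q + L.T @ s["ZtZ"] @ L
        try:
            cf = np.linalg.cholesky(M)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by bounds
            raise FitError("singular per-subject system") from exc
        logdet += 2.0 * float(np.log(np.diag(cf)).sum())
        U = L.T @ s["ZtX"]  # q x p
        u = L.T @ s["Zty"]  # q
        Minv_U = np.linalg.solve(M, U)
        Minv_u = np.linalg.solve(M, u)
        S_xx += s["XtX"] - U.T @ Minv_U
        S_xy += s["Xty"] - U.T @ Minv_u
        S_yy += s["yty"] - float(u @ Minv_u)
        if with_grad:
            # T_i = I - ZtZ Lambda M^{-1} Lambda'; then Z'WZ = T ZtZ etc.
            T = eye_q - s["ZtZ"] @ L @ np.linalg.solve(M, L.T)
            cache.append(T)

    try:
        c_xx = np.linalg.cholesky(S_xx)
    except np.linalg.LinAlgError as exc:
        raise FitError("rank-deficient fixed-effects design") from exc
    beta = np.linalg.solve(S_xx, S_xy)
    rss = max(S_yy - float(S_xy @ beta), 1e-12)
    logdet_sxx = 2.0 * float(np.log(np.diag(c_xx)).sum())

    if method == "ML":
        sigma2 = rss / N
        ll = -0.5 * (N * np.log(2 * np.pi * sigma2) + logdet + N)
    else:  # REML
        sigma2 = rss / (N - p)
        ll = -0.5 * (
            (N - p) * np.log(2 * np.pi * sigma2)
            + logdet
            + logdet_sxx
            + (N - p)
        )
    if not with_grad:
        return float(ll), beta, float(sigma2), L @ L.T, S_xx

    A = np.zeros((q, q))
    C = np.zeros((q, q))
    D = np.zeros((q, q))
    for s, T in zip(blocks.subjects, cache):
        a = T @ (s["Zty"] - s["ZtX"] @ beta)
        A += np.outer(a, a)
        C += T @ s["ZtZ"]
        E = T @ s["ZtX"]  # q x p = Z'WX
        D += E @ cho_solve((c_xx, True), E.T)
    S_psi = -0.5 * (C - A / sigma2 - (D if method == "REML" else 0.0))
    dL = 2.0 * S_psi @ L
    grad = np.empty_like(theta)
    grad[:q] = np.diag(dL) * np.diag(L)  # log-diagonal chain rule
    if q > 1:
        grad[q:] = dL[np.tril_indices(q, k=-1)]
    return float(ll), beta, float(sigma2), L @ L.T, S_xx, grad


def _criterion_eta(blocks: _Blocks, eta: np.ndarray, method: str) -> float:
    """(RE)ML criterion as a function of ``eta = (theta, log sigma^2)``
    with sigma^2 *not* profiled — used for the observed information of the
    variance parameters."""
    q, p, N = blocks.q, blocks.p, blocks.n_total
    theta, log_s2 = eta[:-1], eta[-1]
    sigma2 = float(np.exp(log_s2))
    L = _theta_to_lambda(theta, q)
    S_xx = np.zeros((p, p))
    S_xy = np.zeros(p)
    S_yy = 0.0
    logdet = 0.0
    eye_q = np.eye(q)
    for s in blocks.subjects:
        M = eye_q + L.T @ s["ZtZ"] @ L
        cf = np.linalg.cholesky(M)
        logdet += 2.0 * float(np.log(np.diag(cf)).sum())
        U = L.T @ s["ZtX"]
        u = L.T @ s["Zty"]
        S_xx += s["XtX"] - U.T @ np.linalg.solve(M, U)
        S_xy += s["Xty"] - U.T @ np.linalg.solve(M, u)
        S_yy += s["yty"] - float(u @ np.linalg.solve(M, u))
    beta = np.linalg.solve(S_xx, S_xy)
    rss = max(S_yy - float(S_xy @ beta), 1e-12)
    if method == "ML":
        return -0.5 * (N * np.log(2 * np.pi * sigma2) + logdet + rss / sigma2)
    sign, logdet_sxx = np.linalg.slogdet(S_xx)
    return -0.5 * (
        (N - p) * np.log(2 * np.pi * sigma2) + logdet + logdet_sxx + rss / sigma2
    )


def _variance_param_cov(blocks: _Blocks, theta: np.ndarray, sigma2: float,
                        method: str) -> np.ndarray:
    """Asymptotic covariance of ``eta = (theta, log sigma^2)`` from the
    numerically differenced observed information at the optimum.  Weakly
    identified directions are regularized by flooring the information
    eigenvalues."""
    eta = np.concatenate([theta, [np.log(sigma2)]])
    k = eta.size
    h = 1e-4 * (1.0 + np.abs(eta))
    H = np.zeros((k, k))
    f0 = _criterion_eta(blocks, eta, method)

    def f(v):
        try:
            return _criterion_eta(blocks, v, method)
        except np.linalg.LinAlgError:
            return -np.inf

    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(eta + ei) - 2 * f0 + f(eta - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(eta + ei + ej) - f(eta + ei - ej) - f(eta - ei + ej) + f(eta - ei - ej)
            ) / (4 * h[i] * h[j])
    info = -H
    if not np.all(np.isfinite(info)):
        return np.zeros((k, k))
    w, V = np.linalg.eigh(0.5 * (info + info.T))
    # weakly identified or numerically negative directions get no
    # contribution (pseudo-inverse on the well-identified subspace)
    wmax = float(np.abs(w).max()) if w.size else 0.0
    inv_w = np.where(w > 1e-3 * wmax, 1.0 / np.maximum(w, 1e-300), 0.0)
    return V @ np.diag(inv_w) @ V.T


def marginal_loglik(beta, G, sigma2, cohort: Cohort, spec: ModelSpec, method: str = "ML") -> float:
    """Marginal (RE)ML log-likelihood at given parameters.

    Sum over subjects of ``log N(y_i; X_i beta, Z_i G Z_i' + sigma^2 I)``;
    REML adds the fixed-effects correction
    ``-(1/2) log|sum_i X_i' V_i^{-1} X_i| + (p/2) log(2 pi)``.
    """
    if sigma2 <= 0:
        raise FitError("sigma2 must be > 0")
    beta = np.asarray(beta, dtype=float)
    G = np.asarray(G, dtype=float)
    dm = build_design(cohort, spec)
    p = dm.X.shape[1]
    ll = 0.0
    S_xx = np.zeros((p, p))
    for gi in np.unique(dm.groups):
        m = dm.groups == gi
        X, Z, y = dm.X[m], dm.Z[m], dm.y[m]
        V = Z @ G @ Z.T + sigma2 * np.eye(y.size)
        try:
            cf = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular marginal covariance V_i") from exc
        r = np.linalg.solve(cf, y - X @ beta)
        Vinv_X = np.linalg.solve(cf.T, np.linalg.solve(cf, X))
        S_xx += X.T @ Vinv_X
        ll += -0.5 * (
            y.size * np.log(2 * np.pi)
            + 2.0 * float(np.log(np.diag(cf)).sum())
            + float(r @ r)
        )
    if method == "REML":
        sign, logdet_sxx = np.linalg.slogdet(S_xx)
        if sign <= 0:
            raise FitError("rank-deficient fixed-effects design")
        ll += -0.5 * logdet_sxx + 0.5 * p * np.log(2 * np.pi)
    return float(ll)


class ArmRecoveryModel(BaseEstimator):
    """Spline-based linear mixed-effects model of ARAT recovery.

    scikit-learn-style estimator: ``fit`` takes a :class:`~dynarat.cohort.Cohort`
    and estimates fixed effects ``beta_``, random-effects covariance ``G_``
    and residual variance ``sigma2_`` by profiled ML or REML.  Subject-level
    dynamic prediction lives in :mod:`dynarat.prediction` and on
    :meth:`predict_subject`.

    Parameters
    ----------
    spec : ModelSpec
        Fixed-effect structure, spline knots and covariate policy.  Defaults
        to the SAFE model (shoulder abduction + finger extension, each
        interacted with the 6-knot spline of time).
    method : {"REML", "ML"}
        Estimation criterion.  REML for final fits; ML when comparing
        fixed-effect structures.
    max_restarts : int
        Jittered optimizer restarts on non-convergence.
    tol : float
        Relative convergence tolerance on the profiled log-likelihood.
    """

    def __init__(self, spec: ModelSpec | None = None, method: str = "REML",
                 max_restarts: int = 5, tol: float = 1e-8):
        self.spec = spec
        self.method = method
        self.max_restarts = max_restarts
        self.tol = tol

    # -- estimation ---------------------------------------------------------

    def fit(self, X: Cohort, y=None):
        """Estimate the model on a cohort (``y`` is ignored; the outcome is
        the ``arat`` column of the cohort's measurements)."""
        from .design import model_spec

        cohort = X
        spec = self.spec if self.spec is not None else model_spec("model4_safe")
        if self.method not in ("ML", "REML"):
            raise FitError(f"unknown method {self.method!r}")
        dm = build_design(cohort, spec)
        blocks = _Blocks(dm)
        q = blocks.q
        n_theta = q * (q + 1) // 2

        def objective(theta):
            try:
                out = _profiled(blocks, theta, self.method, with_grad=True)
            except FitError:
                return 1e12, np.zeros_like(theta)
            return -out[0], -out[-1]

        bounds = [(-LOG_DIAG_BOUND, LOG_DIAG_BOUND)] * q + [
            (-OFFDIAG_BOUND, OFFDIAG_BOUND)
        ] * (n_theta - q)
        rng = np.random.default_rng(12345)
        theta_smart = _initial_theta(blocks)
        theta_flat = np.zeros(n_theta)
        theta_flat[:q] = -1.0  # modest relative RE variance
        starts = [theta_smart, theta_flat]
        starts += [
            theta_smart + rng.normal(0, 0.7, n_theta) for _ in range(self.max_restarts)
        ]
        best = None
        converged = False
        for i, start in enumerate(starts):
            res = optimize.minimize(
                objective, np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds]),
                method="L-BFGS-B", bounds=bounds, jac=True,
                options={"ftol": self.tol, "gtol": 1e-6, "maxiter": 1000},
            )
            if best is None or res.fun < best.fun - 1e-9:
                best = res
            if res.success and np.isfinite(res.fun):
                converged = True
            # the two deterministic starts always run; jittered restarts only
            # until something has converged
            if i >= 1 and converged:
                break
        if not converged:
            warnings.warn(
                "mixed-model optimizer did not converge; returning best attempt "
                "with converged_=False",
                RuntimeWarning,
            )

        ll, beta, sigma2, psi, S_xx = _profiled(blocks, best.x, self.method)
        self.spec_ = spec
        self.theta_ = best.x
        self.cov_eta_ = _variance_param_cov(blocks, best.x, sigma2, self.method)
        self.beta_ = beta
        self.psi_ = psi
        self.G_ = sigma2 * psi
        self.sigma2_ = sigma2
        self.loglik_ = ll
        self.cov_beta_ = sigma2 * np.linalg.inv(S_xx)
        self.converged_ = bool(converged)
        self.columns_ = dm.columns
        self.blocks_ = dm.blocks
        self.n_subjects_ = len(dm.subject_ids)
        self.n_obs_ = dm.y.size
        return self

    # -- prediction ---------------------------------------------------------

    def predict(self, X: Cohort) -> np.ndarray:
        """Population-level (fixed-effects only) prediction at the cohort's
        measurement rows, in measurement order."""
        check_is_fitted(self, "beta_")
        dm = build_design(X, self.spec_)
        return dm.X @ self.beta_

    def predict_subject(self, history, grid, **kwargs):
        """Subject-specific dynamic prediction; see
        :func:`dynarat.prediction.predict_trajectory`."""
        from .prediction import predict_trajectory

        return predict_trajectory(self, history, grid, **kwargs)

    # -- inference helpers --------------------------------------------------

    def wald_block_test(self, col_idx) -> tuple[float, float]:
        """Joint Wald test that the coefficients at ``col_idx`` are zero.
        Returns (statistic, p-value) with chi^2(len(col_idx)) reference."""
        check_is_fitted(self, "beta_")
        idx = np.asarray(col_idx, dtype=int)
        if idx.size == 0:
            return 0.0, 1.0
        b = self.beta_[idx]
        C = self.cov_beta_[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(C, b))
        return stat, float(stats.chi2.sf(stat, idx.size))


def fit_lmm(cohort: Cohort, spec: ModelSpec, method: str = "REML",
            **kwargs) -> ArmRecoveryModel:
    """Fit one model structure on a cohort and return the fitted estimator."""
    return ArmRecoveryModel(spec=spec, method=method, **kwargs).fit(cohort)


# ---------------------------------------------------------------------------
# significance-based pruning (model 2 and model 3 structures)


def prune_by_significance(fitted: ArmRecoveryModel, stage: str,
                          alpha: float | None = None) -> ModelSpec:
    """One pruning pass on a fitted model's covariate blocks.

    ``interactions_only``: each covariate's time-interaction columns are
    tested jointly; non-significant interactions are demoted to main-only.
    ``mains_and_interactions``: additionally, covariates whose interactions
    were dropped (or absent) have their main-effect block tested and are
    removed entirely when non-significant.  Iterate via :func:`fit_pruned`.
    """
    check_is_fitted(fitted, "beta_")
    if stage not in ("interactions_only", "mains_and_interactions"):
        raise ValueError(f"unknown pruning stage {stage!r}")
    spec = fitted.spec_
    if alpha is None:
        alpha = spec.prune_alpha
    new_covs = []
    for name, role in spec.covariates:
        block = fitted.blocks_[name]
        keep_interaction = False
        if role == MAIN_AND_INTERACTION and block["interaction"]:
            _, p_int = fitted.wald_block_test(block["interaction"])
            keep_interaction = p_int < alpha
        if keep_interaction:
            new_covs.append((name, MAIN_AND_INTERACTION))
            continue
        if stage == "interactions_only":
            new_covs.append((name, MAIN))
            continue
        _, p_main = fitted.wald_block_test(block["main"])
        if p_main < alpha:
            new_covs.append((name, MAIN))
    return spec.with_(covariates=tuple(new_covs))


def fit_pruned(cohort: Cohort, spec: ModelSpec, stage: str,
               alpha: float | None = None, method: str = "ML",
               max_passes: int = 10) -> ArmRecoveryModel:
    """Backward elimination: fit, prune, refit, until the spec stabilizes."""
    fitted = fit_lmm(cohort, spec, method=method)
    for _ in range(max_passes):
        reduced = prune_by_significance(fitted, stage, alpha)
        if reduced.covariates == fitted.spec_.covariates:
            return fitted
        fitted = fit_lmm(cohort, reduced, method=method)
    return fitted


# ---------------------------------------------------------------------------
# fitting-set filters


def filter_fitting_set(cohort: Cohort, min_measurements: int = 3,
                       min_span_days: float = 84.0) -> tuple[Cohort, Cohort]:
    """Split the cohort into (included, excluded) for model fitting:
    included subjects have at least ``min_measurements`` measurements with
    first and last at least ``min_span_days`` (12 weeks) apart."""
    grp = cohort.measurements.groupby("subject_id")["t_days"]
    counts = grp.size()
    span = grp.max() - grp.min()
    ok = counts.index[(counts >= min_measurements) & (span >= min_span_days)]
    ok = set(ok)
    all_ids = set(cohort.covariates["subject_id"])
    return cohort.subset(ok), cohort.subset(all_ids - ok)


def filter_decliners(cohort: Cohort, threshold: float = 7.25,
                     horizon_days: float = 182.0) -> tuple[Cohort, Cohort]:
    """Split into (retained, declined) by the FM-UE decline rule.

    A subject is a decliner when FM-UE drops by *strictly more than*
    ``threshold`` points (the clinically important difference) between any
    earlier and any later visit within the first 6 months.  Decliners are
    excluded from fitting but must still be predicted in cross-validation.
    """
    declined_ids = set()
    for sid, grp in cohort.measurements.groupby("subject_id"):
        grp = grp[grp["t_days"] <= horizon_days].sort_values("t_days")
        fm = grp["fmue"].to_numpy(dtype=float)
        fm = fm[~np.isnan(fm)]
        if fm.size < 2:
            continue
        drop = np.maximum.accumulate(fm) - fm
        if float(drop.max()) > threshold:
            declined_ids.add(sid)
    all_ids = set(cohort.covariates["subject_id"])
    return cohort.subset(all_ids - declined_ids), cohort.subset(declined_ids)
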