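"""Log-linear multivariate count autoregression.

The log-intensity nu_t = log lambda_t follows

    nu_t = omega + A nu_{t-1} + B log(X_{t-1} + 1),

with unrestricted real coefficients — the log link keeps the intensity
positive, so negative feedback and negative cross-effects are allowed,
which the linear INGARCH model cannot express.  Counts are conditionally
Poisson with mean exp(nu_t).  Estimation is unconstrained Poisson QML
with analytic derivatives and multi-start optimization (the likelihood
surface can be badly behaved in small samples).

Parameter packing matches the linear module: theta = [omega, vec(A),
vec(B)], column-major vec, d = n(1 + 2n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from . import _kernels
from .core import CountSeries, as_rng
from .maci import QmlFit, _sandwich, pack_theta, unpack_theta
from .mvpoisson import CommonShockSpec, sample_common_shock

__all__ = [
    "LogLinParams",
    "ExplosivePathError",
    "filter_nu",
    "quasi_loglik",
    "score",
    "hessian",
    "information",
    "fit_qml",
    "simulate",
    "check_stability",
    "LogLinearIngarch",
]

#: log-intensity above which a path is declared explosive (lambda ~ 1e13)
NU_CAP = 30.0


class ExplosivePathError(RuntimeError):
    """Raised when the log-intensity recursion explodes numerically."""


@dataclass(frozen=True)
class LogLinParams:
    """Unrestricted coefficients of the log-linear recursion."""

    omega: np.ndarray
    A: np.ndarray
    B: np.ndarray
    shock: float = 0.0

    def __post_init__(self) -> None:
        omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        n = omega.size
        A = np.asarray(self.A, dtype=float).reshape(n, n)
        B = np.asarray(self.B, dtype=float).reshape(n, n)
        if self.shock < 0:
            raise ValueError("shock intensity must be non-negative")
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)

    @property
    def n(self) -> int:
        return self.omega.size

    @property
    def theta(self) -> np.ndarray:
        return pack_theta(self.omega, self.A, self.B)


def check_stability(params: LogLinParams, truncation: int = 50):
    """Partial sum sum_{j=0}^{J} ||A^j B||_2 against the threshold 1.

    The condition sum_j ||A^j B||_2 < 1 guarantees stationarity and weak
    dependence.  When ||A||_2 < 1 a geometric tail bound closes the sum;
    otherwise, if the partial sum is still below one the answer is
    undecided (returned as ``None``).
    """
    A, B = params.A, params.B
    a_norm = float(np.linalg.norm(A, 2))
    total = 0.0
    Aj = np.eye(params.n)
    for _ in range(truncation + 1):
        total += float(np.linalg.norm(Aj @ B, 2))
        if total >= 1.0:
            return False, total
        Aj = Aj @ A
    if a_norm < 1.0:
        # tail <= ||A^{J+1}||_2 ||B||_2 / (1 - ||A||_2)
        tail = float(np.linalg.norm(Aj, 2) * np.linalg.norm(B, 2) / (1.0 - a_norm))
        return total + tail < 1.0, total + tail
    return None, total


def filter_nu(params: LogLinParams, x, init: np.ndarray | None = None):
    """Run the log-intensity recursion; returns (nu path, lambda path).

    nu_1 = ``init`` (default omega); raises :class:`ExplosivePathError`
    naming the first offending time point if any nu component exceeds
    the overflow cap.
    """
    X = x.values if isinstance(x, CountSeries) else np.asarray(x)
    if X.ndim == 1:
        X = X[:, None]
    T, n = X.shape
    nu = np.empty((T, n))
    nu[0] = params.omega if init is None else np.atleast_1d(np.asarray(init, float))
    U = np.log(X + 1.0)
    for t in range(1, T):
        nu[t] = params.omega + params.A @ nu[t - 1] + params.B @ U[t - 1]
        if (nu[t] > NU_CAP).any():
            raise ExplosivePathError(f"log-intensity exceeded {NU_CAP} at t={t + 1}")
    return nu, np.exp(nu)


def _qml_parts(theta: np.ndarray, X: np.ndarray, init: np.ndarray, order: int = 1):
    """Log-intensity and derivative recursions in one pass.

    Mirrors the linear model's recursions with log(X_{t-1}+1) in place of
    X_{t-1} and nu in place of lambda.  order=2 additionally returns the
    observed information H (negative Hessian) and the conditional
    information G = sum_t J_t' D_t J_t with D_t = diag(exp(nu_t)).
    """
    T, n = X.shape
    d = n * (1 + 2 * n)
    omega, A, B = unpack_theta(theta, n)
    if order <= 1 and _kernels.HAVE_NUMBA:
        Xf = X.astype(np.float64)
        ll, sc, status = _kernels.loglin_loglik_score(
            np.ascontiguousarray(omega), np.ascontiguousarray(A),
            np.ascontiguousarray(B), Xf, np.log(Xf + 1.0),
            init.astype(np.float64), NU_CAP, order,
        )
        if status:
            raise ExplosivePathError(f"log-intensity exceeded {NU_CAP}")
        return float(ll), sc, None, None
    U = np.log(X + 1.0)
    nu = init.astype(float).copy()
    J = np.zeros((n, d))
    K = np.zeros((n, d, d)) if order >= 2 else None
    loglik = 0.0
    sc = np.zeros(d)
    H = np.zeros((d, d)) if order >= 2 else None
    G = np.zeros((d, d)) if order >= 2 else None
    rows = np.tile(np.arange(n), n)
    cols_j = np.repeat(np.arange(n), n)
    colsA = n + cols_j * n + rows
    colsB = n + n * n + cols_j * n + rows
    eye = np.arange(n)
    for t in range(T):
        if t > 0:
            nu_prev, J_prev = nu, J
            nu = omega + A @ nu_prev + B @ U[t - 1]
            if (nu > NU_CAP).any():
                raise ExplosivePathError(f"log-intensity exceeded {NU_CAP} at t={t + 1}")
            if order >= 1:
                J = A @ J_prev
                J[eye, eye] += 1.0
                J[rows, colsA] += nu_prev[cols_j]
                J[rows, colsB] += U[t - 1][cols_j]
            if order >= 2:
                K = np.einsum("rs,sab->rab", A, K)
                for idx in range(n * n):
                    i, j, a = rows[idx], cols_j[idx], colsA[idx]
                    K[i, a, :] += J_prev[j]
                    K[i, :, a] += J_prev[j]
        lam = np.exp(nu)
        xt = X[t]
        loglik += float(xt @ nu - lam.sum())
        if order >= 1:
            r = xt - lam
            sc += J.T @ r
        if order >= 2:
            H += (J.T * lam) @ J - np.einsum("i,iab->ab", r, K)
            G += (J.T * lam) @ J
    return loglik, sc, H, G


def _prep(x):
    X = x.values if isinstance(x, CountSeries) else np.asarray(x)
    return X[:, None] if X.ndim == 1 else X


def quasi_loglik(params: LogLinParams, x, init=None) -> float:
    """Poisson quasi-log-likelihood sum_t (x'nu - sum exp(nu))."""
    X = _prep(x)
    init = params.omega if init is None else np.atleast_1d(np.asarray(init, float))
    ll, _, _, _ = _qml_parts(params.theta, X, init, order=0)
    return ll


def score(params: LogLinParams, x, init=None) -> np.ndarray:
    """Analytic score sum_t J_t' (X_t - exp(nu_t))."""
    X = _prep(x)
    init = params.omega if init is None else np.atleast_1d(np.asarray(init, float))
    _, sc, _, _ = _qml_parts(params.theta, X, init, order=1)
    return sc


def information(params: LogLinParams, x, init=None):
    """Observed information H and conditional information G."""
    X = _prep(x)
    init = params.omega if init is None else np.atleast_1d(np.asarray(init, float))
    _, _, H, G = _qml_parts(params.theta, X, init, order=2)
    return H, G


def hessian(params: LogLinParams, x, init=None) -> np.ndarray:
    """Hessian of the quasi-log-likelihood (the negative of H)."""
    H, _ = information(params, x, init)
    return -H


def simulate(
    params: LogLinParams,
    T: int,
    rng=None,
    joint: str = "independent",
    init: np.ndarray | None = None,
    labels=(),
) -> CountSeries:
    """Simulate counts; raises :class:`ExplosivePathError` on overflow."""
    rng = as_rng(rng)
    stable, total = check_stability(params)
    if stable is False:
        warnings.warn(f"stability sum {total:.3f} >= 1: paths may be explosive")
    n = params.n
    nu = params.omega.copy() if init is None else np.atleast_1d(np.asarray(init, float))
    X = np.empty((T, n), dtype=np.int64)
    for t in range(T):
        if t > 0:
            nu = params.omega + params.A @ nu + params.B @ np.log(X[t - 1] + 1.0)
            if (nu > NU_CAP).any():
                raise ExplosivePathError(f"log-intensity exceeded {NU_CAP} at t={t + 1}")
        lam = np.exp(nu)
        if joint == "common_shock" and params.shock > 0:
            X[t] = sample_common_shock(CommonShockSpec(lam, params.shock), 1, rng)[0]
        else:
            X[t] = rng.poisson(lam)
    return CountSeries(X, labels)


def _univariate_starts(X: np.ndarray) -> np.ndarray:
    """Per-series univariate fits seed the diagonal; cross terms at 1e-3."""
    n = X.shape[1]
    omega = np.empty(n)
    a = np.empty(n)
    b = np.empty(n)
    for i in range(n):
        xi = X[:, [i]]
        m = np.log(max(xi.mean(), 0.2))
        theta0 = np.array([0.4 * m, 0.2, 0.3])
        init = np.array([m])

        def negll(th):
            try:
                ll, g, _, _ = _qml_parts(th, xi, init, order=1)
            except (ExplosivePathError, FloatingPointError):
                return 1e12, np.zeros(3)
            return -ll, -g

        res = minimize(negll, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 200})
        omega[i], a[i], b[i] = res.x
    A = np.full((n, n), 1e-3)
    B = np.full((n, n), 1e-3)
    np.fill_diagonal(A, a)
    np.fill_diagonal(B, b)
    return pack_theta(omega, A, B)


def fit_qml(
    x,
    init_strategy: str | np.ndarray = "univariate",
    n_starts: int = 5,
    maxiter: int = 500,
    rng=None,
) -> QmlFit:
    """Unconstrained multi-start QML fit of the log-linear model.

    The default start comes from per-series univariate fits (cross terms
    1e-3); the remaining starts are Gaussian perturbations of it.  The
    start with the highest quasi-log-likelihood wins; ties go to the
    smallest parameter norm.  Explosive parameter regions are penalized
    rather than fatal during the search.
    """
    X = _prep(x)
    T, n = X.shape
    d = n * (1 + 2 * n)
    if T * n <= d:
        raise ValueError(f"need T*n > {d} observations to fit {d} parameters")
    rng = as_rng(rng)
    init = np.log(np.maximum(X.mean(axis=0), 0.2))
    if isinstance(init_strategy, np.ndarray):
        starts = [init_strategy]
    else:
        base = _univariate_starts(X)
        starts = [base] + [
            base + rng.normal(scale=0.1, size=d) for _ in range(n_starts - 1)
        ]

    def negll(th):
        try:
            ll, g, _, _ = _qml_parts(th, X, init, order=1)
        except (ExplosivePathError, FloatingPointError):
            return 1e12, np.zeros(d)
        if not np.isfinite(ll):
            return 1e12, np.zeros(d)
        return -ll, -g

    results = []
    for theta0 in starts:
        res = minimize(negll, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7})
        results.append(res)
    ok = [r for r in results if np.isfinite(r.fun) and r.fun < 1e11]
    if not ok:
        status = [f"start {i}: {r.message}" for i, r in enumerate(results)]
        raise RuntimeError("all starts failed to converge:\n" + "\n".join(status))
    best_fun = min(r.fun for r in ok)
    best = min(
        (r for r in ok if r.fun <= best_fun + 1e-8),
        key=lambda r: float(np.linalg.norm(r.x)),
    )
    theta = best.x
    omega, A, B = unpack_theta(theta, n)
    params = LogLinParams(omega, A, B)
    ll, sc, H, G = _qml_parts(theta, X, init, order=2)
    cov, se = _sandwich(H, G)
    return QmlFit(
        params=params, theta=theta, loglik=ll, score=sc, se=se, cov=cov,
        converged=bool(best.success), n_iter=int(best.nit),
        message=str(best.message),
        boundary=np.zeros(d, dtype=bool),
        starts=[{"fun": float(r.fun), "success": bool(r.success)} for r in results],
        init=init,
    )


class LogLinearIngarch(BaseEstimator):
    """Scikit-learn style estimator for the log-linear count autoregression."""

    def __init__(self, n_starts: int = 5, shock: float = 0.0,
                 maxiter: int = 500, random_state=None):
        self.n_starts = n_starts
        self.shock = shock
        self.maxiter = maxiter
        self.random_state = random_state

    def fit(self, X, y=None):
        fit = fit_qml(X, n_starts=self.n_starts, maxiter=self.maxiter,
                      rng=as_rng(self.random_state))
        self.fit_ = fit
        self.params_ = LogLinParams(fit.params.omega, fit.params.A,
                                    fit.params.B, shock=self.shock)
        self.omega_, self.A_, self.B_ = fit.params.omega, fit.params.A, fit.params.B
        self.theta_ = fit.theta
        self.se_ = fit.se
        self.loglik_ = fit.loglik
        self.converged_ = fit.converged
        self.n_features_in_ = self.omega_.size
        return self

    def filter(self, X):
        """(nu, lambda) paths under the fitted parameters."""
        return filter_nu(self.params_, X, self.fit_.init)

    def forecast(self, X, horizon: int, replicates: int = 10_000, rng=None):
        from .forecast import forecast_obs_driven
        return forecast_obs_driven(self.params_, X, horizon, replicates,
                                   rng=rng, model="loglinear", init=self.fit_.init)

    def predict(self, X, horizon: int = 1) -> np.ndarray:
        """Conditional-mean one-step forecast exp(nu_{T+1})."""
        Xv = X.values if isinstance(X, CountSeries) else np.asarray(X)
        nu, _ = filter_nu(self.params_, Xv, self.fit_.init)
        nxt = self.params_.omega + self.params_.A @ nu[-1] \
            + self.params_.B @ np.log(Xv[-1] + 1.0)
        return np.exp(nxt)
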