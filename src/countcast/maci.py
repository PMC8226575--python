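"""Linear multivariate autoregressive conditional intensity (INGARCH) model.

The conditional intensity follows the GARCH-like linear recursion

    lambda_t = omega + A lambda_{t-1} + B X_{t-1},

with all coefficients non-negative so the intensity stays positive, and
counts drawn conditionally Poisson: X_{i,t} | F_{t-1} ~ Poisson(lambda_{i,t}).
Estimation is by Poisson quasi-maximum likelihood with analytic score,
observed-information and conditional-information recursions; standard
errors use the sandwich H^{-1} G H^{-1}.

Parameter packing convention: theta = [omega, vec(A), vec(B)] with
column-major (Fortran) vec, so d = n(1 + 2n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from . import _kernels
from .core import CountSeries, as_rng
from .mvpoisson import CommonShockSpec, sample_common_shock

__all__ = [
    "MaciParams",
    "QmlFit",
    "filter_intensity",
    "quasi_loglik",
    "score",
    "information",
    "fit_qml",
    "simulate",
    "check_stationarity",
    "LinearIngarch",
]


@dataclass(frozen=True)
class MaciParams:
    """Parameters of the linear intensity recursion (one lag each).

    All entries of ``omega``, ``A`` and ``B`` must be non-negative;
    ``shock`` is an optional common-shock intensity adding contemporaneous
    positive correlation on top of the conditional intensities.
    """

    omega: np.ndarray
    A: np.ndarray
    B: np.ndarray
    shock: float = 0.0

    def __post_init__(self) -> None:
        omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        n = omega.size
        A = np.asarray(self.A, dtype=float).reshape(n, n)
        B = np.asarray(self.B, dtype=float).reshape(n, n)
        if (omega < 0).any() or (A < 0).any() or (B < 0).any():
            raise ValueError("omega, A and B must be non-negative")
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

    def unconditional_mean(self) -> np.ndarray:
        """Fixed point (I - A - B)^{-1} omega of the expected recursion."""
        n = self.n
        return np.linalg.solve(np.eye(n) - self.A - self.B, self.omega)


@dataclass
class QmlFit:
    """Result of a quasi-maximum-likelihood fit.

    ``cov`` is the sandwich H^{-1} G H^{-1} with H the observed
    information and G the conditional information; ``se`` its root
    diagonal.  ``boundary`` flags coefficients pinned at the lower bound,
    where sandwich inference is unreliable.
    """

    params: object
    theta: np.ndarray
    loglik: float
    score: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    converged: bool
    n_iter: int
    message: str
    boundary: np.ndarray = field(default=None)
    starts: list = field(default_factory=list)
    init: np.ndarray = field(default=None)  # recursion start used in fitting


def pack_theta(omega: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.concatenate([omega, A.ravel(order="F"), B.ravel(order="F")])


def unpack_theta(theta: np.ndarray, n: int):
    omega = theta[:n]
    A = theta[n : n + n * n].reshape(n, n, order="F")
    B = theta[n + n * n :].reshape(n, n, order="F")
    return omega, A, B


def check_stationarity(params: MaciParams) -> tuple[bool, float]:
    """Spectral norm of A + B and whether it is below one.

    ||A + B||_2 < 1 is the sufficient condition for stationarity of the
    linear intensity recursion.
    """
    norm = float(np.linalg.norm(params.A + params.B, 2))
    return norm < 1.0, norm


def _default_init(params: MaciParams) -> np.ndarray:
    stat, _ = check_stationarity(params)
    if stat:
        return params.unconditional_mean()
    return params.omega.copy()


def filter_intensity(
    params: MaciParams, x: CountSeries | np.ndarray, init: np.ndarray | None = None
) -> np.ndarray:
    """Run the intensity recursion over observed counts.

    Returns the T x n path of conditional intensities lambda_t, with
    lambda_1 = ``init`` (default: unconditional mean when stationary,
    else omega).
    """
    X = x.values if isinstance(x, CountSeries) else np.asarray(x)
    if X.ndim == 1:
        X = X[:, None]
    init = _default_init(params) if init is None else np.atleast_1d(np.asarray(init, float))
    if (init <= 0).any():
        raise ValueError("initial intensity must be strictly positive")
    T, n = X.shape
    lam = np.empty((T, n))
    lam[0] = init
    A, B, omega = params.A, params.B, params.omega
    for t in range(1, T):
        lam[t] = omega + A @ lam[t - 1] + B @ X[t - 1]
    return lam


def _qml_parts(theta: np.ndarray, X: np.ndarray, init: np.ndarray, order: int = 1):
    """One pass of the intensity and derivative recursions.

    order=0: quasi-log-likelihood only; order=1: + score; order=2:
    + observed information H (negative Hessian) and conditional
    information G, via the second-derivative tensor recursion.
    """
    T, n = X.shape
    d = n * (1 + 2 * n)
    omega, A, B = unpack_theta(theta, n)
    if order <= 1 and _kernels.HAVE_NUMBA:
        ll, sc, status = _kernels.maci_loglik_score(
            np.ascontiguousarray(omega), np.ascontiguousarray(A),
            np.ascontiguousarray(B), X.astype(np.float64),
            init.astype(np.float64), order,
        )
        if status:
            raise ValueError("non-positive intensity on the filtered path")
        return float(ll), sc, None, None
    lam = init.astype(float).copy()
    J = np.zeros((n, d))
    K = np.zeros((n, d, d)) if order >= 2 else None
    loglik = 0.0
    sc = np.zeros(d)
    H = np.zeros((d, d)) if order >= 2 else None
    G = np.zeros((d, d)) if order >= 2 else None
    rows = np.tile(np.arange(n), n)        # i index of a_{ij}/b_{ij}
    cols_j = np.repeat(np.arange(n), n)    # j index
    colsA = n + cols_j * n + rows
    colsB = n + n * n + cols_j * n + rows
    eye = np.arange(n)
    for t in range(T):
        if t > 0:
            lam_prev, J_prev = lam, J
            lam = omega + A @ lam_prev + B @ X[t - 1]
            if order >= 1:
                J = A @ J_prev
                J[eye, eye] += 1.0
                J[rows, colsA] += lam_prev[cols_j]
                J[rows, colsB] += X[t - 1][cols_j]
            if order >= 2:
                K = np.einsum("rs,sab->rab", A, K)
                for idx in range(n * n):
                    i, j, a = rows[idx], cols_j[idx], colsA[idx]
                    K[i, a, :] += J_prev[j]
                    K[i, :, a] += J_prev[j]
        if (lam <= 0).any():
            raise ValueError(f"non-positive intensity at t={t + 1}")
        xt = X[t]
        loglik += float(xt @ np.log(lam) - lam.sum())
        if order >= 1:
            r = xt / lam - 1.0
            sc += J.T @ r
        if order >= 2:
            H += (J.T * (xt / lam**2)) @ J - np.einsum("i,iab->ab", r, K)
            G += (J.T / lam) @ J
    return loglik, sc, H, G


def _coerce_init(X: np.ndarray, params: MaciParams, init) -> np.ndarray:
    if init is None:
        return _default_init(params)
    init = np.atleast_1d(np.asarray(init, float))
    if (init <= 0).any():
        raise ValueError("initial intensity must be strictly positive")
    return init


def quasi_loglik(params: MaciParams, x, init=None) -> float:
    """Poisson quasi-log-likelihood sum_t sum_i (x log lambda - lambda).

    The factorial term of the full likelihood is a constant in theta and
    is dropped.
    """
    X = x.values if isinstance(x, CountSeries) else np.asarray(x)
    if X.ndim == 1:
        X = X[:, None]
    ll, _, _, _ = _qml_parts(params.theta, X, _coerce_init(X, params, init), order=0)
    return ll


def score(params: MaciParams, x, init=None) -> np.ndarray:
    """Analytic score S_T(theta) = sum_t J_t' D_t^{-1} (X_t - lambda_t)."""
    X = x.values if isinstance(x, CountSeries) else np.asarray(x)
    if X.ndim == 1:
        X = X[:, None]
    _, sc, _, _ = _qml_parts(params.theta, X, _coerce_init(X, params, init), order=1)
    return sc


def information(params: MaciParams, x, init=None):
    """Observed information H and conditional information G at theta.

    H is the negative Hessian of the quasi-log-likelihood (so positive
    definite near a regular optimum); G uses the working-Poisson
    substitution of the conditional count covariance by D_t, giving
    G = sum_t J_t' D_t^{-1} J_t.
    """
    X = x.values if isinstance(x, CountSeries) else np.asarray(x)
    if X.ndim == 1:
        X = X[:, None]
    _, _, H, G = _qml_parts(params.theta, X, _coerce_init(X, params, init), order=2)
    return H, G


def simulate(
    params: MaciParams,
    T: int,
    rng=None,
    joint: str = "independent",
    init: np.ndarray | None = None,
    labels=(),
) -> CountSeries:
    """Simulate counts from the model.

    ``joint='independent'`` draws the series conditionally independent
    Poisson; ``joint='common_shock'`` adds a shared Poisson shock of
    intensity ``params.shock`` each period, inducing positive
    contemporaneous correlation.
    """
    rng = as_rng(rng)
    stat, norm = check_stationarity(params)
    if not stat:
        warnings.warn(f"||A+B||_2 = {norm:.3f} >= 1: recursion may be explosive")
    lam = _coerce_init(None, params, init)
    n = params.n
    X = np.empty((T, n), dtype=np.int64)
    for t in range(T):
        if t > 0:
            lam = params.omega + params.A @ lam + params.B @ X[t - 1]
        if joint == "common_shock" and params.shock > 0:
            spec = CommonShockSpec(lam, params.shock)
            X[t] = sample_common_shock(spec, 1, rng)[0]
        else:
            X[t] = rng.poisson(lam)
    return CountSeries(X, labels)


def _univariate_starts(X: np.ndarray, bound: float) -> np.ndarray:
    """Per-series univariate fits; cross terms seeded at 1e-3."""
    n = X.shape[1]
    omega = np.empty(n)
    a = np.empty(n)
    b = np.empty(n)
    for i in range(n):
        xi = X[:, [i]]
        m = max(xi.mean(), 0.1)
        theta0 = np.array([0.4 * m, 0.3, 0.3])
        init = np.array([m])

        def negll(th):
            try:
                ll, g, _, _ = _qml_parts(th, xi, init, order=1)
            except ValueError:
                return 1e12, np.zeros(3)
            return -ll, -g

        res = minimize(
            negll, theta0, jac=True, method="L-BFGS-B",
            bounds=[(bound, None)] * 3, options={"maxiter": 200},
        )
        omega[i], a[i], b[i] = res.x
    A = np.full((n, n), 1e-3)
    B = np.full((n, n), 1e-3)
    np.fill_diagonal(A, a)
    np.fill_diagonal(B, b)
    return pack_theta(omega, A, B)


def fit_qml(
    x: CountSeries | np.ndarray,
    init_strategy: str | np.ndarray = "univariate",
    bound: float = 1e-8,
    maxiter: int = 500,
) -> QmlFit:
    """Constrained QML fit of the linear model.

    Maximizes the quasi-log-likelihood over the positive orthant (lower
    bound ``bound`` on every coefficient) with analytic gradient.  The
    intensity recursion is initialized at the sample mean of each series,
    held fixed during optimization so the analytic gradient is exact.
    """
    X = x.values if isinstance(x, CountSeries) else np.asarray(x)
    if X.ndim == 1:
        X = X[:, None]
    T, n = X.shape
    d = n * (1 + 2 * n)
    if T * n <= d:
        raise ValueError(f"need T*n > {d} observations to fit {d} parameters")
    init = np.maximum(X.mean(axis=0), 0.1)
    if isinstance(init_strategy, np.ndarray):
        theta0 = init_strategy
    elif init_strategy == "univariate":
        theta0 = _univariate_starts(X, bound)
    else:
        theta0 = np.full(d, 0.1)
        theta0[:n] = np.maximum(0.4 * X.mean(axis=0), 0.1)

    def negll(th):
        try:
            ll, g, _, _ = _qml_parts(th, X, init, order=1)
        except ValueError:
            return 1e12, np.zeros(d)
        return -ll, -g

    res = minimize(
        negll, theta0, jac=True, method="L-BFGS-B",
        bounds=[(bound, None)] * d,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
    )
    theta = res.x
    omega, A, B = unpack_theta(theta, n)
    params = MaciParams(omega, A, B)
    ll, sc, H, G = _qml_parts(theta, X, init, order=2)
    boundary = theta <= bound * 2
    if boundary.any():
        warnings.warn(
            f"{int(boundary.sum())} coefficient(s) at the lower bound; "
            "sandwich standard errors are unreliable there"
        )
    cov, se = _sandwich(H, G)
    return QmlFit(
        params=params, theta=theta, loglik=ll, score=sc, se=se, cov=cov,
        converged=bool(res.success), n_iter=int(res.nit),
        message=str(res.message), boundary=boundary, init=init,
    )


def _sandwich(H: np.ndarray, G: np.ndarray):
    """Sandwich covariance H^{-1} G H^{-1}; NaN on singular information."""
    try:
        Hinv = np.linalg.inv(H)
        cov = Hinv @ G @ Hinv
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        d = H.shape[0]
        cov = np.full((d, d), np.nan)
        se = np.full(d, np.nan)
    return cov, se


class LinearIngarch(BaseEstimator):
    """Scikit-learn style estimator for the linear INGARCH model.

    Parameters
    ----------
    bound : float
        Lower bound for all coefficients during constrained optimization.
    init_strategy : str
        'univariate' seeds diagonal terms from per-series univariate fits.
    shock : float
        Common-shock intensity used when simulating/forecasting jointly.
    """

    def __init__(self, bound: float = 1e-8, init_strategy: str = "univariate",
                 shock: float = 0.0, maxiter: int = 500):
        self.bound = bound
        self.init_strategy = init_strategy
        self.shock = shock
        self.maxiter = maxiter

    def fit(self, X, y=None):
        fit = fit_qml(X, init_strategy=self.init_strategy, bound=self.bound,
                      maxiter=self.maxiter)
        self.fit_ = fit
        self.params_ = MaciParams(fit.params.omega, fit.params.A,
                                  fit.params.B, shock=self.shock)
        self.omega_, self.A_, self.B_ = fit.params.omega, fit.params.A, fit.params.B
        self.theta_ = fit.theta
        self.se_ = fit.se
        self.loglik_ = fit.loglik
        self.converged_ = fit.converged
        self.n_features_in_ = self.omega_.size
        return self

    def filter(self, X) -> np.ndarray:
        """Conditional intensity path under the fitted parameters."""
        return filter_intensity(self.params_, X, self.fit_.init)

    def forecast(self, X, horizon: int, replicates: int = 10_000, rng=None):
        """Monte-Carlo predictive ensemble ``horizon`` steps past the data."""
        from .forecast import forecast_obs_driven
        return forecast_obs_driven(self.params_, X, horizon, replicates,
                                   rng=rng, model="maci", init=self.fit_.init)

    def predict(self, X, horizon: int = 1) -> np.ndarray:
        """One-step conditional-mean forecast lambda_{T+1} (horizon 1 exact)."""
        Xv = X.values if isinstance(X, CountSeries) else np.asarray(X)
        lam = filter_intensity(self.params_, Xv, self.fit_.init)
        out = self.params_.omega + self.params_.A @ lam[-1] + self.params_.B @ Xv[-1]
        for _ in range(horizon - 1):
            out = self.params_.omega + (self.params_.A + self.params_.B) @ out
        return out
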