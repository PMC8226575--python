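"""Nonlinear Poisson state-space model with a Gaussian VAR latent process.

Observations are conditionally independent Poisson counts whose
intensity depends nonlinearly on a latent log-scale process:

    X_{i,t} ~ Poisson(lambda_{i,t}),   lambda_t = beta * exp(h_t),
    h_t = Phi_1 h_{t-1} + ... + Phi_p h_{t-p} + eta_t,  eta_t ~ N(0, Sigma).

The latent VAR carries the dependence structure: off-diagonal Phi
entries encode (possibly signed) Granger-causal feedback between
series' intensities, and the innovation correlation encodes signed
contemporaneous dependence — neither is available in the linear
observation-driven model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .core import CountSeries, as_rng

__all__ = [
    "SsmParams",
    "intensity",
    "simulate",
    "check_stationarity",
    "granger_structure",
    "stationary_covariance",
]


@dataclass(frozen=True)
class SsmParams:
    """Scale vector, VAR coefficients and innovation covariance.

    ``Phi`` may be a single n x n matrix (p = 1) or a list of matrices
    for a VAR(p) latent process.  For n = 2 the covariance can be given
    as ``(sigma1, sigma2, rho)`` via :meth:`bivariate`; internally the
    off-diagonal is the covariance rho * sigma1 * sigma2.
    """

    beta: np.ndarray
    Phi: tuple
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        n = beta.size
        if (beta <= 0).any():
            raise ValueError("beta must be strictly positive")
        Phi = self.Phi
        if isinstance(Phi, np.ndarray) and Phi.ndim == 2:
            Phi = (Phi,)
        Phi = tuple(np.asarray(P, dtype=float).reshape(n, n) for P in Phi)
        Sigma = np.asarray(self.Sigma, dtype=float).reshape(n, n)
        if not np.allclose(Sigma, Sigma.T):
            raise ValueError("Sigma must be symmetric")
        eigs = np.linalg.eigvalsh(Sigma)
        if (eigs < -1e-12).any():
            raise ValueError("Sigma must be positive semidefinite")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "Phi", Phi)
        object.__setattr__(self, "Sigma", Sigma)

    @classmethod
    def bivariate(cls, beta, phi, sigma1, sigma2, rho) -> "SsmParams":
        """Bivariate parameterization with innovation correlation rho."""
        if not -1.0 < rho < 1.0:
            raise ValueError("|rho| must be < 1")
        Sigma = np.array(
            [
                [sigma1**2, rho * sigma1 * sigma2],
                [rho * sigma1 * sigma2, sigma2**2],
            ]
        )
        return cls(np.asarray(beta, float), np.asarray(phi, float), Sigma)

    @property
    def n(self) -> int:
        return self.beta.size

    @property
    def p(self) -> int:
        return len(self.Phi)


def intensity(beta: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Observation intensity lambda = beta * exp(h), elementwise."""
    beta = np.atleast_1d(np.asarray(beta, float))
    if (beta <= 0).any():
        raise ValueError("beta must be strictly positive")
    return beta * np.exp(np.asarray(h, float))


def companion_matrix(Phi: tuple) -> np.ndarray:
    """Stacked VAR(1) companion form of a VAR(p) coefficient set."""
    Phi = tuple(np.asarray(P, float) for P in Phi)
    n = Phi[0].shape[0]
    p = len(Phi)
    C = np.zeros((n * p, n * p))
    C[:n, :] = np.hstack(Phi)
    if p > 1:
        C[n:, :-n] = np.eye(n * (p - 1))
    return C


def check_stationarity(Phi) -> tuple[bool, np.ndarray]:
    """Companion-matrix eigenvalues and whether all lie inside the unit circle."""
    if isinstance(Phi, SsmParams):
        Phi = Phi.Phi
    if isinstance(Phi, np.ndarray) and Phi.ndim == 2:
        Phi = (Phi,)
    eigs = np.linalg.eigvals(companion_matrix(tuple(Phi)))
    return bool(np.max(np.abs(eigs)) < 1.0), eigs


def stationary_covariance(params: SsmParams) -> np.ndarray:
    """Stationary covariance of the latent process (companion Lyapunov solve)."""
    stat, _ = check_stationarity(params.Phi)
    if not stat:
        raise ValueError("latent VAR is not stationary")
    n, p = params.n, params.p
    C = companion_matrix(params.Phi)
    Q = np.zeros((n * p, n * p))
    Q[:n, :n] = params.Sigma
    gamma = solve_discrete_lyapunov(C, Q)
    return gamma[:n, :n] if p == 1 else gamma


def granger_structure(Phi) -> dict:
    """Which series' latent components feed which, from Phi's zero pattern.

    Returns {'edges': [(j, i), ...], 'description': str} where an edge
    (j, i) means series j Granger-causes series i (some Phi_ij != 0,
    0-based indices).
    """
    if isinstance(Phi, SsmParams):
        Phi = Phi.Phi
    if isinstance(Phi, np.ndarray) and Phi.ndim == 2:
        Phi = (Phi,)
    Phi = tuple(np.asarray(P, float) for P in Phi)
    n = Phi[0].shape[0]
    edges = sorted(
        {
            (j, i)
            for P in Phi
            for i in range(n)
            for j in range(n)
            if i != j and P[i, j] != 0.0
        }
    )
    if not edges:
        desc = "no cross-series Granger causation"
    else:
        desc = "; ".join(f"series {j + 1} causes series {i + 1}" for j, i in edges)
    return {"edges": edges, "description": desc}


def simulate(
    params: SsmParams,
    T: int,
    rng=None,
    h_init: np.ndarray | None = None,
    labels=(),
):
    """Simulate (counts, latent path).

    The latent start is drawn from the stationary VAR distribution when
    the process is stationary (h_init=None), else started at zero; an
    explicit ``h_init`` fixes h_1 deterministically (minus its own
    innovation, which is still added).
    """
    import warnings

    rng = as_rng(rng)
    n, p = params.n, params.p
    stat, eigs = check_stationarity(params.Phi)
    if not stat:
        warnings.warn(
            f"latent VAR not stationary (max |eig| = {np.max(np.abs(eigs)):.3f})"
        )
    chol = _safe_cholesky(params.Sigma)
    h = np.empty((T, n))
    hist = np.zeros((p, n))
    if h_init is not None:
        hist[0] = np.atleast_1d(np.asarray(h_init, float))
    elif stat:
        gamma = stationary_covariance(params)
        big = gamma if p > 1 else gamma
        ch = _safe_cholesky(big)
        draw = ch @ rng.standard_normal(big.shape[0])
        hist = draw.reshape(p, n) if p > 1 else draw[None, :]
    for t in range(T):
        mean = np.zeros(n)
        for lag, P in enumerate(params.Phi):
            mean += P @ hist[lag]
        h[t] = mean + chol @ rng.standard_normal(n)
        hist = np.vstack([h[t][None, :], hist[:-1]]) if p > 1 else h[t][None, :]
    lam = intensity(params.beta, h)
    X = rng.poisson(lam)
    return CountSeries(X, labels), h


def _safe_cholesky(S: np.ndarray) -> np.ndarray:
    """Cholesky factor tolerating positive-semidefinite (even zero) matrices."""
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(S)
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
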