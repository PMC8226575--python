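"""Bootstrap particle filter and backward smoothing for the Poisson SSM.

The filter propagates particles from the latent VAR transition, weights
them by the Poisson observation density and resamples every step
(systematic by default).  The log-likelihood estimate accumulates, per
time step, the log of the mean unnormalized weight via log-sum-exp —
the standard unbiased-likelihood estimator that particle MCMC requires.

All weight arithmetic is in log space; the filter raises
:class:`FilterDegeneracyError` if every particle underflows at some t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import CountSeries, as_rng
from .ssm import SsmParams, _safe_cholesky, check_stationarity, companion_matrix, stationary_covariance

__all__ = [
    "ParticleApprox",
    "SmoothedPaths",
    "FilterDegeneracyError",
    "bootstrap_pf",
    "resample",
    "ffbs",
    "smoothing_weights",
]

#: log-weight floor below which exp() underflows to zero
LOG_UNDERFLOW = -745.0

try:  # optional acceleration; the numpy path is numerically identical
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional extra
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not args else args[0]


@_njit(cache=True)
def _pf_core_poisson(X, logbeta, Phi, chol, z, gl, rng,
                     particles, weights, ancestors, ess):
    """Jitted inner loop: Poisson observations, VAR(1), systematic resampling.

    Draws follow the exact call order of the generic path (one
    standard_normal block then one uniform per step), so both paths
    produce bit-identical output for the same Generator state.
    """
    T, n = X.shape
    N = z.shape[0]
    logw = np.empty(N)
    loglik = 0.0
    for t in range(T):
        eps = rng.standard_normal((N, n))
        z = z @ Phi.T + eps @ chol.T
        m = -np.inf
        for i in range(N):
            s = 0.0
            for j in range(n):
                ll = logbeta[j] + z[i, j]
                s += X[t, j] * ll - np.exp(ll)
            logw[i] = s - gl[t]
            if logw[i] > m:
                m = logw[i]
        if not np.isfinite(m) or m < LOG_UNDERFLOW:
            return np.nan, t + 1
        wsum = 0.0
        for i in range(N):
            logw[i] = np.exp(logw[i] - m)
            wsum += logw[i]
        loglik += m + np.log(wsum / N)
        sq = 0.0
        for i in range(N):
            logw[i] /= wsum
            sq += logw[i] * logw[i]
        particles[t] = z
        weights[t] = logw
        ess[t] = 1.0 / sq
        u = rng.random()
        # systematic resampling
        c = logw[0]
        i = 0
        znew = np.empty_like(z)
        for k in range(N):
            target = (u + k) / N
            while c < target and i < N - 1:
                i += 1
                c += logw[i]
            ancestors[t, k] = i
            znew[k] = z[i]
        z = znew
    return loglik, 0


class FilterDegeneracyError(RuntimeError):
    """All particle weights underflowed at some time step."""

    def __init__(self, t: int):
        super().__init__(f"all particle weights underflowed at t={t}")
        self.t = t


@dataclass
class ParticleApprox:
    """Weighted particle approximation of the filtering distributions.

    ``particles[t]`` holds the N pre-resampling particles at time t+1
    (latent values, N x n), ``weights[t]`` their normalized weights, and
    ``ancestors[t]`` the resampled indices carried into step t+2.
    """

    particles: np.ndarray  # (T, N, n)
    weights: np.ndarray  # (T, N)
    ancestors: np.ndarray  # (T, N)
    loglik: float
    ess: np.ndarray  # (T,)

    @property
    def n_steps(self) -> int:
        return self.particles.shape[0]

    @property
    def n_particles(self) -> int:
        return self.particles.shape[1]

    def filtered_mean(self) -> np.ndarray:
        """Weighted particle mean at each time step (T x n)."""
        return np.einsum("tN,tNn->tn", self.weights, self.particles)


@dataclass
class SmoothedPaths:
    """Backward-sampled latent trajectories (M x T x n)."""

    paths: np.ndarray

    def mean(self) -> np.ndarray:
        return self.paths.mean(axis=0)


def resample(weights: np.ndarray, rng=None, scheme: str = "systematic") -> np.ndarray:
    """Draw N ancestor indices with expected multiplicity N * w_i."""
    rng = as_rng(rng)
    w = np.asarray(weights, float)
    N = w.size
    if scheme == "multinomial":
        return rng.choice(N, size=N, p=w)
    if scheme == "systematic":
        u = (rng.random() + np.arange(N)) / N
    elif scheme == "stratified":
        u = (rng.random(N) + np.arange(N)) / N
    else:
        raise ValueError(f"unknown resampling scheme: {scheme}")
    return np.searchsorted(np.cumsum(w), u).clip(max=N - 1)


def poisson_obs_loglik(x_t: np.ndarray, h: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Log p(x_t | h) for Poisson counts with intensity beta * exp(h).

    ``h`` is (N, n); returns the per-particle log observation density.
    """
    log_lam = np.log(beta)[None, :] + h
    return ((x_t[None, :] * log_lam) - np.exp(log_lam)).sum(axis=1) - gammaln(
        x_t + 1.0
    ).sum()


def bootstrap_pf(
    params: SsmParams,
    x: CountSeries | np.ndarray,
    N: int,
    rng=None,
    obs_loglik=None,
    scheme: str = "systematic",
    h_init: np.ndarray | None = None,
) -> ParticleApprox:
    """Bootstrap particle filter with per-step resampling.

    Parameters
    ----------
    obs_loglik : callable, optional
        ``obs_loglik(x_t, h) -> (N,) log-densities``; defaults to the
        Poisson observation model with scale ``params.beta``.  Supplying
        a Gaussian density turns the filter into its linear-Gaussian
        analogue (used for exact Kalman cross-checks).
    h_init : array, optional
        Deterministic latent value at t=0 (pre-sample); default draws
        initial particles from the stationary VAR distribution.
    """
    if N < 2:
        raise ValueError("need at least 2 particles")
    rng = as_rng(rng)
    X = x.values if isinstance(x, CountSeries) else np.asarray(x)
    if X.ndim == 1:
        X = X[:, None]
    T, n = X.shape
    p = params.p
    chol = _safe_cholesky(params.Sigma)
    C = companion_matrix(params.Phi)
    dim = n * p
    particles = np.empty((T, N, n))
    weights = np.empty((T, N))
    ancestors = np.zeros((T, N), dtype=np.int64)
    ess = np.empty(T)
    stat, _ = check_stationarity(params.Phi)

    # state of dimension n*p (companion form); observation reads first n
    if h_init is not None:
        z = np.tile(np.atleast_1d(np.asarray(h_init, float)), (N, p))
    elif stat:
        gamma = stationary_covariance(params)
        if p == 1:
            z = rng.standard_normal((N, n)) @ _safe_cholesky(gamma).T
        else:
            z = rng.standard_normal((N, dim)) @ _safe_cholesky(gamma).T
    else:
        z = np.zeros((N, dim))

    if obs_loglik is None and p == 1 and scheme == "systematic" and _HAVE_NUMBA:
        gl = gammaln(X + 1.0).sum(axis=1)
        loglik, bad_t = _pf_core_poisson(
            X.astype(np.float64), np.log(params.beta), params.Phi[0], chol,
            np.ascontiguousarray(z, dtype=np.float64), gl, rng,
            particles, weights, ancestors, ess,
        )
        if bad_t:
            raise FilterDegeneracyError(int(bad_t))
        return ParticleApprox(particles, weights, ancestors, float(loglik), ess)

    if obs_loglik is None:
        beta = params.beta
        gl = gammaln(X + 1.0).sum(axis=1)

        def obs_loglik(xt, h, _gl_t=None):  # noqa: F811
            log_lam = np.log(beta)[None, :] + h
            return (xt[None, :] * log_lam - np.exp(log_lam)).sum(axis=1)

        gl_terms = gl
    else:
        gl_terms = np.zeros(T)

    loglik = 0.0
    logN = np.log(N)
    for t in range(T):
        # prediction: propagate through the VAR transition
        z = z @ C.T
        z[:, :n] += rng.standard_normal((N, n)) @ chol.T
        particles[t] = z[:, :n]
        # updating: weight by the observation density
        logw = obs_loglik(X[t], z[:, :n]) - gl_terms[t]
        m = np.max(logw)
        if not np.isfinite(m) or m < LOG_UNDERFLOW:
            raise FilterDegeneracyError(t + 1)
        w = np.exp(logw - m)
        wsum = w.sum()
        loglik += float(m + np.log(wsum) - logN)
        w /= wsum
        weights[t] = w
        ess[t] = 1.0 / float((w**2).sum())
        # resampling
        idx = resample(w, rng, scheme)
        ancestors[t] = idx
        z = z[idx]
    return ParticleApprox(particles, weights, ancestors, loglik, ess)


def _transition_logpdf(h_next: np.ndarray, h_prev: np.ndarray, Phi: np.ndarray,
                       Sigma_inv: np.ndarray, logdet: float) -> np.ndarray:
    """log N(h_next; Phi h_prev, Sigma) for broadcastable particle arrays."""
    diff = h_next - h_prev @ Phi.T
    quad = np.einsum("...i,ij,...j->...", diff, Sigma_inv, diff)
    n = Phi.shape[0]
    return -0.5 * (quad + logdet + n * np.log(2.0 * np.pi))


def ffbs(
    fwd: ParticleApprox, params: SsmParams, M: int, rng=None
) -> SmoothedPaths:
    """Forward-filtering backward-sampling of M latent trajectories.

    Samples h_T from the terminal filter and walks backwards, reweighting
    each filtered particle by the VAR transition density to the already
    sampled future value.  Requires a VAR(1) latent process.
    """
    if params.p != 1:
        raise NotImplementedError("backward sampling implemented for p=1 only")
    rng = as_rng(rng)
    T, N, n = fwd.particles.shape
    Phi = params.Phi[0]
    Sigma = params.Sigma
    if np.allclose(Sigma, 0.0):
        Sigma = Sigma + 1e-12 * np.eye(n)
    Sigma_inv = np.linalg.inv(Sigma)
    logdet = float(np.linalg.slogdet(Sigma)[1])
    paths = np.empty((M, T, n))
    idx = rng.choice(N, size=M, p=fwd.weights[-1])
    paths[:, -1] = fwd.particles[-1][idx]
    for k in range(T - 2, -1, -1):
        # (N, M) transition log-densities from each filtered particle to
        # each sampled future value
        logf = _transition_logpdf(
            paths[:, k + 1][None, :, :], fwd.particles[k][:, None, :],
            Phi, Sigma_inv, logdet,
        )
        logp = np.log(fwd.weights[k])[:, None] + logf
        logp -= logsumexp(logp, axis=0, keepdims=True)
        probs = np.exp(logp)
        u = rng.random(M)
        idx = (np.cumsum(probs, axis=0) < u[None, :]).sum(axis=0).clip(max=N - 1)
        paths[:, k] = fwd.particles[k][idx]
    return SmoothedPaths(paths)


def smoothing_weights(fwd: ParticleApprox, params: SsmParams) -> np.ndarray:
    """Marginal smoothing weights W_{k|T} over the filtered particles.

    Backward recursion over the full (N x N) transition-density matrices;
    O(N^2 T) cost.  Each row sums to one.
    """
    if params.p != 1:
        raise NotImplementedError("marginal smoothing implemented for p=1 only")
    T, N, n = fwd.particles.shape
    Phi = params.Phi[0]
    Sigma = params.Sigma
    if np.allclose(Sigma, 0.0):
        Sigma = Sigma + 1e-12 * np.eye(n)
    Sigma_inv = np.linalg.inv(Sigma)
    logdet = float(np.linalg.slogdet(Sigma)[1])
    W = np.empty((T, N))
    W[-1] = fwd.weights[-1]
    for k in range(T - 2, -1, -1):
        # logf[i, j] = log f(h_{k+1}^j | h_k^i)
        logf = _transition_logpdf(
            fwd.particles[k + 1][None, :, :], fwd.particles[k][:, None, :],
            Phi, Sigma_inv, logdet,
        )
        logw_k = np.log(fwd.weights[k])
        denom = logsumexp(logw_k[:, None] + logf, axis=0)  # (N,)
        contrib = logsumexp(
            np.log(W[k + 1])[None, :] + logf - denom[None, :], axis=1
        )
        logW = logw_k + contrib
        W[k] = np.exp(logW - logsumexp(logW))
    return W
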