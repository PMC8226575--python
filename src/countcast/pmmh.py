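"""Particle marginal Metropolis-Hastings for the Poisson state-space model.

The sampler runs a Gaussian random walk on an unconstrained
transformation of the parameters (log beta, Phi entries as-is, log
sigma, atanh rho), substituting the bootstrap-particle-filter estimate
of the intractable likelihood into the acceptance ratio.  Because the
estimate is unbiased, the chain targets the exact posterior; the
current state's estimate is stored, never recomputed.

The proposal scale adapts during warm-up only (Robbins-Monro toward a
30% acceptance rate, inside the 25-40% target band) and is frozen
afterwards so the retained chain has the correct invariant law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator

from .core import CountSeries, as_rng
from .smc import FilterDegeneracyError, bootstrap_pf
from .ssm import SsmParams, check_stationarity

__all__ = [
    "PriorSpec",
    "PosteriorSample",
    "transform",
    "inverse_transform",
    "param_names",
    "run",
    "summarize_posterior",
    "hpd_interval",
    "PoissonStateSpace",
]


def param_names(n: int) -> list[str]:
    """Natural-scale parameter names for the bivariate-style packing."""
    names = [f"beta{i + 1}" for i in range(n)]
    names += [f"phi{i + 1}{j + 1}" for j in range(n) for i in range(n)]
    if n == 2:
        names += ["sigma1", "sigma2", "rho"]
    else:
        names += [f"sigma{i + 1}" for i in range(n)]
        names += [f"rho{i + 1}{j + 1}" for i in range(n) for j in range(i + 1, n)]
    return names


def transform(params: SsmParams) -> np.ndarray:
    """Map parameters to the unconstrained sampling scale.

    theta = [log beta, vec_F(Phi), log sigma_i, atanh r_ij] where r_ij
    are the innovation correlations (upper triangle).
    """
    if params.p != 1:
        raise NotImplementedError("PMMH supports a VAR(1) latent process")
    n = params.n
    sig = np.sqrt(np.diag(params.Sigma))
    corr = params.Sigma / np.outer(sig, sig)
    rho = corr[np.triu_indices(n, 1)]
    return np.concatenate(
        [np.log(params.beta), params.Phi[0].ravel(order="F"),
         np.log(sig), np.arctanh(rho)]
    )


def inverse_transform(theta: np.ndarray, n: int) -> SsmParams:
    """Inverse of :func:`transform`."""
    beta = np.exp(theta[:n])
    Phi = theta[n : n + n * n].reshape(n, n, order="F")
    sig = np.exp(theta[n + n * n : n + n * n + n])
    rho = np.tanh(theta[n + n * n + n :])
    corr = np.eye(n)
    corr[np.triu_indices(n, 1)] = rho
    corr[np.tril_indices(n, -1)] = corr.T[np.tril_indices(n, -1)]
    Sigma = corr * np.outer(sig, sig)
    return SsmParams(beta, (Phi,), Sigma)


def theta_dim(n: int) -> int:
    return n + n * n + n + n * (n - 1) // 2


@dataclass
class PriorSpec:
    """Independent Gaussian priors on the transformed scale.

    Defaults: log beta ~ N(0, 10), Phi entries ~ N(0, 1), log sigma ~
    N(0, 1), atanh rho ~ N(0, 1) — weakly informative and proper.  With
    ``stationary_only`` (default) the prior is zero outside the
    stationary region of the latent VAR.
    """

    n: int = 2
    loc: np.ndarray = None
    scale: np.ndarray = None
    stationary_only: bool = True

    def __post_init__(self) -> None:
        d = theta_dim(self.n)
        n = self.n
        if self.loc is None:
            self.loc = np.zeros(d)
        if self.scale is None:
            scale = np.ones(d)
            scale[:n] = np.sqrt(10.0)
            self.scale = scale
        self.loc = np.asarray(self.loc, float)
        self.scale = np.asarray(self.scale, float)
        if (self.scale <= 0).any():
            raise ValueError("prior scales must be positive")

    def logpdf(self, theta: np.ndarray) -> float:
        if self.stationary_only:
            n = self.n
            Phi = theta[n : n + n * n].reshape(n, n, order="F")
            stat, _ = check_stationarity(Phi)
            if not stat:
                return -np.inf
        z = (theta - self.loc) / self.scale
        return float(
            -0.5 * (z**2).sum()
            - np.log(self.scale).sum()
            - 0.5 * theta.size * np.log(2.0 * np.pi)
        )

    def sample(self, rng, size: int) -> np.ndarray:
        rng = as_rng(rng)
        draws = rng.normal(self.loc, self.scale, size=(size, self.loc.size))
        if self.stationary_only:
            n = self.n
            keep = []
            for row in draws:
                Phi = row[n : n + n * n].reshape(n, n, order="F")
                if check_stationarity(Phi)[0]:
                    keep.append(row)
            while len(keep) < size:
                row = rng.normal(self.loc, self.scale)
                Phi = row[n : n + n * n].reshape(n, n, order="F")
                if check_stationarity(Phi)[0]:
                    keep.append(row)
            draws = np.array(keep[:size])
        return draws


@dataclass
class PosteriorSample:
    """Retained PMMH draws with chain diagnostics.

    ``draws`` is on the transformed scale (M_kept x d); :meth:`to_frame`
    maps to the natural scale with named columns.
    """

    draws: np.ndarray
    logliks: np.ndarray
    acceptance_rate: float
    n: int
    warmup: int
    proposal_scale: float
    seed: object = None

    @property
    def names(self) -> list[str]:
        return param_names(self.n)

    def to_frame(self) -> pd.DataFrame:
        n = self.n
        rows = np.empty_like(self.draws)
        d = self.draws.shape[1]
        rows[:, :n] = np.exp(self.draws[:, :n])
        rows[:, n : n + n * n] = self.draws[:, n : n + n * n]
        rows[:, n + n * n : n + n * n + n] = np.exp(
            self.draws[:, n + n * n : n + n * n + n]
        )
        rows[:, n + n * n + n :] = np.tanh(self.draws[:, n + n * n + n :])
        return pd.DataFrame(rows[:, :d], columns=self.names)

    def params_at(self, i: int) -> SsmParams:
        return inverse_transform(self.draws[i], self.n)

    def posterior_mean_params(self) -> SsmParams:
        return inverse_transform(self.draws.mean(axis=0), self.n)


def run(
    x: CountSeries | np.ndarray,
    prior: PriorSpec | None = None,
    N: int = 500,
    M: int = 4000,
    warmup: int = 1000,
    rng=None,
    init_params: SsmParams | None = None,
    proposal_scale: float = 0.15,
    proposal_scales: np.ndarray | None = None,
    adapt: bool = True,
    target_rate: float = 0.30,
    prior_only: bool = False,
    thin: int = 1,
) -> PosteriorSample:
    """Run the particle Metropolis-Hastings chain.

    Parameters
    ----------
    N, M, warmup : int
        Particles per filter run, total MH iterations, and warm-up
        iterations discarded from the retained sample.
    proposal_scale, proposal_scales
        The random-walk step is ``proposal_scale * L @ N(0, I)`` where L
        starts as diag(proposal_scales).  During warm-up the scalar is
        tuned by Robbins-Monro toward ``target_rate`` and, from iteration
        200 on, L is refreshed from the empirical covariance of the chain
        history (adaptive-Metropolis style); both freeze at the end of
        warm-up so the retained chain is a valid Markov chain.
    prior_only : bool
        Replace the likelihood by a constant; the retained draws then
        sample the prior (the standard sampler-correctness check).
    """
    if not M > warmup >= 0:
        raise ValueError("need M > warmup >= 0")
    rng = as_rng(rng)
    X = x.values if isinstance(x, CountSeries) else np.asarray(x)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[1]
    prior = prior if prior is not None else PriorSpec(n=n)
    if prior.n != n:
        raise ValueError("prior dimension does not match the data")
    if proposal_scale <= 0:
        raise ValueError("proposal scale must be positive")
    d = theta_dim(n)
    if proposal_scales is None:
        proposal_scales = np.ones(d)
    proposal_scales = np.asarray(proposal_scales, float)
    if (proposal_scales <= 0).any():
        raise ValueError("proposal scales must be positive")

    if init_params is None:
        init_params = SsmParams(
            np.maximum(X.mean(axis=0), 0.2), (0.2 * np.eye(n),),
            0.25 * np.eye(n),
        )
    theta = transform(init_params)

    def loglik(th: np.ndarray) -> float:
        if prior_only:
            return 0.0
        pars = inverse_transform(th, n)
        return bootstrap_pf(pars, X, N, rng).loglik

    lp = prior.logpdf(theta)
    if not np.isfinite(lp):
        raise ValueError("initial parameters have zero prior probability")
    ll = loglik(theta)

    scale = proposal_scale
    L = np.diag(proposal_scales)
    draws = np.empty((M, d))
    lls = np.empty(M)
    n_accept = 0
    n_degenerate = 0
    for i in range(M):
        if adapt and 200 <= i < warmup and i % 50 == 0:
            emp = np.cov(draws[:i].T) + 1e-8 * np.eye(d)
            # effective step right after refresh is the AM-optimal
            # 2.38/sqrt(d) * chol(emp); Robbins-Monro keeps tuning `scale`
            L = np.linalg.cholesky(emp) * (2.38 / np.sqrt(d) / scale)
        prop = theta + scale * (L @ rng.standard_normal(d))
        lp_prop = prior.logpdf(prop)
        accept = False
        if np.isfinite(lp_prop):
            try:
                ll_prop = loglik(prop)
                log_ratio = (ll_prop + lp_prop) - (ll + lp)
                accept = np.log(rng.random()) < log_ratio
            except FilterDegeneracyError:
                n_degenerate += 1
        if accept:
            theta, ll, lp = prop, ll_prop, lp_prop
            n_accept += 1
        draws[i] = theta
        lls[i] = ll
        if adapt and i < warmup:
            # Robbins-Monro on the log proposal scale
            gamma = 2.0 / (1.0 + i) ** 0.6
            scale *= np.exp(gamma * ((1.0 if accept else 0.0) - target_rate))
    if n_degenerate:
        warnings.warn(f"{n_degenerate} proposals rejected due to filter degeneracy")
    kept = draws[warmup::thin]
    return PosteriorSample(
        draws=kept,
        logliks=lls[warmup::thin],
        acceptance_rate=n_accept / M,
        n=n,
        warmup=warmup,
        proposal_scale=scale,
    )


def hpd_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``level`` of the draws."""
    s = np.sort(np.asarray(draws, float))
    m = s.size
    k = max(int(np.ceil(level * m)), 1)
    if k >= m:
        return float(s[0]), float(s[-1])
    widths = s[k:] - s[: m - k]
    j = int(np.argmin(widths))
    return float(s[j]), float(s[j + k])


def _kde_mode(draws: np.ndarray) -> float:
    draws = np.asarray(draws, float)
    if np.ptp(draws) < 1e-12:
        return float(draws[0])
    kde = gaussian_kde(draws)  # Silverman-type bandwidth
    grid = np.linspace(draws.min(), draws.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def summarize_posterior(sample: PosteriorSample, level: float = 0.95) -> pd.DataFrame:
    """Mean, median, kernel-density mode and HPD bounds per parameter."""
    frame = sample.to_frame()
    if len(frame) < 100:
        warnings.warn("fewer than 100 retained draws; summaries are noisy")
    rows = {}
    lo_name = f"HPDl {level:.0%}"
    hi_name = f"HPDu {level:.0%}"
    for name in frame.columns:
        v = frame[name].to_numpy()
        lo, hi = hpd_interval(v, level)
        rows[name] = {
            "Mean": v.mean(),
            "Median": float(np.median(v)),
            "Mode": _kde_mode(v),
            lo_name: lo,
            hi_name: hi,
        }
    return pd.DataFrame(rows).T


class PoissonStateSpace(BaseEstimator):
    """Scikit-learn style estimator: Bayesian fit of the Poisson SSM.

    ``fit`` runs the particle Metropolis-Hastings sampler and stores the
    posterior; ``forecast`` propagates terminal particles under posterior
    parameter draws so that parameter uncertainty enters the predictive.

    Parameters
    ----------
    n_particles, n_iter, warmup : int
        Bootstrap-filter particles and MH chain lengths.
    stationary_only : bool
        Restrict the prior to the stationary region of the latent VAR.
    """

    def __init__(self, n_particles: int = 500, n_iter: int = 4000,
                 warmup: int = 1000, proposal_scale: float = 0.15,
                 stationary_only: bool = True, random_state=None):
        self.n_particles = n_particles
        self.n_iter = n_iter
        self.warmup = warmup
        self.proposal_scale = proposal_scale
        self.stationary_only = stationary_only
        self.random_state = random_state

    def fit(self, X, y=None):
        Xv = X.values if isinstance(X, CountSeries) else np.asarray(X)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        n = Xv.shape[1]
        rng = as_rng(self.random_state)
        prior = PriorSpec(n=n, stationary_only=self.stationary_only)
        self.posterior_ = run(
            Xv, prior, N=self.n_particles, M=self.n_iter,
            warmup=self.warmup, rng=rng, proposal_scale=self.proposal_scale,
        )
        self.acceptance_rate_ = self.posterior_.acceptance_rate
        self.params_ = self.posterior_.posterior_mean_params()
        # terminal particle set under the posterior-mean parameters,
        # reused as the forecast origin
        self.terminal_filter_ = bootstrap_pf(
            self.params_, Xv, self.n_particles, rng
        )
        self._rng = rng
        self.n_features_in_ = n
        return self

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        return summarize_posterior(self.posterior_, level)

    def forecast(self, horizon: int, replicates: int = 10_000, rng=None):
        from .forecast import forecast_ssm
        rng = self._rng if rng is None else as_rng(rng)
        return forecast_ssm(
            self.posterior_, self.terminal_filter_, horizon, replicates, rng
        )

    def predict(self, horizon: int = 1, replicates: int = 4000, rng=None):
        """Posterior predictive mean path (horizon x n)."""
        ens = self.forecast(horizon, replicates, rng)
        return ens.draws.mean(axis=0)
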