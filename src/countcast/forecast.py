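"""Monte-Carlo predictive distributions for all three model families.

Forecasts condition on the data through the origin T only; the
state-space predictive mixes over posterior parameter draws and terminal
filtered particles, so both parameter and latent-state uncertainty enter
the ensemble.  Observation-driven multi-step forecasts are generated by
stochastic path simulation (sampled counts are fed back into the
intensity recursion), giving a full predictive distribution for every
scoring rule rather than only a point forecast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

from .core import CountSeries, as_rng
from .loglinear import NU_CAP, ExplosivePathError, LogLinParams, filter_nu
from .maci import MaciParams, filter_intensity
from .pmmh import PosteriorSample
from .smc import ParticleApprox
from .ssm import _safe_cholesky

__all__ = [
    "PredictiveEnsemble",
    "forecast_ssm",
    "forecast_obs_driven",
    "predictive_pmf",
]


@dataclass
class PredictiveEnsemble:
    """Monte-Carlo draws from the s-step-ahead predictive distribution.

    ``draws`` is (R, s, n) integer counts; ``intensities`` holds the
    per-draw conditional intensities when the sampler exposes them,
    enabling Rao-Blackwellized pmf estimates.
    """

    draws: np.ndarray
    intensities: np.ndarray | None
    origin: int
    model: str

    @property
    def n_replicates(self) -> int:
        return self.draws.shape[0]

    @property
    def horizon(self) -> int:
        return self.draws.shape[1]

    @property
    def n_series(self) -> int:
        return self.draws.shape[2]

    def mean(self) -> np.ndarray:
        """Predictive mean per horizon and series (s x n)."""
        if self.intensities is not None:
            return self.intensities.mean(axis=0)
        return self.draws.mean(axis=0)

    def std(self) -> np.ndarray:
        """Predictive standard deviation per horizon and series (s x n)."""
        if self.intensities is not None:
            lam = self.intensities
            # law of total variance for a Poisson mixture
            return np.sqrt(lam.mean(axis=0) + lam.var(axis=0))
        return self.draws.std(axis=0)

    def interval(self, level: float = 0.90) -> tuple[np.ndarray, np.ndarray]:
        a = (1.0 - level) / 2.0
        return (
            np.quantile(self.draws, a, axis=0),
            np.quantile(self.draws, 1.0 - a, axis=0),
        )


def forecast_ssm(
    posterior: PosteriorSample,
    terminal: ParticleApprox,
    horizon: int,
    replicates: int = 10_000,
    rng=None,
) -> PredictiveEnsemble:
    """Predictive ensemble for the state-space model.

    Each replicate samples a posterior parameter draw and a terminal
    particle (by its filter weight), propagates the latent VAR(1)
    ``horizon`` steps and emits Poisson counts.  The posterior is not
    re-estimated between horizons.
    """
    if horizon < 1:
        raise ValueError("forecast horizon must be >= 1")
    rng = as_rng(rng)
    R = replicates
    n = posterior.n
    kept = posterior.draws.shape[0]
    pick = rng.integers(kept, size=R)
    thetas = posterior.draws[pick]
    beta = np.exp(thetas[:, :n])  # (R, n)
    Phi = thetas[:, n : n + n * n].reshape(R, n, n, order="F")
    sig = np.exp(thetas[:, n + n * n : n + n * n + n])
    rho = np.tanh(thetas[:, n + n * n + n :])
    chols = np.empty((R, n, n))
    for r in range(R):  # small n: direct per-draw Cholesky
        corr = np.eye(n)
        corr[np.triu_indices(n, 1)] = rho[r]
        corr[np.tril_indices(n, -1)] = corr.T[np.tril_indices(n, -1)]
        chols[r] = _safe_cholesky(corr * np.outer(sig[r], sig[r]))
    w = terminal.weights[-1]
    part_idx = rng.choice(terminal.n_particles, size=R, p=w)
    h = terminal.particles[-1][part_idx]  # (R, n)
    draws = np.empty((R, horizon, n), dtype=np.int64)
    lams = np.empty((R, horizon, n))
    for s in range(horizon):
        h = np.einsum("rij,rj->ri", Phi, h)
        h = h + np.einsum("rij,rj->ri", chols, rng.standard_normal((R, n)))
        lam = beta * np.exp(h)
        lams[:, s] = lam
        draws[:, s] = rng.poisson(lam)
    return PredictiveEnsemble(draws, lams, terminal.n_steps, "ssm")


def forecast_obs_driven(
    params: MaciParams | LogLinParams,
    x: CountSeries | np.ndarray,
    horizon: int,
    replicates: int = 10_000,
    rng=None,
    model: str = "maci",
    init: np.ndarray | None = None,
) -> PredictiveEnsemble:
    """Predictive ensemble for the observation-driven models.

    Horizon 1 is the exact conditional distribution (the intensity is a
    deterministic function of the data); beyond that, each replicate
    simulates its own count path, feeding sampled counts back into the
    recursion.  ``init`` seeds the in-sample filter (pass the value the
    fit used for consistency with the estimated likelihood).
    """
    if horizon < 1:
        raise ValueError("forecast horizon must be >= 1")
    rng = as_rng(rng)
    X = x.values if isinstance(x, CountSeries) else np.asarray(x)
    if X.ndim == 1:
        X = X[:, None]
    T, n = X.shape
    R = replicates
    omega, A, B = params.omega, params.A, params.B
    draws = np.empty((R, horizon, n), dtype=np.int64)
    lams = np.empty((R, horizon, n))
    if model == "maci":
        lam_path = filter_intensity(params, X, init)
        state = np.tile(lam_path[-1], (R, 1))
        xprev = np.tile(X[-1].astype(float), (R, 1))
        for s in range(horizon):
            state = omega[None, :] + state @ A.T + xprev @ B.T
            lams[:, s] = state
            draws[:, s] = rng.poisson(state)
            xprev = draws[:, s].astype(float)
    elif model == "loglinear":
        nu_path, _ = filter_nu(params, X, init)
        state = np.tile(nu_path[-1], (R, 1))
        uprev = np.tile(np.log(X[-1] + 1.0), (R, 1))
        for s in range(horizon):
            state = omega[None, :] + state @ A.T + uprev @ B.T
            if (state > NU_CAP).any():
                raise ExplosivePathError(
                    f"log-intensity exceeded {NU_CAP} at forecast step {s + 1}"
                )
            lam = np.exp(state)
            lams[:, s] = lam
            draws[:, s] = rng.poisson(lam)
            uprev = np.log(draws[:, s] + 1.0)
    else:
        raise ValueError(f"unknown model: {model}")
    return PredictiveEnsemble(draws, lams, T, model)


def predictive_pmf(
    ens: PredictiveEnsemble,
    horizon: int,
    series: int,
    support: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal predictive pmf at one horizon for one series.

    With per-draw intensities available this is the Rao-Blackwellized
    Poisson mixture (1/R) sum_r Pois(k; lambda_r); otherwise empirical
    frequencies of the draws.  The support is auto-extended to cover all
    observed draws and the 1 - 1e-9 quantile of the fitted mixture.

    Returns (support, probabilities); probabilities sum to one up to the
    truncated tail mass.
    """
    draws = ens.draws[:, horizon, series]
    if support is None:
        hi = int(draws.max())
        if ens.intensities is not None:
            lam = ens.intensities[:, horizon, series]
            hi = max(hi, int(poisson.ppf(1.0 - 1e-9, lam.max())))
        support = np.arange(hi + 1)
    support = np.asarray(support)
    if ens.intensities is not None:
        lam = ens.intensities[:, horizon, series]
        # log-space mixture over replicates, column per support point
        logp = (
            support[None, :] * np.log(lam[:, None])
            - lam[:, None]
            - gammaln(support[None, :] + 1.0)
        )
        probs = np.exp(logsumexp(logp, axis=0) - np.log(lam.size))
    else:
        counts = np.bincount(draws, minlength=support.size)[: support.size]
        probs = counts / draws.size
    return support, probs
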