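"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from countcast import ssm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bivariate_ssm_params():
    phi = np.array([[0.5, 0.0], [0.3, 0.5]])
    return ssm.SsmParams.bivariate([1.0, 2.0], phi, 0.5, 0.5, 0.3)


# --- independent linear-Gaussian oracle (textbook Kalman recursions) ---


def kalman_filter_loglik(ys, Phi, Sigma, obs_var, P0):
    """Exact log-likelihood of y_t = h_t + N(0, obs_var I), h_t a VAR(1)."""
    n = Phi.shape[0]
    m = np.zeros(n)
    P = P0.copy()
    ll = 0.0
    for y in ys:
        m = Phi @ m
        P = Phi @ P @ Phi.T + Sigma
        S = P + obs_var * np.eye(n)
        v = y - m
        ll += -0.5 * (np.log(np.linalg.det(2.0 * np.pi * S)) + v @ np.linalg.solve(S, v))
        K = P @ np.linalg.inv(S)
        m = m + K @ v
        P = P - K @ P
    return ll


def kalman_smoother_means(ys, Phi, Sigma, obs_var, P0):
    """Rauch-Tung-Striebel smoothed means for the same model."""
    n = Phi.shape[0]
    T = len(ys)
    ms = np.zeros((T, n))
    Ps = np.zeros((T, n, n))
    mp = np.zeros((T, n))
    Pp = np.zeros((T, n, n))
    m = np.zeros(n)
    P = P0.copy()
    for t, y in enumerate(ys):
        m = Phi @ m
        P = Phi @ P @ Phi.T + Sigma
        mp[t], Pp[t] = m, P
        S = P + obs_var * np.eye(n)
        K = P @ np.linalg.inv(S)
        m = m + K @ (y - m)
        P = P - K @ P
        ms[t], Ps[t] = m, P
    sm = ms.copy()
    for t in range(T - 2, -1, -1):
        J = Ps[t] @ Phi.T @ np.linalg.inv(Pp[t + 1])
        sm[t] = ms[t] + J @ (sm[t + 1] - mp[t + 1])
    return sm


def simulate_linear_gaussian(Phi, Sigma, obs_var, T, rng):
    """Draw (latent, observed) from the linear-Gaussian analogue model."""
    from countcast.ssm import SsmParams, stationary_covariance

    n = Phi.shape[0]
    gam = stationary_covariance(SsmParams(np.ones(n), (Phi,), Sigma))
    ch = np.linalg.cholesky(Sigma)
    h = np.linalg.cholesky(gam) @ rng.standard_normal(n)
    hs = np.zeros((T, n))
    ys = np.zeros((T, n))
    for t in range(T):
        h = Phi @ h + ch @ rng.standard_normal(n)
        hs[t] = h
        ys[t] = h + np.sqrt(obs_var) * rng.standard_normal(n)
    return hs, ys


@pytest.fixture
def gaussian_obs_loglik():
    """Per-particle Gaussian observation log-density factory."""

    def make(obs_var, n):
        const = 0.5 * n * np.log(2.0 * np.pi * obs_var)

        def obs(xt, h):
            return -0.5 * ((xt[None, :] - h) ** 2).sum(axis=1) / obs_var - const

        return obs

    return make
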