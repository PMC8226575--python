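"""Compiled inner loops for the QML derivative recursions.

The numpy implementations in :mod:`countcast.maci` and
:mod:`countcast.loglinear` remain the reference (and the only path for
the second-order recursions); these kernels reproduce the first-order
pass with explicit loops for speed inside the optimizer.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not args else args[0]


@njit(cache=True)
def maci_loglik_score(omega, A, B, X, init, order):
    """Linear-intensity quasi-log-likelihood and score in one pass.

    Returns (loglik, score, status); status 1 flags a non-positive
    intensity (invalid parameter point).
    """
    T, n = X.shape
    d = n * (1 + 2 * n)
    lam = init.copy()
    J = np.zeros((n, d))
    sc = np.zeros(d)
    ll = 0.0
    for t in range(T):
        if t > 0:
            lam_prev = lam
            lam = omega + A @ lam_prev + B @ X[t - 1]
            if order >= 1:
                J = A @ J
                for i in range(n):
                    J[i, i] += 1.0
                for j in range(n):
                    for i in range(n):
                        J[i, n + j * n + i] += lam_prev[j]
                        J[i, n + n * n + j * n + i] += X[t - 1, j]
        for i in range(n):
            if lam[i] <= 0.0:
                return np.nan, sc, 1
        for i in range(n):
            ll += X[t, i] * np.log(lam[i]) - lam[i]
            if order >= 1:
                r = X[t, i] / lam[i] - 1.0
                for a in range(d):
                    sc[a] += J[i, a] * r
    return ll, sc, 0


@njit(cache=True)
def loglin_loglik_score(omega, A, B, X, U, init, nu_cap, order):
    """Log-linear quasi-log-likelihood and score in one pass.

    ``U`` is log(X + 1) precomputed; status 2 flags an explosive path
    (some nu component above ``nu_cap``).
    """
    T, n = X.shape
    d = n * (1 + 2 * n)
    nu = init.copy()
    J = np.zeros((n, d))
    sc = np.zeros(d)
    ll = 0.0
    for t in range(T):
        if t > 0:
            nu_prev = nu
            nu = omega + A @ nu_prev + B @ U[t - 1]
            for i in range(n):
                if nu[i] > nu_cap:
                    return np.nan, sc, 2
            if order >= 1:
                J = A @ J
                for i in range(n):
                    J[i, i] += 1.0
                for j in range(n):
                    for i in range(n):
                        J[i, n + j * n + i] += nu_prev[j]
                        J[i, n + n * n + j * n + i] += U[t - 1, j]
        for i in range(n):
            lam_i = np.exp(nu[i])
            ll += X[t, i] * nu[i] - lam_i
            if order >= 1:
                r = X[t, i] - lam_i
                for a in range(d):
                    sc[a] += J[i, a] * r
    return ll, sc, 0
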