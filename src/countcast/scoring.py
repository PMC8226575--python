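"""Proper scoring rules and error measures for count forecasts.

All rules are negatively oriented (smaller is better).  For a predictive
pmf p over counts and realized count x:

* logarithmic score  -log p_x
* quadratic score    -2 p_x + ||p||^2
* spherical score    -p_x / ||p||
* ranked probability score  sum_k (P(X <= k) - 1(x <= k))^2
* squared error score  (x - mu_p)^2
* Dawid-Sebastiani score  ((x - mu)/sigma)^2 + 2 log sigma

The RPS indicator and the DSS square each have an ``as_printed`` literal
variant (indicator 1(x >= k); no square) selectable by flag, for
comparison with sources that print those forms.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "log_score",
    "quadratic_score",
    "spherical_score",
    "rps",
    "ses",
    "dss",
    "mse_mae",
    "mean_score",
    "score_forecasts",
    "score_report",
    "SCORE_COLUMNS",
]

SCORE_COLUMNS = ["log", "qs", "sph", "rps", "ds", "se"]


def _check_pmf(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < -1e-12).any():
        raise ValueError("pmf has negative entries")
    total = p.sum()
    if total > 1.0 + 1e-6:
        raise ValueError("pmf mass exceeds one")
    return np.clip(p, 0.0, None)


def _p_at(p: np.ndarray, x: int) -> float:
    """p_x on the truncated support; counts beyond it carry zero mass."""
    if x < 0:
        raise ValueError("count must be non-negative")
    return float(p[x]) if x < p.size else 0.0


def log_score(p: np.ndarray, x: int) -> float:
    """-log p_x; +inf (with a warning) when the outcome has zero mass."""
    p = _check_pmf(p)
    px = _p_at(p, int(x))
    if px <= 0.0:
        warnings.warn("outcome has zero predictive mass; log score is infinite")
        return np.inf
    return float(-np.log(px))


def quadratic_score(p: np.ndarray, x: int) -> float:
    """-2 p_x + ||p||^2 (the Brier score up to a constant)."""
    p = _check_pmf(p)
    return float(-2.0 * _p_at(p, int(x)) + (p**2).sum())


def spherical_score(p: np.ndarray, x: int) -> float:
    """-p_x / ||p||."""
    p = _check_pmf(p)
    norm = float(np.sqrt((p**2).sum()))
    if norm == 0.0:
        raise ValueError("pmf has zero norm")
    return float(-_p_at(p, int(x)) / norm)


def rps(p: np.ndarray, x: int, as_printed: bool = False) -> float:
    """Ranked probability score sum_k (P(X <= k) - 1(x <= k))^2.

    The truncated tail contributes (1 - total mass)^2 per omitted term
    and is negligible for supports covering all but < 1e-8 mass.  With
    ``as_printed`` the indicator is 1(x >= k) instead.
    """
    p = _check_pmf(p)
    x = int(x)
    cdf = np.cumsum(p)
    k = np.arange(p.size)
    ind = (x >= k).astype(float) if as_printed else (x <= k).astype(float)
    return float(((cdf - ind) ** 2).sum())


def pmf_mean_std(p: np.ndarray, support: np.ndarray | None = None):
    """Mean and standard deviation of a (truncated) predictive pmf."""
    p = _check_pmf(p)
    support = np.arange(p.size) if support is None else np.asarray(support)
    total = p.sum()
    mu = float((support * p).sum() / total)
    var = float(((support - mu) ** 2 * p).sum() / total)
    return mu, float(np.sqrt(var))


def ses(p: np.ndarray, x: int, support: np.ndarray | None = None) -> float:
    """Squared error score (x - mu_p)^2 with mu_p the predictive mean."""
    mu, _ = pmf_mean_std(p, support)
    return float((int(x) - mu) ** 2)


def dss(mu: float, sigma: float, x: float, as_printed: bool = False) -> float:
    """Dawid-Sebastiani score ((x - mu)/sigma)^2 + 2 log sigma.

    ``as_printed`` drops the square on the standardized residual (a
    non-proper literal variant kept for comparison).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = (x - mu) / sigma
    if as_printed:
        return float(z + 2.0 * np.log(sigma))
    return float(z**2 + 2.0 * np.log(sigma))


def mse_mae(actuals, forecasts) -> tuple[float, float]:
    """Mean squared and mean absolute error of point forecasts."""
    a = np.asarray(actuals, dtype=float).ravel()
    f = np.asarray(forecasts, dtype=float).ravel()
    if a.size != f.size:
        raise ValueError("actuals and forecasts must have equal length")
    d = a - f
    return float((d**2).mean()), float(np.abs(d).mean())


def mean_score(scores) -> float:
    """Arithmetic mean of per-observation scores."""
    return float(np.mean(np.asarray(scores, dtype=float)))


def score_forecasts(ens, actual: np.ndarray, as_printed: bool = False) -> dict:
    """All six mean scores of a predictive ensemble against realized counts.

    Scores are computed per series and horizon on the marginal
    predictives, then averaged.  ``actual`` is (s x n) counts aligned
    with the ensemble horizons.
    """
    from .forecast import predictive_pmf

    actual = np.asarray(actual)
    if actual.ndim == 1:
        actual = actual[:, None]
    s, n = actual.shape
    if s != ens.horizon or n != ens.n_series:
        raise ValueError("actual shape does not match the ensemble")
    per = {k: [] for k in SCORE_COLUMNS}
    for h in range(s):
        for i in range(n):
            xhi = int(actual[h, i])
            support, p = predictive_pmf(ens, h, i)
            if xhi >= support.size:
                support = np.arange(xhi + 1)
                support, p = predictive_pmf(ens, h, i, support)
            per["log"].append(log_score(p, xhi))
            per["qs"].append(quadratic_score(p, xhi))
            per["sph"].append(spherical_score(p, xhi))
            per["rps"].append(rps(p, xhi, as_printed=as_printed))
            per["se"].append(ses(p, xhi, support))
            mu, sd = pmf_mean_std(p, support)
            per["ds"].append(dss(mu, sd, xhi, as_printed=as_printed))
    return {k: mean_score(v) for k, v in per.items()}


def score_report(entries: dict) -> pd.DataFrame:
    """Assemble a models-by-rules score table.

    ``entries`` maps a model name either to a precomputed score dict or
    to a tuple ``(ensemble, actual)``.  Lower is better in every column.
    """
    rows = {}
    for name, entry in entries.items():
        if isinstance(entry, dict):
            rows[name] = entry
        else:
            ens, actual = entry
            rows[name] = score_forecasts(ens, actual)
    return pd.DataFrame(rows).T[SCORE_COLUMNS]
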