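"""Multivariate Poisson distributions built from independent shocks.

Three constructions are provided:

* **independent** — a product of univariate Poisson marginals;
* **common shock** — the trivariate-reduction construction
  ``X_i = Y_i + Y_0`` with a single shared Poisson shock ``Y_0`` whose
  intensity equals the common covariance of every pair;
* **pairwise shock** — one shared Poisson component per pair
  ``(i, j)``, so cov(X_i, X_j) = lambda_ij, giving a richer (but still
  non-negative) covariance structure.

All pmf evaluation happens in log space with log-gamma factorials: the
shock sums run through the observed counts and overflow in natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import as_rng

__all__ = [
    "CommonShockSpec",
    "PairwiseShockSpec",
    "pmf_independent",
    "logpmf_independent",
    "pmf_common_shock",
    "logpmf_common_shock",
    "sample_common_shock",
    "moments_pairwise_shock",
    "sample_pairwise_shock",
    "truncation_bound",
]


@dataclass(frozen=True)
class CommonShockSpec:
    """Intensities for the common-shock construction.

    ``base`` holds the idiosyncratic intensities (one per series, > 0) and
    ``common`` the shared shock intensity (>= 0).  Marginally series ``i``
    is Poisson(base_i + common) and cov(X_i, X_j) = common for i != j.
    """

    base: np.ndarray
    common: float = 0.0

    def __post_init__(self) -> None:
        base = np.atleast_1d(np.asarray(self.base, dtype=float))
        if (base <= 0).any():
            raise ValueError("base intensities must be strictly positive")
        if self.common < 0:
            raise ValueError("common shock intensity must be non-negative")
        object.__setattr__(self, "base", base)

    @property
    def n(self) -> int:
        return self.base.size

    @property
    def marginal_means(self) -> np.ndarray:
        return self.base + self.common


@dataclass(frozen=True)
class PairwiseShockSpec:
    """Intensities for the pairwise-shock construction.

    ``individual`` holds lambda_i (one per series); ``pairwise`` maps the
    pair ``(i, j)`` with i < j (0-based) to the shared intensity lambda_ij.
    Marginally series ``i`` is Poisson(lambda_i + sum_j lambda_ij) and the
    covariance matrix has lambda_ij off the diagonal.
    """

    individual: np.ndarray
    pairwise: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ind = np.atleast_1d(np.asarray(self.individual, dtype=float))
        if (ind < 0).any():
            raise ValueError("individual intensities must be non-negative")
        pw = {}
        for (i, j), lam in dict(self.pairwise).items():
            if lam < 0:
                raise ValueError("pairwise intensities must be non-negative")
            if not (0 <= i < j < ind.size):
                raise ValueError(f"invalid pair ({i}, {j}) for n={ind.size}")
            pw[(int(i), int(j))] = float(lam)
        object.__setattr__(self, "individual", ind)
        object.__setattr__(self, "pairwise", pw)

    @property
    def n(self) -> int:
        return self.individual.size


def _validate_counts(x: np.ndarray) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x))
    if not np.issubdtype(x.dtype, np.integer):
        if not np.allclose(x, np.round(x)):
            raise ValueError("counts must be integers")
        x = np.round(x).astype(np.int64)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    return x.astype(np.int64)


def _poisson_logpmf(x: np.ndarray, lam: np.ndarray) -> np.ndarray:
    return x * np.log(lam) - lam - gammaln(x + 1.0)


def logpmf_independent(x, lam) -> float:
    """Log joint pmf of independent Poisson counts."""
    x = _validate_counts(x)
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if (lam <= 0).any():
        raise ValueError("intensities must be strictly positive")
    return float(_poisson_logpmf(x, lam).sum())


def pmf_independent(x, lam) -> float:
    """Joint pmf of independent Poisson counts (product of marginals)."""
    return float(np.exp(logpmf_independent(x, lam)))


def logpmf_common_shock(x, spec: CommonShockSpec) -> float:
    """Log joint pmf under the common-shock construction.

    Evaluates the finite sum over the shock count k = 0..min(x):
    each term is the product of Poisson(x_i - k; base_i) marginals times
    Poisson(k; common), accumulated with log-sum-exp.  Written in the
    binomial form (log space) rather than as an explicit convolution so
    that the convolution serves as an independent cross-check.
    """
    x = _validate_counts(x)
    if x.size != spec.n:
        raise ValueError("count vector length must match spec dimension")
    lam, lam0 = spec.base, spec.common
    base_log = float(_poisson_logpmf(x, lam).sum()) - lam0
    if lam0 == 0.0:
        return base_log
    m = int(x.min())
    ks = np.arange(m + 1)
    # term_k = (k!)^(n-1) * prod_i C(x_i, k) * (lam0 / prod lam)^k, in logs
    log_binom = sum(
        gammaln(xi + 1.0) - gammaln(ks + 1.0) - gammaln(xi - ks + 1.0) for xi in x
    )
    log_terms = (
        log_binom
        + (spec.n - 1) * gammaln(ks + 1.0)
        + ks * (np.log(lam0) - np.log(lam).sum())
    )
    return base_log + float(logsumexp(log_terms))


def pmf_common_shock(x, spec: CommonShockSpec) -> float:
    """Joint pmf under the common-shock construction."""
    return float(np.exp(logpmf_common_shock(x, spec)))


def sample_common_shock(
    spec: CommonShockSpec, size: int, rng=None
) -> np.ndarray:
    """Draw ``size`` vectors: X_i = Y_i + Y_0 with independent Poissons.

    Returns an integer matrix of shape (size, n).
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = as_rng(rng)
    base = rng.poisson(spec.base, size=(size, spec.n))
    if spec.common > 0:
        base = base + rng.poisson(spec.common, size=(size, 1))
    return base


def moments_pairwise_shock(spec: PairwiseShockSpec):
    """Mean vector and covariance matrix of the pairwise-shock law.

    mean_i = lambda_i + sum_{j != i} lambda_ij; the covariance matrix has
    the means on its diagonal (equi-dispersion) and lambda_ij off it.
    """
    n = spec.n
    mean = spec.individual.copy()
    cov = np.zeros((n, n))
    for (i, j), lam in spec.pairwise.items():
        mean[i] += lam
        mean[j] += lam
        cov[i, j] = cov[j, i] = lam
    np.fill_diagonal(cov, mean)
    return mean, cov


def sample_pairwise_shock(
    spec: PairwiseShockSpec, size: int, rng=None
) -> np.ndarray:
    """Draw ``size`` vectors by explicit summation of shared components."""
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = as_rng(rng)
    n = spec.n
    out = rng.poisson(np.where(spec.individual > 0, spec.individual, 0.0), size=(size, n))
    out[:, spec.individual == 0] = 0
    for (i, j), lam in spec.pairwise.items():
        if lam > 0:
            shared = rng.poisson(lam, size=size)
            out[:, i] += shared
            out[:, j] += shared
    return out


def truncation_bound(marginal_means: np.ndarray, tail: float = 1e-12) -> np.ndarray:
    """Component-wise support bound leaving marginal tail mass < ``tail``.

    Uses the Poisson quantile of each marginal mean; summing a joint pmf
    over the box [0, bound] captures all but at most ``n * tail`` mass.
    """
    from scipy.stats import poisson

    means = np.atleast_1d(np.asarray(marginal_means, dtype=float))
    return poisson.ppf(1.0 - tail, means).astype(np.int64) + 1


def all_pairs(n: int):
    """All index pairs (i, j) with i < j for an n-variate spec."""
    return list(combinations(range(n), 2))
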