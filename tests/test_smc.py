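"""Particle filter and smoother against exact degenerate and Kalman oracles."""

import numpy as np
import pytest
from scipy.stats import chi2, poisson

from countcast import smc, ssm
from countcast.smc import FilterDegeneracyError, bootstrap_pf, ffbs, resample
from countcast.ssm import SsmParams

from conftest import (
    kalman_filter_loglik,
    kalman_smoother_means,
    simulate_linear_gaussian,
)

PHI = np.array([[0.5, 0.0], [0.3, 0.5]])
SIGMA = np.array([[0.25, 0.075], [0.075, 0.25]])


class TestResample:
    def test_uniform_weights_chi_square(self, rng):
        N = 8
        counts = np.zeros(N)
        reps = 10_000
        idx = np.concatenate(
            [resample(np.full(N, 1 / N), rng, "multinomial") for _ in range(reps // N)]
        )
        counts = np.bincount(idx, minlength=N)
        expected = counts.sum() / N
        stat = ((counts - expected) ** 2 / expected).sum()
        assert stat < chi2.ppf(0.999, N - 1)

    def test_point_mass_weight(self, rng):
        w = np.zeros(16)
        w[5] = 1.0
        for scheme in ("multinomial", "systematic", "stratified"):
            assert (resample(w, rng, scheme) == 5).all()

    def test_systematic_multiplicities(self, rng):
        w = np.array([0.4, 0.3, 0.2, 0.1])
        N = w.size
        for _ in range(200):
            idx = resample(w, rng, "systematic")
            counts = np.bincount(idx, minlength=N)
            assert all(
                np.floor(N * wi) <= c <= np.ceil(N * wi)
                for wi, c in zip(w, counts)
            )


class TestBootstrapFilter:
    def test_degenerate_dynamics_gives_exact_loglik(self):
        p = SsmParams([1.0, 2.0], np.zeros((2, 2)), np.zeros((2, 2)))
        x = np.random.default_rng(1).poisson([1.0, 2.0], size=(50, 2))
        out = bootstrap_pf(p, x, 100, np.random.default_rng(2), h_init=np.zeros(2))
        exact = poisson.logpmf(x, [1.0, 2.0]).sum()
        assert out.loglik == pytest.approx(exact, abs=1e-9)

    def test_matches_kalman_on_gaussian_swap(self, gaussian_obs_loglik):
        params = SsmParams([1.0, 1.0], PHI, SIGMA)
        rng = np.random.default_rng(3)
        _, ys = simulate_linear_gaussian(PHI, SIGMA, 0.3, 100, rng)
        gam = ssm.stationary_covariance(params)
        exact = kalman_filter_loglik(ys, PHI, SIGMA, 0.3, gam)
        obs = gaussian_obs_loglik(0.3, 2)
        lls = np.array(
            [
                bootstrap_pf(params, ys, 2000, np.random.default_rng(100 + s),
                             obs_loglik=obs).loglik
                for s in range(20)
            ]
        )
        assert abs(lls.mean() - exact) <= 3 * lls.std()

    def test_loglik_variance_shrinks_with_particles(self, bivariate_ssm_params):
        x, _ = ssm.simulate(bivariate_ssm_params, 80, np.random.default_rng(4))
        sds = []
        for N in (100, 400, 1600):
            lls = [
                bootstrap_pf(bivariate_ssm_params, x, N,
                             np.random.default_rng(1000 * N + s)).loglik
                for s in range(15)
            ]
            sds.append(np.std(lls))
        assert sds[2] < sds[0]

    def test_reproducible_under_fixed_seed(self, bivariate_ssm_params):
        x, _ = ssm.simulate(bivariate_ssm_params, 40, np.random.default_rng(5))
        a = bootstrap_pf(bivariate_ssm_params, x, 64, np.random.default_rng(7))
        b = bootstrap_pf(bivariate_ssm_params, x, 64, np.random.default_rng(7))
        assert a.loglik == b.loglik
        assert np.array_equal(a.particles, b.particles)
        assert np.array_equal(a.ancestors, b.ancestors)

    def test_numba_and_numpy_paths_agree(self, bivariate_ssm_params):
        if not smc._HAVE_NUMBA:
            # generic path is the only path; nothing to compare
            return
        x, _ = ssm.simulate(bivariate_ssm_params, 40, np.random.default_rng(5))
        fast = bootstrap_pf(bivariate_ssm_params, x, 64, np.random.default_rng(7))
        smc._HAVE_NUMBA = False
        try:
            slow = bootstrap_pf(bivariate_ssm_params, x, 64, np.random.default_rng(7))
        finally:
            smc._HAVE_NUMBA = True
        assert np.array_equal(fast.particles, slow.particles)
        assert np.array_equal(fast.ancestors, slow.ancestors)
        assert fast.loglik == pytest.approx(slow.loglik, abs=1e-9)

    def test_weights_normalized_and_ess_bounded(self, bivariate_ssm_params):
        x, _ = ssm.simulate(bivariate_ssm_params, 60, np.random.default_rng(6))
        out = bootstrap_pf(bivariate_ssm_params, x, 128, np.random.default_rng(8))
        assert np.allclose(out.weights.sum(axis=1), 1.0, atol=1e-12)
        assert ((out.ess >= 1.0) & (out.ess <= 128.0)).all()
        assert np.isfinite(out.loglik)

    def test_degeneracy_reports_time_step(self):
        # huge counts under a tiny intensity underflow every particle weight
        p = SsmParams([1e-8, 1e-8], np.zeros((2, 2)), 1e-12 * np.eye(2))
        x = np.full((5, 2), 100_000, dtype=np.int64)
        with pytest.raises(FilterDegeneracyError, match="t=1"):
            bootstrap_pf(p, x, 50, np.random.default_rng(9), h_init=np.zeros(2))


class TestSmoothing:
    def test_ffbs_matches_kalman_smoother(self, gaussian_obs_loglik):
        params = SsmParams([1.0, 1.0], PHI, SIGMA)
        rng = np.random.default_rng(11)
        _, ys = simulate_linear_gaussian(PHI, SIGMA, 0.3, 60, rng)
        gam = ssm.stationary_covariance(params)
        sm = kalman_smoother_means(ys, PHI, SIGMA, 0.3, gam)
        obs = gaussian_obs_loglik(0.3, 2)
        fwd = bootstrap_pf(params, ys, 2000, np.random.default_rng(12), obs_loglik=obs)
        paths = ffbs(fwd, params, 500, np.random.default_rng(13))
        assert paths.paths.shape == (500, 60, 2)
        assert np.abs(paths.mean() - sm).max() < 0.12

    def test_marginal_smoothing_weights_match_ffbs(self, gaussian_obs_loglik):
        params = SsmParams([1.0, 1.0], PHI, SIGMA)
        rng = np.random.default_rng(14)
        _, ys = simulate_linear_gaussian(PHI, SIGMA, 0.3, 40, rng)
        obs = gaussian_obs_loglik(0.3, 2)
        fwd = bootstrap_pf(params, ys, 1000, np.random.default_rng(15), obs_loglik=obs)
        W = smc.smoothing_weights(fwd, params)
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-10)
        marg = np.einsum("tN,tNn->tn", W, fwd.particles)
        gam = ssm.stationary_covariance(params)
        sm = kalman_smoother_means(ys, PHI, SIGMA, 0.3, gam)
        assert np.abs(marg - sm).max() < 0.15

    def test_smoothed_equals_filtered_at_terminal_time(self, bivariate_ssm_params):
        x, _ = ssm.simulate(bivariate_ssm_params, 30, np.random.default_rng(16))
        fwd = bootstrap_pf(bivariate_ssm_params, x, 300, np.random.default_rng(17))
        paths = ffbs(fwd, bivariate_ssm_params, 2000, np.random.default_rng(18))
        filt_mean = fwd.filtered_mean()[-1]
        assert np.allclose(paths.mean()[-1], filt_mean, atol=0.1)
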