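"""Linear INGARCH: filtering, analytic derivatives and QML recovery."""

import numpy as np
import pytest

from countcast import maci
from countcast.core import CountSeries
from countcast.maci import LinearIngarch, MaciParams


def random_admissible_params(rng, n=2):
    """Random parameter point comfortably inside the stationary region."""
    omega = rng.uniform(0.2, 1.0, n)
    A = rng.uniform(0.0, 0.25, (n, n))
    B = rng.uniform(0.0, 0.25, (n, n))
    return MaciParams(omega, A, B)


def fd_gradient(f, theta, h=1e-6):
    return np.array(
        [(f(theta + h * e) - f(theta - h * e)) / (2 * h) for e in np.eye(theta.size)]
    )


class TestFilter:
    def test_degenerate_recursion_is_constant(self):
        p = MaciParams([1.0, 2.0], np.zeros((2, 2)), np.zeros((2, 2)))
        x = np.ones((10, 2), dtype=int)
        lam = maci.filter_intensity(p, x, init=[1.0, 2.0])
        assert np.allclose(lam, [1.0, 2.0])

    def test_decoupled_series_ignores_the_other(self, rng):
        p = MaciParams([0.5, 0.5], [[0.3, 0.0], [0.2, 0.3]], [[0.3, 0.0], [0.1, 0.3]])
        x = rng.poisson(2.0, size=(50, 2))
        perm = x.copy()
        perm[:, 1] = rng.poisson(5.0, size=50)
        lam = maci.filter_intensity(p, x, init=[1.0, 1.0])
        lam_perm = maci.filter_intensity(p, perm, init=[1.0, 1.0])
        assert np.allclose(lam[:, 0], lam_perm[:, 0])

    def test_positive_path_and_bad_init_rejected(self, rng):
        p = random_admissible_params(rng)
        x = maci.simulate(p, 200, rng)
        assert (maci.filter_intensity(p, x) > 0).all()
        with pytest.raises(ValueError):
            maci.filter_intensity(p, x, init=[0.0, 1.0])

    def test_long_run_average_matches_fixed_point(self):
        p = MaciParams([1.0, 1.0], 0.3 * np.eye(2), 0.3 * np.eye(2))
        x = maci.simulate(p, 100_000, np.random.default_rng(5))
        lam = maci.filter_intensity(p, x)
        target = p.unconditional_mean()
        assert np.allclose(lam.mean(axis=0), target, rtol=0.03)


class TestStationarity:
    @pytest.mark.parametrize(
        "a, b, norm, stat",
        [(0.0, 0.0, 0.0, True), (0.6, 0.5, 1.1, False), (0.25, 0.25, 0.5, True)],
    )
    def test_diagonal_cases(self, a, b, norm, stat):
        p = MaciParams([1.0, 1.0], a * np.eye(2), b * np.eye(2))
        ok, value = maci.check_stationarity(p)
        assert ok is stat
        assert value == pytest.approx(norm, abs=1e-12)


class TestQuasiLikelihood:
    def test_constant_intensity_value(self):
        p = MaciParams([1.0], [[0.0]], [[0.0]])
        x = np.array([[1], [2]])
        assert maci.quasi_loglik(p, x, init=[1.0]) == pytest.approx(-2.0)

    def test_relabeling_invariance(self, rng):
        p = random_admissible_params(rng)
        x = maci.simulate(p, 100, rng)
        ll = maci.quasi_loglik(p, x, init=[1.0, 1.0])
        perm = MaciParams(p.omega[::-1], p.A[::-1, ::-1], p.B[::-1, ::-1])
        ll_perm = maci.quasi_loglik(perm, x.values[:, ::-1], init=[1.0, 1.0])
        assert ll == pytest.approx(ll_perm, rel=1e-12)

    def test_equals_full_likelihood_plus_factorials(self, rng):
        from scipy.special import gammaln
        from scipy.stats import poisson

        p = random_admissible_params(rng)
        x = maci.simulate(p, 30, rng)
        init = np.array([1.0, 1.0])
        lam = maci.filter_intensity(p, x, init)
        full = poisson.logpmf(x.values, lam).sum()
        assert maci.quasi_loglik(p, x, init) == pytest.approx(
            full + gammaln(x.values + 1.0).sum(), rel=1e-10
        )


class TestDerivatives:
    def test_score_matches_finite_differences(self, rng):
        init = np.array([0.8, 1.1])
        for _ in range(5):
            p = random_admissible_params(rng)
            x = maci.simulate(p, 50, rng).values

            def ll(theta):
                return maci.quasi_loglik(
                    MaciParams(*maci.unpack_theta(theta, 2)), x, init
                )

            g = maci.score(p, x, init)
            fd = fd_gradient(ll, p.theta)
            assert np.max(np.abs(g - fd) / (np.abs(fd) + 1e-8)) < 1e-5

    def test_information_matches_score_differences(self, rng):
        init = np.array([0.8, 1.1])
        p = random_admissible_params(rng)
        x = maci.simulate(p, 50, rng).values
        H, G = maci.information(p, x, init)
        assert np.allclose(H, H.T) and np.allclose(G, G.T)
        assert (np.linalg.eigvalsh(G) > -1e-8).all()
        fdH = np.array(
            [
                (
                    maci.score(MaciParams(*maci.unpack_theta(p.theta + 1e-6 * e, 2)), x, init)
                    - maci.score(MaciParams(*maci.unpack_theta(p.theta - 1e-6 * e, 2)), x, init)
                )
                / 2e-6
                for e in np.eye(p.theta.size)
            ]
        )
        # H is the negative Hessian of the quasi-log-likelihood
        assert np.max(np.abs(-H - fdH) / (np.abs(fdH) + 1e-6)) < 1e-5

    def test_omega_derivative_is_identity_when_a_zero(self):
        p = MaciParams([0.5, 0.5], np.zeros((2, 2)), 0.3 * np.eye(2))
        x = np.random.default_rng(0).poisson(1.0, (20, 2))
        # with A = 0 the omega-block of the score Jacobian is I from the
        # second step on (derivative states start at zero at t=1), so
        # d(loglik)/d(omega) = sum_{t>=2} (x_t/lam_t - 1)
        lam = maci.filter_intensity(p, x, init=[0.5, 0.5])
        expected = (x[1:] / lam[1:] - 1.0).sum(axis=0)
        assert np.allclose(maci.score(p, x, init=[0.5, 0.5])[:2], expected)


class TestSimulate:
    def test_no_dynamics_gives_iid_poisson(self, rng):
        p = MaciParams([2.0, 3.0], np.zeros((2, 2)), np.zeros((2, 2)))
        x = maci.simulate(p, 20_000, rng)
        assert np.allclose(x.values.mean(axis=0), [2.0, 3.0], atol=0.06)

    def test_sample_mean_matches_unconditional_mean(self, rng):
        p = MaciParams([0.5, 0.3], 0.2 * np.eye(2), [[0.3, 0.1], [0.0, 0.25]])
        x = maci.simulate(p, 50_000, rng)
        assert np.allclose(x.values.mean(axis=0), p.unconditional_mean(), rtol=0.05)

    def test_common_shock_induces_positive_correlation(self, rng):
        p = MaciParams([1.0, 1.0], np.zeros((2, 2)), np.zeros((2, 2)), shock=1.0)
        x = maci.simulate(p, 20_000, rng, joint="common_shock")
        assert np.corrcoef(x.values.T)[0, 1] > 0.2


class TestFit:
    def test_recovers_diagonal_truth(self):
        p = MaciParams([0.2, 0.3], np.diag([0.2, 0.3]), np.diag([0.4, 0.3]))
        x = maci.simulate(p, 2000, np.random.default_rng(21))
        fit = maci.fit_qml(x)
        assert fit.converged
        assert np.all(np.abs(fit.theta - p.theta) <= 4 * fit.se + 0.02)
        assert maci.quasi_loglik(fit.params, x) >= maci.quasi_loglik(p, x) - 1e-6

    def test_all_zero_series_flags_boundary(self):
        x = np.zeros((120, 2), dtype=int)
        x[:, 1] = np.random.default_rng(3).poisson(1.0, 120)
        with pytest.warns(UserWarning, match="lower bound"):
            fit = maci.fit_qml(CountSeries(x))
        assert fit.boundary.any()

    def test_estimator_interface(self):
        p = MaciParams([0.5, 0.5], 0.2 * np.eye(2), 0.3 * np.eye(2))
        x = maci.simulate(p, 400, np.random.default_rng(9))
        est = LinearIngarch().fit(x)
        assert est.omega_.shape == (2,)
        assert est.converged_
        lam = est.filter(x)
        assert lam.shape == (400, 2)
        one_step = est.predict(x)
        assert one_step.shape == (2,)
        # clone/get_params round trip (sklearn contract)
        from sklearn.base import clone

        est2 = clone(est)
        assert est2.get_params() == est.get_params()
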