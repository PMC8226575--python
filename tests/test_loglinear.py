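"""Log-linear count autoregression: filtering, derivatives, stability, QML."""

import numpy as np
import pytest

from countcast import loglinear as ll
from countcast.loglinear import ExplosivePathError, LogLinearIngarch, LogLinParams
from countcast.maci import unpack_theta

LL1 = LogLinParams([0.9, 0.4], np.diag([-0.5, 0.2]),
                   np.array([[0.5, 0.2], [0.0, 0.4]]))
LL2 = LogLinParams([0.2, 0.3], np.diag([0.2, 0.4]),
                   np.array([[0.5, 0.2], [0.0, 0.4]]))


class TestFilter:
    def test_zero_parameters_give_unit_intensity(self):
        p = LogLinParams([0.0, 0.0], np.zeros((2, 2)), np.zeros((2, 2)))
        nu, lam = ll.filter_nu(p, np.ones((10, 2), dtype=int), init=[0.0, 0.0])
        assert np.allclose(nu, 0.0) and np.allclose(lam, 1.0)

    def test_zero_counts_kill_feedback_term(self):
        p = LogLinParams([0.1, 0.1], np.zeros((2, 2)), np.full((2, 2), 5.0))
        nu, _ = ll.filter_nu(p, np.zeros((5, 2), dtype=int), init=[0.0, 0.0])
        # log(0 + 1) = 0, so nu_t = omega for t >= 2 regardless of B
        assert np.allclose(nu[1:], 0.1)

    def test_two_step_manual_unroll(self):
        omega = np.array([0.1, -0.2])
        A = np.array([[0.3, -0.1], [0.0, 0.2]])
        B = np.array([[0.4, 0.1], [-0.2, 0.3]])
        p = LogLinParams(omega, A, B)
        x = np.array([[2, 0], [1, 3], [0, 1]])
        nu, lam = ll.filter_nu(p, x, init=[0.0, 0.0])
        u0 = np.log(x[0] + 1.0)
        nu1 = omega + A @ np.zeros(2) + B @ u0
        nu2 = omega + A @ nu1 + B @ np.log(x[1] + 1.0)
        assert np.allclose(nu[1], nu1) and np.allclose(nu[2], nu2)
        assert np.allclose(lam, np.exp(nu))

    def test_explosive_path_names_time_point(self):
        p = LogLinParams([0.0, 0.0], 2.0 * np.eye(2), 2.0 * np.eye(2))
        x = np.full((30, 2), 1000, dtype=int)
        with pytest.raises(ExplosivePathError, match="t="):
            ll.filter_nu(p, x, init=[1.0, 1.0])

    def test_permutation_equivariance(self, rng):
        x = rng.poisson(2.0, size=(40, 2))
        nu, _ = ll.filter_nu(LL2, x, init=[0.0, 0.0])
        perm = LogLinParams(LL2.omega[::-1], LL2.A[::-1, ::-1], LL2.B[::-1, ::-1])
        nu_p, _ = ll.filter_nu(perm, x[:, ::-1], init=[0.0, 0.0])
        assert np.allclose(nu, nu_p[:, ::-1])


class TestStability:
    def test_reduces_to_b_norm_when_a_zero(self):
        p = LogLinParams([0.0, 0.0], np.zeros((2, 2)), 0.7 * np.eye(2))
        stable, total = ll.check_stability(p)
        assert stable and total == pytest.approx(0.7, abs=1e-9)

    @pytest.mark.parametrize("a, b, expected", [(0.5, 0.4, 0.8), (0.3, 0.5, 5 / 7)])
    def test_diagonal_geometric_series(self, a, b, expected):
        p = LogLinParams([0.0, 0.0], a * np.eye(2), b * np.eye(2))
        stable, total = ll.check_stability(p)
        assert stable and total == pytest.approx(expected, abs=1e-6)

    def test_unstable_detected(self):
        p = LogLinParams([0.0, 0.0], 0.5 * np.eye(2), 0.8 * np.eye(2))
        stable, total = ll.check_stability(p)
        assert stable is False and total >= 1.0


class TestDerivatives:
    def test_score_and_information_match_finite_differences(self, rng):
        init = np.array([0.1, 0.2])
        for _ in range(5):
            p = LogLinParams(
                rng.uniform(-0.3, 0.3, 2),
                rng.uniform(-0.3, 0.3, (2, 2)),
                rng.uniform(-0.3, 0.3, (2, 2)),
            )
            x = rng.poisson(2.0, size=(50, 2))

            def qll(theta):
                return ll.quasi_loglik(
                    LogLinParams(*unpack_theta(theta, 2)), x, init
                )

            g = ll.score(p, x, init)
            fd = np.array(
                [
                    (qll(p.theta + 1e-6 * e) - qll(p.theta - 1e-6 * e)) / 2e-6
                    for e in np.eye(10)
                ]
            )
            assert np.max(np.abs(g - fd) / (np.abs(fd) + 1e-8)) < 1e-5
            H, G = ll.information(p, x, init)
            assert (np.linalg.eigvalsh(G) > -1e-8).all()
            fdH = np.array(
                [
                    (
                        ll.score(LogLinParams(*unpack_theta(p.theta + 1e-6 * e, 2)), x, init)
                        - ll.score(LogLinParams(*unpack_theta(p.theta - 1e-6 * e, 2)), x, init)
                    )
                    / 2e-6
                    for e in np.eye(10)
                ]
            )
            assert np.max(np.abs(-H - fdH) / (np.abs(fdH) + 1e-6)) < 1e-5


class TestSimulate:
    def test_zero_parameters_give_unit_poisson(self, rng):
        p = LogLinParams([0.0, 0.0], np.zeros((2, 2)), np.zeros((2, 2)))
        x = ll.simulate(p, 20_000, rng)
        assert np.allclose(x.values.mean(axis=0), 1.0, atol=0.05)

    @pytest.mark.parametrize("params", [LL1, LL2], ids=["LL1", "LL2"])
    def test_benchmark_rows_are_non_explosive(self, params, rng):
        x = ll.simulate(params, 500, rng)
        assert x.values.max() < 10_000

    def test_zero_b21_blocks_feedback(self, rng):
        # series 2's log-intensity never responds to series 1's counts
        x1 = ll.simulate(LL2, 200, np.random.default_rng(4)).values
        nu_a, _ = ll.filter_nu(LL2, x1, init=[0.0, 0.0])
        x2 = x1.copy()
        x2[:, 0] = 0
        nu_b, _ = ll.filter_nu(LL2, x2, init=[0.0, 0.0])
        assert np.allclose(nu_a[:, 1], nu_b[:, 1])


class TestFit:
    def test_recovers_ll2_within_sandwich_bands(self):
        x = ll.simulate(LL2, 2000, np.random.default_rng(7))
        fit = ll.fit_qml(x, n_starts=1, rng=np.random.default_rng(0))
        assert fit.converged
        assert np.all(np.abs(fit.theta - LL2.theta) <= 4 * fit.se + 0.02)
        assert fit.loglik >= ll.quasi_loglik(LL2, x) - 1e-6
        # score near zero at the optimum (first-order condition, scaled)
        assert np.max(np.abs(fit.score)) / len(x.values) < 1e-4

    def test_recovers_negative_feedback_sign(self):
        x = ll.simulate(LL1, 2000, np.random.default_rng(11))
        fit = ll.fit_qml(x, n_starts=1, rng=np.random.default_rng(0))
        a11 = fit.theta[2]
        assert a11 < 0
        assert a11 == pytest.approx(-0.5, abs=0.25)

    def test_dynamics_shrink_on_iid_data(self):
        rng = np.random.default_rng(13)
        norms = []
        for T in (300, 3000):
            x = rng.poisson(1.0, size=(T, 2))
            fit = ll.fit_qml(x, n_starts=1, rng=np.random.default_rng(1))
            norms.append(np.linalg.norm(fit.theta[2:]))
        assert norms[1] < norms[0]

    def test_estimator_interface(self):
        x = ll.simulate(LL2, 500, np.random.default_rng(2))
        est = LogLinearIngarch(n_starts=2, random_state=0).fit(x)
        assert est.converged_
        nu, lam = est.filter(x)
        assert lam.shape == (500, 2) and (lam > 0).all()
        assert est.predict(x).shape == (2,)
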