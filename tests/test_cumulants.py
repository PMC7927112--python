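import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from openchain.cumulants import (lambda_matrix, mean_step, normalized_time_corr,
                                 propagate, space_correlations, stationary_mean,
                                 stationary_variance, stationary_variance_series,
                                 two_time_cov, var_step)
from openchain.fixtures import one_vertex, triangle, triangle_Qk
from openchain.protocols import poisson_product_protocol

from conftest import random_open_chain


class TestLambdaMatrix:
    def test_empty_system_no_redistribution_noise(self):
        Q = np.array([[0.1, 0.2], [0.3, 0.4]])
        np.testing.assert_array_equal(lambda_matrix(np.zeros(2), Q), 0.0)

    def test_scalar_case_is_binomial_variance(self):
        # one state: Lambda = mu q (1 - q), the variance of thinned retention
        mu, q = 7.0, 0.3
        assert lambda_matrix([mu], [[q]])[0, 0] == pytest.approx(mu * q * (1 - q), abs=1e-14)

    def test_triangle_stationary_lambda_off_diagonal(self):
        # at mu_bar = 1/(2-4q) per state, off-diagonal entries are -q^2/(2-4q)
        q = 0.2
        fx = triangle(0.5, q)
        mu_bar = fx.closed_forms["mu_bar"]
        lam = lambda_matrix(mu_bar, fx.chain.Q)
        expected_off = -(q**2) / (2 - 4 * q)
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert lam[i, j] == pytest.approx(expected_off, abs=1e-14)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), S=st.integers(1, 5))
    def test_symmetric_psd(self, seed, S):
        rng = np.random.default_rng(seed)
        chain = random_open_chain(rng, S)
        mu = rng.uniform(0, 5, size=S)
        lam = lambda_matrix(mu, chain.Q)
        np.testing.assert_allclose(lam, lam.T, atol=1e-14)
        assert np.all(np.linalg.eigvalsh(lam) > -1e-12)


class TestRecursions:
    def test_mean_step_from_empty(self):
        eps = np.array([0.3, 0.7])
        Q = np.zeros((2, 2))
        np.testing.assert_array_equal(mean_step(np.zeros(2), eps, Q), eps)

    def test_no_retention_gives_arrival_moments(self):
        # Q = 0: occupancy is exactly the fresh arrivals each step
        eps, delta = np.array([1.0, 2.0]), np.diag([1.0, 2.0])
        Q = np.zeros((2, 2))
        np.testing.assert_array_equal(mean_step(np.zeros(2), eps, Q), eps)
        np.testing.assert_array_equal(var_step(np.zeros((2, 2)), delta, np.zeros(2), Q), delta)

    def test_scalar_fixed_point(self):
        p, q = 0.4, 0.6
        mu = p / (1 - q)
        assert mean_step([mu], [p], [[q]])[0] == pytest.approx(mu, abs=1e-14)

    def test_iteration_converges_to_stein_solution(self):
        """200 recursion steps from an empty triangle system land on the
        direct Stein solve to 1e-10."""
        fx = triangle(0.40, 0.45)
        eps, delta = fx.protocol.mean(), fx.protocol.cov()
        state = propagate(eps, delta, fx.chain.Q, 200)
        mu_bar = stationary_mean(eps, fx.chain.Q)
        sigma_bar = stationary_variance(delta, mu_bar, fx.chain.Q)
        np.testing.assert_allclose(state.mu, mu_bar, atol=1e-10)
        np.testing.assert_allclose(state.sigma, sigma_bar, atol=1e-10)

    def test_fixed_point_consistency(self):
        fx = triangle(0.3, 0.25)
        eps, delta = fx.protocol.mean(), fx.protocol.cov()
        mu_bar = stationary_mean(eps, fx.chain.Q)
        sigma_bar = stationary_variance(delta, mu_bar, fx.chain.Q)
        np.testing.assert_allclose(mean_step(mu_bar, eps, fx.chain.Q), mu_bar, atol=1e-12)
        np.testing.assert_allclose(var_step(sigma_bar, delta, mu_bar, fx.chain.Q),
                                   sigma_bar, atol=1e-12)


class TestStationarySolutions:
    def test_scalar_mean(self):
        assert stationary_mean([0.5], [[0.5]])[0] == pytest.approx(1.0, abs=1e-14)

    def test_triangle_uniform_mean(self):
        for q in (0.1, 0.25, 0.45):
            fx = triangle(0.5, q)
            np.testing.assert_allclose(stationary_mean(fx.protocol.mean(), fx.chain.Q),
                                       np.full(3, 1 / (2 - 4 * q)), atol=1e-13)

    def test_no_retention_mean_is_arrival_mean(self):
        eps = np.array([1.0, 2.0])
        np.testing.assert_allclose(stationary_mean(eps, np.zeros((2, 2))), eps, atol=1e-15)

    def test_no_retention_variance_is_arrival_variance(self):
        delta = np.array([[0.5, 0.1], [0.1, 0.8]])
        np.testing.assert_allclose(
            stationary_variance(delta, np.zeros(2), np.zeros((2, 2))), delta, atol=1e-15)

    def test_scalar_variance_closed_form(self):
        p, q = 0.5, 0.5
        mu = p / (1 - q)
        sigma = stationary_variance([[p * (1 - p)]], [mu], [[q]])
        assert sigma[0, 0] == pytest.approx(p / (1 - q) - p**2 / (1 - q**2), abs=1e-13)

    def test_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="spectral radius"):
            stationary_mean([1.0, 1.0], np.array([[0.5, 0.5], [0.5, 0.5]]))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), S=st.integers(1, 5))
    def test_poisson_arrivals_give_poisson_marginals(self, seed, S):
        """Product-Poisson stationarity: with independent Poisson arrivals the
        stationary covariance is exactly diag(mu_bar)."""
        rng = np.random.default_rng(seed)
        chain = random_open_chain(rng, S)
        lam = rng.uniform(0.1, 3.0, size=S)
        mu_bar = stationary_mean(lam, chain.Q)
        sigma_bar = stationary_variance(np.diag(lam), mu_bar, chain.Q)
        np.testing.assert_allclose(sigma_bar, np.diag(mu_bar), atol=1e-12)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000), S=st.integers(1, 5))
    def test_series_equals_direct_solve(self, seed, S):
        rng = np.random.default_rng(seed)
        chain = random_open_chain(rng, S)
        proto = poisson_product_protocol(rng.uniform(0.1, 2.0, size=S))
        mu_bar = stationary_mean(proto.mean(), chain.Q)
        direct = stationary_variance(proto.cov(), mu_bar, chain.Q)
        series = stationary_variance_series(proto.cov(), mu_bar, chain.Q)
        np.testing.assert_allclose(direct, series, atol=1e-10)


class TestCorrelations:
    def test_diagonal_covariance_uncorrelated(self):
        kappa = space_correlations(np.diag([2.0, 3.0]))
        np.testing.assert_allclose(kappa, np.eye(2), atol=1e-15)

    def test_symmetric_bounded_unit_diagonal(self):
        fx = triangle(0.40, 0.45)
        mu_bar = stationary_mean(fx.protocol.mean(), fx.chain.Q)
        sigma_bar = stationary_variance(fx.protocol.cov(), mu_bar, fx.chain.Q)
        kappa = space_correlations(sigma_bar)
        np.testing.assert_allclose(kappa, kappa.T, atol=1e-14)
        np.testing.assert_allclose(np.diag(kappa), 1.0, atol=1e-14)
        assert np.all(np.abs(kappa) <= 1 + 1e-14)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            space_correlations(np.diag([1.0, 0.0]))


class TestTwoTimeCovariance:
    def test_lag_zero_identity(self):
        sigma = np.array([[2.0, 0.5], [0.5, 1.0]])
        Q = np.array([[0.1, 0.2], [0.0, 0.3]])
        np.testing.assert_array_equal(two_time_cov(sigma, Q, 0), sigma)

    def test_scalar_geometric_decay(self):
        p, q = 0.5, 0.5
        var = p / (1 - q) - p**2 / (1 - q**2)
        for s in range(6):
            assert two_time_cov([[var]], [[q]], s)[0, 0] == pytest.approx(var * q**s, abs=1e-15)

    def test_decay_to_zero_at_rate_rho(self):
        fx = triangle(0.40, 0.45)
        mu_bar = stationary_mean(fx.protocol.mean(), fx.chain.Q)
        sigma_bar = stationary_variance(fx.protocol.cov(), mu_bar, fx.chain.Q)
        norms = [np.abs(two_time_cov(sigma_bar, fx.chain.Q, s)).max() for s in (0, 20, 40, 80)]
        # geometric decay at rate rho = 0.9: rho^80 ~ 2e-4
        assert norms[3] < 1e-3 * norms[0]
        assert norms[1] > norms[2] > norms[3]

    def test_normalized_corr_lag_zero_is_kappa(self):
        fx = triangle(0.40, 0.45)
        mu_bar = stationary_mean(fx.protocol.mean(), fx.chain.Q)
        sigma_bar = stationary_variance(fx.protocol.cov(), mu_bar, fx.chain.Q)
        np.testing.assert_allclose(normalized_time_corr(sigma_bar, fx.chain.Q, 0),
                                   space_correlations(sigma_bar), atol=1e-14)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            two_time_cov(np.eye(2), np.zeros((2, 2)), -1)


class TestTrianglePower:
    @pytest.mark.parametrize("q", [0.1, 0.3, 0.45])
    def test_closed_form_matches_repeated_multiplication(self, q):
        fx = triangle(0.5, q)
        for k in range(21):
            np.testing.assert_allclose(triangle_Qk(q, k),
                                       np.linalg.matrix_power(fx.chain.Q, k), atol=1e-12)

    def test_small_powers(self):
        q = 0.3
        np.testing.assert_allclose(triangle_Qk(q, 0), np.eye(3), atol=1e-15)
        np.testing.assert_allclose(triangle_Qk(q, 1), triangle(0.5, q).chain.Q, atol=1e-15)
        # (J - I)^2 = J + I for the 3x3 all-ones J
        expected = q**2 * (np.ones((3, 3)) + np.eye(3))
        np.testing.assert_allclose(triangle_Qk(q, 2), expected, atol=1e-15)
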