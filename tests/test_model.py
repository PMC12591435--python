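"""Unit tests for the matrix-F model core: reparameterization, conditional
modes, GEM fitting and the Gibbs sampler."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hmfgraph.model import (
    Hyperparameters,
    SampleMoments,
    alpha_lower_bound,
    conditional_mode_omega,
    conditional_mode_phi,
    conditional_params_omega,
    conditional_params_phi,
    delta_from_beta,
    gem_fit,
    gibbs_fit,
    nu_from_alpha,
    sample_moments,
    update_b_diag,
    _wishart_bartlett,
)


class TestReparameterization:
    @pytest.mark.parametrize(
        "alpha,n,p,expected",
        [(0.0, 100, 10, 11.0), (0.5, 100, 10, 111.0), (0.9, 10, 5, 96.0)],
    )
    def test_nu_values(self, alpha, n, p, expected):
        assert nu_from_alpha(alpha, n, p) == pytest.approx(expected)

    @pytest.mark.parametrize("alpha", [-0.1, 1.0, 1.5])
    def test_nu_domain_errors(self, alpha):
        with pytest.raises(ValueError):
            nu_from_alpha(alpha, 100, 10)

    @given(st.floats(0.01, 0.98), st.integers(5, 500), st.integers(2, 50))
    @settings(max_examples=50, deadline=None)
    def test_nu_round_trip(self, alpha, n, p):
        nu = nu_from_alpha(alpha, n, p)
        assert (nu - p - 1) / (nu + n - p - 1) == pytest.approx(alpha, rel=1e-9)

    @pytest.mark.parametrize(
        "beta,nu,p,expected", [(0.9, 111.0, 10, 891.0), (0.5, 20.0, 5, 10.0)]
    )
    def test_delta_values(self, beta, nu, p, expected):
        assert delta_from_beta(beta, nu, p) == pytest.approx(expected)

    def test_delta_round_trip(self):
        for beta in (0.6, 0.9, 0.99):
            delta = delta_from_beta(beta, 111.0, 10)
            assert (delta + 9) / (delta + 109) == pytest.approx(beta, rel=1e-12)

    def test_delta_degenerate_nu(self):
        # nu = p + 1 forces beta = 1 regardless of delta: inversion must fail
        with pytest.raises(ValueError, match="not identifiable"):
            delta_from_beta(0.9, 6.0, 5)

    def test_delta_inadmissible_beta(self):
        with pytest.raises(ValueError, match="admissible"):
            delta_from_beta(0.5, 111.0, 100)

    def test_alpha_lower_bound_boundary(self):
        # just above the bound delta is positive, just below it is not
        beta, n, p = 0.9, 300, 100
        a0 = alpha_lower_bound(beta, n, p)
        nu_hi = nu_from_alpha(a0 * 1.01, n, p)
        assert delta_from_beta(beta, nu_hi, p) > 0
        with pytest.raises(ValueError):
            delta_from_beta(beta, nu_from_alpha(a0 * 0.99, n, p), p)


class TestSampleMoments:
    def test_identical_rows_zero_covariance(self):
        Y = np.tile([1.0, 2.0, 3.0], (5, 1))
        m = sample_moments(Y, standardize=False)
        assert np.allclose(m.S, 0.0)

    def test_hand_computed_two_by_two(self):
        m = sample_moments(np.array([[1.0, 2.0], [3.0, 4.0]]), standardize=False)
        assert np.allclose(m.S, [[1.0, 1.0], [1.0, 1.0]])

    def test_divisor_is_n_and_diag_unit_when_standardized(self, rng):
        Y = rng.standard_normal((40, 6)) * 3.0 + 1.0
        m = sample_moments(Y, standardize=True)
        assert np.allclose(np.diag(m.S), 1.0)
        assert m.standardized

    def test_monte_carlo_consistency(self):
        rng = np.random.default_rng(0)
        sigma = np.array([[2.0, 0.6], [0.6, 1.0]])
        n = 50_000
        Y = rng.multivariate_normal([0, 0], sigma, size=n)
        m = sample_moments(Y, standardize=False)
        # elementwise 3-standard-error band for covariance entries
        se = 3 * np.sqrt((np.outer(np.diag(sigma), np.diag(sigma)) + sigma**2) / n)
        assert np.all(np.abs(m.S - sigma) < se)

    def test_constant_column_error_names_column(self):
        Y = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match=r"\[1\]"):
            sample_moments(Y, standardize=True)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            SampleMoments(S=np.array([[1.0, 0.5], [0.0, 1.0]]), n=10, p=2,
                          standardized=False)


class TestConditionalModes:
    def test_omega_mode_limits(self, rng):
        A = rng.standard_normal((5, 5))
        phi = A @ A.T + 5 * np.eye(5)
        B = rng.standard_normal((5, 5))
        S = B @ B.T / 5 + np.eye(5)
        assert np.allclose(conditional_mode_omega(phi, S, 1.0), np.linalg.inv(phi))
        assert np.allclose(conditional_mode_omega(phi, S, 0.0), np.linalg.inv(S))
        assert np.allclose(conditional_mode_omega(np.eye(4), np.eye(4), 0.3), np.eye(4))

    def test_omega_mode_singular_blend(self):
        S = np.ones((3, 3))  # rank one
        with pytest.raises(np.linalg.LinAlgError, match="larger alpha"):
            conditional_mode_omega(np.eye(3), S, 0.0)

    def test_phi_mode_limits(self, rng):
        A = rng.standard_normal((4, 4))
        omega = A @ A.T + 4 * np.eye(4)
        assert np.allclose(conditional_mode_phi(omega, np.ones(4), 1.0), np.eye(4))
        assert np.allclose(conditional_mode_phi(omega, np.ones(4), 0.0),
                           np.linalg.inv(omega))

    def test_phi_mode_diagonal_closure(self):
        omega = np.diag([1.0, 2.0, 4.0])
        out = conditional_mode_phi(omega, np.array([1.0, 0.5, 2.0]), 0.7)
        assert np.allclose(out, np.diag(np.diag(out)))

    def test_phi_mode_rejects_nonpositive_b(self):
        with pytest.raises(ValueError, match="positive"):
            conditional_mode_phi(np.eye(3), np.array([1.0, -1.0, 1.0]), 0.5)


class TestBDiagUpdate:
    def test_printed_formula_arithmetic(self):
        # delta + p - 1 = 1000, phi_ii = 1: b = (500.001 - 1) / 500.001
        out = update_b_diag(np.array([1.0]), delta=1000 - 0, p=1, eps1=0.001, eps2=0.001)
        assert out[0] == pytest.approx((500.001 - 1) / 500.001, rel=1e-12)

    def test_rate_dominates_for_large_phi(self):
        out = update_b_diag(np.array([1e12]), delta=50.0, p=10)
        assert out[0] < 1e-10

    def test_matches_grid_search_mode_of_gamma_density(self):
        delta, p, phi_ii = 30.0, 8, 0.7
        shape = (delta + p - 1) / 2 + 0.001
        rate = (delta + p - 1) * phi_ii / 2 + 0.001
        grid = np.linspace(1e-6, 10, 400_000)
        logpdf = stats.gamma.logpdf(grid, a=shape, scale=1 / rate)
        b_grid = grid[np.argmax(logpdf)]
        b = update_b_diag(np.array([phi_ii]), delta, p)[0]
        assert b == pytest.approx(b_grid, abs=5e-5)

    def test_shape_at_most_one_errors(self):
        with pytest.raises(ValueError, match="mode undefined"):
            update_b_diag(np.array([1.0]), delta=0.5, p=2, eps1=0.001)


def _reference_fixed_point(S, n, p, alpha, beta, iters=5000, tol=1e-12):
    """Independent implementation of the conditional-mode iteration, using
    plain numpy inverses and scalar loops."""
    nu = p + 1 + alpha * n / (1 - alpha)
    delta = (beta * (nu - 2) - (p - 1)) / (1 - beta)
    B = np.eye(p)
    phi = np.eye(p)
    omega = np.eye(p)
    for _ in range(iters):
        for i in range(p):
            shape = (delta + p - 1) / 2 + 0.001
            rate = (delta + p - 1) * phi[i, i] / 2 + 0.001
            B[i, i] = (shape - 1) / rate
        phi = np.linalg.inv(beta * B + (1 - beta) * omega)
        omega_new = np.linalg.inv(alpha * phi + (1 - alpha) * S)
        if np.linalg.norm(omega_new - omega) < tol:
            omega = omega_new
            break
        omega = omega_new
    return omega


class TestGem:
    def test_diagonal_closure(self):
        m = SampleMoments(S=np.eye(5), n=100, p=5, standardized=True)
        fit = gem_fit(m, Hyperparameters(alpha=0.5, beta=0.9))
        off = fit.omega_hat[~np.eye(5, dtype=bool)]
        assert np.all(off == 0.0)

    def test_matches_independent_fixed_point_p3(self):
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((30, 3))
        m = sample_moments(Y)
        hp = Hyperparameters(alpha=0.5, beta=0.9, stop_criterion=1e-13,
                             max_iters=20000)
        fit = gem_fit(m, hp)
        ref = _reference_fixed_point(m.S, m.n, m.p, 0.5, 0.9)
        assert np.allclose(fit.omega_hat, ref, atol=1e-8)

    def test_fixed_point_consistency_and_pd(self, small_fit):
        fit = small_fit
        hp = fit.hyperparameters
        omega_re = conditional_mode_omega(fit.phi_hat, fit.moments.S, hp.alpha)
        rel = np.linalg.norm(fit.omega_hat - omega_re, "fro") / np.linalg.norm(
            fit.omega_hat, "fro")
        assert rel < 1e-4  # one extra sweep moves Omega by < O(stop tolerance)
        phi_re = conditional_mode_phi(fit.omega_hat, fit.b_diag, hp.beta)
        assert np.linalg.norm(fit.phi_hat - phi_re, "fro") < 1e-3
        assert np.linalg.eigvalsh(fit.omega_hat)[0] > 0
        assert np.linalg.eigvalsh(fit.phi_hat)[0] > 0

    def test_monotone_shrinkage_in_beta(self, small_dataset):
        _, Y = small_dataset
        m = sample_moments(Y)
        maxima = []
        for beta in (0.5, 0.7, 0.9, 0.97):
            fit = gem_fit(m, Hyperparameters(alpha=0.8, beta=beta))
            off = fit.omega_hat[~np.eye(m.p, dtype=bool)]
            maxima.append(np.max(np.abs(off)))
        assert all(a >= b - 1e-9 for a, b in zip(maxima, maxima[1:]))

    def test_deterministic_and_warm_start_consistent(self, small_dataset):
        _, Y = small_dataset
        m = sample_moments(Y)
        hp = Hyperparameters(alpha=0.5)
        f1, f2 = gem_fit(m, hp), gem_fit(m, hp)
        assert np.array_equal(f1.omega_hat, f2.omega_hat)
        f3 = gem_fit(m, hp, init=(f1.omega_hat, f1.phi_hat, f1.b_diag))
        assert np.allclose(f3.omega_hat, f1.omega_hat, atol=1e-5)


class TestGibbs:
    def test_conditional_modes_reproduce_gem_updates(self, rng):
        # (df - p - 1) * scale of each Wishart conditional is exactly the
        # corresponding GEM update, so the mode-following chain IS the GEM.
        p, n = 6, 40
        Y = rng.standard_normal((n, p))
        m = sample_moments(Y)
        hp = Hyperparameters(alpha=0.6, beta=0.9)
        nu, delta = hp.nu(n, p), hp.delta(n, p)
        A = rng.standard_normal((p, p))
        phi = A @ A.T / p + np.eye(p)
        b_diag = rng.uniform(0.5, 2.0, p)
        omega = conditional_mode_omega(phi, m.S, hp.alpha)

        df_o, scale_o = conditional_params_omega(phi, m.S, n, nu, p)
        assert np.allclose((df_o - p - 1) * scale_o, omega, atol=1e-10)
        df_p, scale_p = conditional_params_phi(omega, b_diag, nu, delta, p)
        assert np.allclose((df_p - p - 1) * scale_p,
                           conditional_mode_phi(omega, b_diag, hp.beta), atol=1e-10)

    def test_bartlett_sampler_mean(self, rng):
        scale = np.array([[1.0, 0.3], [0.3, 0.5]])
        df = 10.0
        draws = np.mean([_wishart_bartlett(rng, df, scale) for _ in range(4000)], axis=0)
        assert np.allclose(draws, df * scale, rtol=0.05)

    def test_empirical_variance_matches_normal_approximation(self):
        from hmfgraph.edges import edge_variances
        from hmfgraph.simulate import generate_scale_free, sample_mvn

        net = generate_scale_free(10, "fixed", seed=4)
        Y = sample_mvn(net, 50, seed=5)
        m = sample_moments(Y)
        hp = Hyperparameters(alpha=0.5)
        fit = gem_fit(m, hp)
        draws = gibbs_fit(m, hp, n_draws=5000, burn_in=2500, seed=6)
        emp = draws.omega_draws.var(axis=0)
        app = edge_variances(fit)
        iu = np.triu_indices(10, 1)
        rel = np.abs(emp[iu] / app[iu] - 1)
        assert np.mean(rel < 0.2) > 0.8

    def test_posterior_mean_approaches_inverse_sample_covariance(self):
        from hmfgraph.simulate import generate_scale_free, sample_mvn

        net = generate_scale_free(5, "fixed", seed=10)
        Y = sample_mvn(net, 5000, seed=11)
        m = sample_moments(Y)
        draws = gibbs_fit(m, Hyperparameters(alpha=0.02), n_draws=2000,
                          burn_in=1000, seed=12)
        Sinv = np.linalg.inv(m.S)
        pm = draws.omega_draws.mean(axis=0)
        assert np.max(np.abs(pm - Sinv) / (np.abs(Sinv) + 0.05)) < 0.15

    def test_reproducible_and_positive_definite(self, rng):
        Y = rng.standard_normal((30, 5))
        m = sample_moments(Y)
        hp = Hyperparameters(alpha=0.5)
        d1 = gibbs_fit(m, hp, n_draws=50, burn_in=20, seed=42)
        d2 = gibbs_fit(m, hp, n_draws=50, burn_in=20, seed=42)
        assert np.array_equal(d1.omega_draws, d2.omega_draws)
        for k in range(0, 50, 10):
            assert np.linalg.eigvalsh(d1.omega_draws[k])[0] > 0
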