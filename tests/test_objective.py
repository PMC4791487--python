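"""Likelihood, priors, gradients and the metric tensor."""

import numpy as np
import pytest
from scipy.integrate import quad

from inputest import (
    InputFunction,
    NoiseModel,
    PosteriorSpec,
    bspline_basis,
    derivative_penalty,
    entropy_penalty,
    guo_hall_system,
    kl_basis,
    linear_test_system,
    metric_tensor,
    piecewise_constant_basis,
    simulate,
)
from inputest.synthgen import case2_schedule


def _finite_diff_grad(f, x, h=1e-5):
    g = np.zeros_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


class TestDataMisfit:
    def test_zero_at_perfect_fit(self, linear_setup):
        s = linear_setup
        spec = PosteriorSpec(
            s.system, s.times, s.spec.predictions(s.oracle.mean),
            NoiseModel("additive", 1.0), s.template, penalty_order=1, tau=1.0,
        )
        assert spec.data_misfit(s.oracle.mean) == pytest.approx(0.0, abs=1e-12)

    def test_additive_unit_residuals(self):
        nm = NoiseModel("additive", 1.0)
        assert nm.neg_loglik(np.array([1.0, -1.0]), np.zeros(2)) == pytest.approx(1.0)

    def test_proportional_form(self):
        nm = NoiseModel("proportional", 0.005)
        y = np.array([2.0])
        yhat = np.array([2.1])
        expected = (y[0] - yhat[0]) ** 2 / (2 * (0.005 * yhat[0]) ** 2) + np.log(0.005 * yhat[0])
        assert nm.neg_loglik(y, yhat) == pytest.approx(expected)

    def test_proportional_rejects_zero_prediction(self):
        nm = NoiseModel("proportional", 0.005)
        with pytest.raises(ValueError):
            nm.neg_loglik(np.array([1.0]), np.array([0.0]))

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            NoiseModel("additive", 0.0)


class TestDerivativePenalty:
    def test_constant_first_derivative_zero(self):
        bp = np.linspace(0.0, 1.0, 6)
        basis = bspline_basis(bp)
        theta = np.full(basis.n_total, 3.7)  # partition of unity -> u = 3.7
        assert derivative_penalty(InputFunction(basis, theta), 1) == pytest.approx(0.0, abs=1e-10)

    def test_affine_second_derivative_zero(self):
        bp = np.linspace(0.0, 1.0, 6)
        basis = bspline_basis(bp)
        # interpolate u(t) = 2t + 1 exactly (a degree-1 polynomial is in the
        # cubic spline space); coefficients from least squares on a fine grid
        t = np.linspace(0, 1, 200)
        theta, *_ = np.linalg.lstsq(basis.eval_matrix(t), 2 * t + 1, rcond=None)
        assert derivative_penalty(InputFunction(basis, theta), 2) == pytest.approx(0.0, abs=1e-10)

    def test_quadratic_against_analytic_integral(self):
        # u(t) = t^2 on [0,1]: int (du/dt)^2 = int (2t)^2 dt = 4/3
        bp = np.linspace(0.0, 1.0, 8)
        basis = bspline_basis(bp)
        t = np.linspace(0, 1, 300)
        theta, *_ = np.linalg.lstsq(basis.eval_matrix(t), t**2, rcond=None)
        val = derivative_penalty(InputFunction(basis, theta), 1)
        quad_val, _ = quad(lambda x: (2 * x) ** 2, 0, 1)
        assert val == pytest.approx(quad_val, abs=1e-6)
        assert val == pytest.approx(4.0 / 3.0, abs=1e-6)

    def test_kl_quadratic_form(self):
        basis = kl_basis(1, 6, (0.0, 1.0), grid_size=100)
        theta = np.arange(1.0, 7.0)
        assert derivative_penalty(InputFunction(basis, theta), 1) == pytest.approx(
            0.5 * np.sum(theta**2)
        )

    def test_pc_discrete_difference(self):
        basis = piecewise_constant_basis(4, (0.0, 2.0))  # dt = 0.5
        theta = np.array([0.0, 1.0, 1.0, 3.0])
        expected = ((1 - 0) ** 2 + 0 + (3 - 1) ** 2) / 0.5
        assert derivative_penalty(InputFunction(basis, theta), 1) == pytest.approx(expected)


class TestEntropyPenalty:
    def test_zero_when_u_equals_baseline(self):
        u = np.array([2.0, 3.0, 4.0])
        assert entropy_penalty(u, u) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        assert entropy_penalty([2.0, 1.0], [1.0, 1.0]) == pytest.approx(2 * np.log(2.0))

    def test_zero_value_contributes_nothing(self):
        assert entropy_penalty([0.0, 1.0], [1.0, 1.0]) == pytest.approx(0.0)

    def test_negative_u_rejected(self):
        with pytest.raises(ValueError):
            entropy_penalty([-1.0, 1.0])

    def test_default_baseline_nearest_neighbours(self):
        u = np.array([1.0, 2.0, 3.0])
        # m = [2, (1+3)/2, 2]
        expected = 1 * np.log(1 / 2) + 2 * np.log(2 / 2) + 3 * np.log(3 / 2)
        assert entropy_penalty(u) == pytest.approx(expected)


class TestLogPosterior:
    def test_fixed_tau_is_negated_objective(self, linear_setup):
        s = linear_setup
        theta = s.oracle.mean
        lp = s.spec.log_posterior(theta)
        assert lp == pytest.approx(-(s.spec.data_misfit(theta) + s.tau * s.spec.penalty(theta)))

    def test_tau_separability_when_penalty_zero(self, linear_setup):
        from inputest import TauPrior

        s = linear_setup
        spec = PosteriorSpec(
            s.system, s.times, s.y, NoiseModel("additive", s.sigma), s.template,
            penalty_order=1, tau=1.0, tau_prior=TauPrior(0.001, 0.001),
        )
        theta = np.zeros(s.basis.n_total)  # E_W = 0
        lp1 = spec.log_posterior(theta, tau=1.0)
        lp2 = spec.log_posterior(theta, tau=2.0)
        np_half_logtau = 0.5 * spec.n_penalized * np.log(2.0)
        gamma_diff = spec.tau_prior.log_pdf(2.0) - spec.tau_prior.log_pdf(1.0)
        assert lp2 - lp1 == pytest.approx(np_half_logtau + gamma_diff, abs=1e-10)

    def test_matches_linear_gaussian_quadratic_form(self, linear_setup):
        # ln p(theta) - ln p(theta') must equal the closed-form Gaussian
        # log-density difference from the oracle posterior
        s = linear_setup
        rng = np.random.default_rng(5)
        prec = np.linalg.inv(s.oracle.cov)
        # tight solver tolerances so the comparison probes the formulation,
        # not integrator error
        spec = PosteriorSpec(
            s.system, s.times, s.y, NoiseModel("additive", s.sigma), s.template,
            penalty_order=1, tau=s.tau, rtol=1e-12, atol=1e-14,
        )
        for _ in range(3):
            th1 = s.oracle.mean + 0.1 * rng.standard_normal(s.basis.n_total)
            th2 = s.oracle.mean + 0.1 * rng.standard_normal(s.basis.n_total)
            lhs = spec.log_posterior(th1) - spec.log_posterior(th2)
            d1 = th1 - s.oracle.mean
            d2 = th2 - s.oracle.mean
            rhs = -0.5 * (d1 @ prec @ d1 - d2 @ prec @ d2)
            # the two routes build the forward map independently (ODE solve
            # vs quadrature); their ~1e-11 prediction difference is amplified
            # by 1/sigma^2 in the quadratic form
            assert lhs == pytest.approx(rhs, abs=2e-7)


class TestGradient:
    def test_linear_model_gradient_vs_finite_differences(self, linear_setup, rng):
        s = linear_setup
        for _ in range(3):
            theta = rng.standard_normal(s.basis.n_total)
            g = s.spec.log_posterior_gradient(theta)
            fd = _finite_diff_grad(lambda th: s.spec.log_posterior(th), theta)
            assert np.max(np.abs(g - fd)) / max(np.max(np.abs(fd)), 1.0) < 1e-6

    def test_eflornithine_gradient_vs_finite_differences(self, efl_system, rng):
        times = np.array([30.0, 90.0, 240.0, 600.0, 1200.0])
        basis = bspline_basis(np.concatenate([[0.0], times]))
        template = InputFunction(basis, np.zeros(basis.n_total), "log")
        y = np.abs(rng.standard_normal(times.size)) + 0.3
        spec = PosteriorSpec(
            efl_system, times, y, NoiseModel("additive", 0.05), template,
            penalty_order=2, tau=0.5, rtol=1e-11, atol=1e-13,
        )
        for _ in range(2):
            theta = 0.2 * rng.standard_normal(basis.n_total)
            g = spec.log_posterior_gradient(theta)
            fd = _finite_diff_grad(lambda th: spec.log_posterior(th), theta)
            assert np.max(np.abs(g - fd)) / np.max(np.abs(fd)) < 1e-4

    def test_guo_hall_gradient_vs_finite_differences(self, rng):
        sysg = guo_hall_system()
        times = case2_schedule()
        basis = kl_basis(1, 8, (-9.0, 30.0), grid_size=200, augmentation="constant")
        template = InputFunction(basis, np.zeros(basis.n_total))
        truth = np.concatenate([0.3 * rng.standard_normal(8), [12.0]])
        _, out = simulate(sysg, template.with_coeffs(truth), times)
        spec = PosteriorSpec(
            sysg, times, out[:, 0] * (1 + 0.005 * rng.standard_normal(times.size)),
            NoiseModel("proportional", 0.005), template,
            penalty_order=1, tau=1.0, rtol=1e-11, atol=1e-13,
        )
        g = spec.log_posterior_gradient(truth)
        fd = _finite_diff_grad(lambda th: spec.log_posterior(th), truth)
        assert np.max(np.abs(g - fd)) / np.max(np.abs(fd)) < 1e-4

    def test_prior_gradient_zero_at_origin(self, linear_setup):
        s = linear_setup
        g_at_zero = s.spec.log_posterior_gradient(np.zeros(s.basis.n_total))
        # data part at theta = 0: J' r / sigma^2 with r = y (x0 = 0)
        expected = s.oracle.J.T @ s.y / s.sigma**2
        assert np.allclose(g_at_zero, expected, rtol=1e-5, atol=1e-8)

    def test_gradient_line_integral_consistency(self, linear_setup, rng):
        # log-posterior differences equal the line integral of the gradient
        s = linear_setup
        a = rng.standard_normal(s.basis.n_total)
        b = rng.standard_normal(s.basis.n_total)
        ts = np.linspace(0.0, 1.0, 101)
        integrand = np.array(
            [(b - a) @ s.spec.log_posterior_gradient(a + t * (b - a)) for t in ts]
        )
        integral = np.trapezoid(integrand, ts)
        diff = s.spec.log_posterior(b) - s.spec.log_posterior(a)
        assert integral == pytest.approx(diff, rel=1e-3)


class TestMetricTensor:
    def test_linear_model_equals_oracle_form(self, linear_setup):
        s = linear_setup
        G = s.spec.metric_tensor(np.zeros(s.basis.n_total))
        G_true = s.oracle.J.T @ s.oracle.J / s.sigma**2 + s.tau * np.eye(s.basis.n_total)
        assert np.max(np.abs(G - G_true)) / np.max(np.abs(G_true)) < 1e-6

    def test_positive_definite_at_random_points(self, linear_setup, rng):
        s = linear_setup
        for _ in range(10):
            theta = rng.standard_normal(s.basis.n_total)
            G = s.spec.metric_tensor(theta)
            np.linalg.cholesky(G)  # raises if not PD
            assert np.allclose(G, G.T)

    def test_no_data_limit_is_prior_precision(self):
        # with a single far-away measurement carrying huge noise the data
        # block vanishes and G -> tau * I on penalised coefficients
        basis = kl_basis(1, 5, (0.0, 1.0), grid_size=100)
        sysl = linear_test_system(k=1.0, V=1.0)
        template = InputFunction(basis, np.zeros(5))
        spec = PosteriorSpec(
            sysl, np.array([1.0]), np.array([0.0]),
            NoiseModel("additive", 1e12), template, penalty_order=1, tau=3.0,
        )
        G = spec.metric_tensor(np.zeros(5))
        assert np.allclose(G, 3.0 * np.eye(5), atol=1e-12)

    def test_gauss_newton_exact_for_linear_map(self, linear_setup, rng):
        # negative Hessian of the log posterior equals the metric when the
        # forward map is linear; verify via finite differences of the gradient
        s = linear_setup
        theta = rng.standard_normal(s.basis.n_total)
        G = s.spec.metric_tensor(theta)
        H = np.zeros_like(G)
        h = 1e-5
        for i in range(theta.size):
            e = np.zeros_like(theta)
            e[i] = h
            H[:, i] = -(
                s.spec.log_posterior_gradient(theta + e)
                - s.spec.log_posterior_gradient(theta - e)
            ) / (2 * h)
        assert np.allclose(G, H, rtol=1e-5, atol=1e-6)
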