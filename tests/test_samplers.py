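"""MCMC kernels: invariance on known targets, tuning, Gibbs conjugacy."""

import numpy as np
import pytest

from inputest import (
    CallableTarget,
    TauPrior,
    gibbs_tau,
    run_sampler,
    rwmh_componentwise,
    rwmh_joint,
    smmala_step,
    tune_scales,
)
from inputest.diagnostics import effective_sample_size, mcse
from inputest.samplers import ChainState


@pytest.fixture(scope="module")
def gauss2d():
    Sigma = np.array([[1.0, 0.8], [0.8, 2.0]])
    Prec = np.linalg.inv(Sigma)
    target = CallableTarget(
        log_pdf=lambda x: -0.5 * x @ Prec @ x,
        grad=lambda x: -(Prec @ x),
        metric=lambda x: Prec.copy(),
        n_theta=2,
    )
    return target, Sigma


def _moment_check(samples, true_mean, true_cov):
    """Mean within 3 ESS-based standard errors; variances within 3 se."""
    for j in range(samples.shape[1]):
        x = samples[:, j]
        ess = effective_sample_size(x)
        se_mean = np.std(x, ddof=1) / np.sqrt(ess)
        assert abs(x.mean() - true_mean[j]) < 3 * se_mean
        se_var = true_cov[j, j] * np.sqrt(2.0 / ess)
        assert abs(np.var(x, ddof=1) - true_cov[j, j]) < 3 * se_var


class TestComponentwiseRWMH:
    def test_zero_move_always_accepted(self, gauss2d, rng):
        target, _ = gauss2d
        theta = np.array([0.3, -0.2])
        parts = target.parts(theta)
        state = ChainState(theta=theta, tau=1.0, log_post=target.log_post(parts, 1.0), parts=parts)
        accepted = 0
        for _ in range(50):
            new, flags, _ = rwmh_componentwise(target, state, np.full(2, 1e-14), rng)
            accepted += flags.sum()
        assert accepted == 100  # proposals ~ current value, ratio ~ 1

    def test_recovers_2d_gaussian_moments(self, gauss2d):
        target, Sigma = gauss2d
        chain = run_sampler(target, "componentwise", 20000, init=np.zeros(2),
                            rng_seed=11, scales0=np.array([2.0, 2.5]))
        samples, _ = chain.post_burn_in()
        _moment_check(samples, np.zeros(2), Sigma)

    def test_adaptive_tuning_reaches_target_band(self, gauss2d):
        target, _ = gauss2d
        # start far outside the reasonable range: scales must adapt into the
        # 0.2-0.5 acceptance band during burn-in and stay there after
        chain = run_sampler(target, "componentwise", 9000, init=np.zeros(2),
                            rng_seed=12, scales0=np.array([200.0, 0.001]), burn_in=3000)
        post = np.asarray(chain.accepts["theta"][3000:], dtype=float)
        rates = post.mean(axis=0)
        assert np.all(rates >= 0.2) and np.all(rates <= 0.5)


class TestTuneScales:
    def test_inside_band_unchanged(self):
        assert tune_scales([35], [1.0])[0] == 1.0

    def test_below_band_halved_above_doubled(self):
        out = tune_scales([5, 60], [1.0, 1.0])
        assert out[0] == 0.5 and out[1] == 2.0

    def test_repeated_application_settles(self, gauss2d, rng):
        target, _ = gauss2d
        theta = np.zeros(2)
        parts = target.parts(theta)
        state = ChainState(theta=theta, tau=1.0, log_post=target.log_post(parts, 1.0), parts=parts)
        scales = np.array([50.0, 50.0])
        stable_windows = 0
        for window in range(40):
            counts = np.zeros(2)
            for _ in range(100):
                state, flags, _ = rwmh_componentwise(target, state, scales, rng)
                counts += flags
            rates = counts / 100.0
            if np.all((rates >= 0.2) & (rates <= 0.5)):
                stable_windows += 1
                if stable_windows >= 5:
                    break
            else:
                stable_windows = 0
            scales = tune_scales(counts, scales)
        assert stable_windows >= 5


class TestJointRWMH:
    def test_degenerate_proposal_rejected_at_construction(self, gauss2d):
        target, _ = gauss2d
        with pytest.raises(ValueError):
            run_sampler(target, "joint_rwmh", 10, init=np.zeros(2),
                        proposal_cov=np.zeros((2, 2)))

    def test_recovers_correlated_gaussian_covariance(self, gauss2d):
        target, Sigma = gauss2d
        chain = run_sampler(target, "joint_rwmh", 50000, init=np.zeros(2), rng_seed=21)
        samples, _ = chain.post_burn_in()
        _moment_check(samples, np.zeros(2), Sigma)
        emp = np.cov(samples.T)
        assert np.linalg.norm(emp - Sigma) / np.linalg.norm(Sigma) < 0.10

    def test_metric_based_default_proposal_acceptance(self, gauss2d):
        # default proposal cov = s^2 G^-1 tuned towards 20-30 % acceptance
        target, _ = gauss2d
        chain = run_sampler(target, "joint_rwmh", 12000, init=np.zeros(2), rng_seed=22)
        assert 0.1 < chain.acceptance_rate() < 0.45


class TestSMMALA:
    def test_specialises_to_langevin_with_identity_metric(self, rng):
        # flat gradient, identity metric: proposal ~ N(theta, eps^2 I)
        target = CallableTarget(
            log_pdf=lambda x: 0.0,
            grad=lambda x: np.zeros_like(x),
            metric=lambda x: np.eye(x.size),
            n_theta=3,
        )
        theta = np.array([1.0, -2.0, 0.5])
        eps = 0.7
        moves = []
        for seed in range(300):
            parts = target.parts(theta)
            st = ChainState(theta=theta, tau=1.0, log_post=0.0, parts=parts)
            new, acc, _ = smmala_step(target, st, eps, np.random.default_rng(seed))
            assert acc == 1  # flat target accepts everything
            moves.append(new.theta - theta)
        moves = np.asarray(moves)
        assert np.allclose(moves.mean(axis=0), 0.0, atol=0.15)
        assert np.allclose(moves.std(axis=0), eps, rtol=0.15)

    def test_recovers_gaussian_moments(self, gauss2d):
        target, Sigma = gauss2d
        chain = run_sampler(target, "smmala_gibbs", 20000, init=np.zeros(2),
                            rng_seed=31, epsilon=1.5)
        samples, _ = chain.post_burn_in()
        _moment_check(samples, np.zeros(2), Sigma)

    def test_double_well_stationary_distribution(self):
        # 1-D double well p(x) ∝ exp(-(x^2-1)^2): compare the empirical
        # histogram to the discretised density via a chi-square statistic
        logp = lambda x: -((x[0] ** 2 - 1.0) ** 2)
        grad = lambda x: np.array([-4.0 * x[0] * (x[0] ** 2 - 1.0)])
        metric = lambda x: np.array([[max(12 * x[0] ** 2 - 4.0, 1.0)]])
        target = CallableTarget(logp, grad, metric, n_theta=1)
        chain = run_sampler(target, "smmala_gibbs", 100000, init=np.array([1.0]),
                            rng_seed=41, epsilon=1.2)
        x = chain.post_burn_in()[0][:, 0]
        edges = np.linspace(-2.2, 2.2, 23)
        counts, _ = np.histogram(x, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = np.exp(-((centers**2 - 1.0) ** 2))
        expected = dens / dens.sum() * counts.sum()
        keep = expected > 10
        # inflate by the autocorrelation factor: effective counts are fewer
        ess_ratio = effective_sample_size(x) / x.size
        chi2 = np.sum((counts[keep] - expected[keep]) ** 2 / expected[keep]) * ess_ratio
        from scipy.stats import chi2 as chi2_dist

        crit = chi2_dist.ppf(0.99, df=keep.sum() - 1)
        assert chi2 < crit

    def test_higher_acceptance_than_rwmh_at_matched_step(self, gauss2d):
        target, Sigma = gauss2d
        ch_s = run_sampler(target, "smmala_gibbs", 5000, init=np.zeros(2),
                           rng_seed=51, epsilon=1.5, burn_in=1)
        cov = 1.5**2 * Sigma  # same move size, no gradient drift
        ch_r = run_sampler(target, "joint_rwmh", 5000, init=np.zeros(2),
                           rng_seed=51, proposal_cov=cov, burn_in=1)
        assert ch_s.acceptance_rate() > ch_r.acceptance_rate()


class TestGibbsTau:
    def test_conjugate_update_arithmetic(self, rng):
        # theta = (1, 1): conditional is Gamma(a0 + 1, b0 + 1)
        prior = TauPrior(0.001, 0.001)
        draws = np.array([gibbs_tau(np.ones(2), prior, np.random.default_rng(s)) for s in range(20000)])
        expected_mean = (0.001 + 1.0) / (0.001 + 1.0)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected_mean) < 3 * se

    def test_moment_matches_conditional_mean(self, rng):
        prior = TauPrior(0.001, 0.001)
        theta = np.linspace(0.2, 1.5, 20)
        n_draws = 100000
        draws = np.array([gibbs_tau(theta, prior, rng) for _ in range(n_draws)])
        shape = 0.001 + 10.0
        rate = 0.001 + 0.5 * np.sum(theta**2)
        expected = shape / rate
        se = np.sqrt(shape) / rate / np.sqrt(n_draws)
        assert abs(draws.mean() - expected) < 3 * se

    def test_hyperparameters_positive(self):
        with pytest.raises(ValueError):
            TauPrior(0.0, 0.001)


class TestTauRecovery:
    def test_tau_posterior_concentrates_on_generating_value(self, linear_setup):
        # data simulated from the KL prior at a known tau: the sampled tau
        # posterior (Gibbs within SMMALA) should concentrate near it
        from inputest import (
            InputFunction, NoiseModel, PosteriorSpec, TauPrior, kl_basis,
            linear_test_system, map_single_shooting, simulate,
        )
        from inputest.synthgen import draw_prior_function

        tau_true, sigma = 1.0, 0.02
        system = linear_test_system(k=0.5, V=2.0)
        basis = kl_basis(1, 20, (0.0, 10.0), grid_size=200)
        template = InputFunction(basis, np.zeros(20))
        times = np.linspace(0.25, 10.0, 40)
        medians = []
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            truth = draw_prior_function(basis, tau_true, rng)
            _, out = simulate(system, truth, times)
            y = out[:, 0] + sigma * rng.standard_normal(40)
            spec = PosteriorSpec(
                system, times, y, NoiseModel("additive", sigma), template,
                penalty_order=1, tau=tau_true, tau_prior=TauPrior(0.001, 0.001),
            )
            init = map_single_shooting(spec)
            chain = run_sampler(spec, "smmala_gibbs", 3000, init=init,
                                rng_seed=seed, epsilon=1.0)
            _, taus = chain.post_burn_in()
            medians.append(np.median(taus))
        avg_median = np.mean(medians)
        assert tau_true / 3.0 < avg_median < tau_true * 3.0, medians


class TestRunSampler:
    def test_reproducibility_and_seed_sensitivity(self, gauss2d):
        target, _ = gauss2d
        c1 = run_sampler(target, "joint_rwmh", 200, init=np.zeros(2), rng_seed=7)
        c2 = run_sampler(target, "joint_rwmh", 200, init=np.zeros(2), rng_seed=7)
        c3 = run_sampler(target, "joint_rwmh", 200, init=np.zeros(2), rng_seed=8)
        assert np.array_equal(c1.samples, c2.samples)
        assert not np.array_equal(c1.samples[:10], c3.samples[:10])

    def test_acceptance_log_consistent_with_flags(self, gauss2d):
        target, _ = gauss2d
        chain = run_sampler(target, "joint_rwmh", 2000, init=np.zeros(2), rng_seed=9)
        a = np.asarray(chain.accepts["theta"])
        assert np.all((a == 0) | (a == 1))
        assert chain.acceptance_rate(after_burn_in=False) == pytest.approx(a.mean())

    def test_unknown_scheme_rejected(self, gauss2d):
        with pytest.raises(ValueError):
            run_sampler(gauss2d[0], "nuts", 10, init=np.zeros(2))

    def test_detailed_balance_flux_symmetry(self):
        # discretised 1-D standard normal: empirical transition flux between
        # any two bins must be symmetric for a reversible kernel
        target = CallableTarget(lambda x: -0.5 * x[0] ** 2, n_theta=1)
        chain = run_sampler(target, "componentwise", 60000, init=np.zeros(1),
                            rng_seed=13, scales0=np.array([2.4]), burn_in=1)
        x = chain.samples[:, 0]
        edges = np.array([-np.inf, -0.6, 0.0, 0.6, np.inf])
        bins = np.digitize(x, edges[1:-1])
        flux = np.zeros((4, 4))
        for a, b in zip(bins[:-1], bins[1:]):
            flux[a, b] += 1
        for i in range(4):
            for j in range(i + 1, 4):
                tot = flux[i, j] + flux[j, i]
                if tot > 100:
                    assert abs(flux[i, j] - flux[j, i]) < 4 * np.sqrt(tot)
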