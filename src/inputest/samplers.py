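"""MCMC kernels and sampling schemes.

Three kernels are provided, all special cases of Metropolis-Hastings:

* component-wise Gaussian random-walk (each coefficient updated singly, with
  acceptance-rate-driven scale tuning: monitored every 100 sweeps, scale
  doubled above 0.5 acceptance and halved below 0.2),
* joint Gaussian random-walk with a fixed proposal covariance (by default
  s^2 G(theta_MAP)^-1, s tuned during burn-in to 20-30 % acceptance),
* SMMALA, the simplified manifold Metropolis-adjusted Langevin algorithm:
  proposals are Gaussian with mean theta + (eps^2/2) G^-1 grad and covariance
  eps^2 G^-1, accepted with the full asymmetric ratio (the metric is
  recomputed at the proposal for the reverse density).

The regularisation parameter tau is conjugate under KL priors — its full
conditional is Gamma(a0 + N_p/2, b0 + sum(theta_p^2)/2) — and is updated by
Gibbs sampling (always accepted), once per iteration before the theta update.

Adaptation (scale tuning) runs only during burn-in (the first third of the
chain by default) and is frozen afterwards, since continual adaptation
breaks the invariance of the chain; burn-in samples are recorded but
excluded from inference summaries.  Failed ODE solves during proposals count
as zero-probability proposals (rejections), not errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky

from .map_control import MAPResult
from .objective import PosteriorSpec, TauPrior

#: relative diagonal jitter applied before factorising a metric tensor
METRIC_JITTER = 1e-8


class ChainAborted(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Targets
# ---------------------------------------------------------------------------


class SpecTarget:
    """Adapter exposing a PosteriorSpec to the kernels with caching that
    separates tau-independent work (the ODE/sensitivity solves) from the
    cheap tau-dependent terms, so Gibbs tau-updates never re-solve the ODE."""

    def __init__(self, spec: PosteriorSpec):
        self.spec = spec
        self.n_theta = spec.n_theta
        self.n_penalized = spec.n_penalized
        self.tau_sampled = spec.tau_sampled
        self.tau_prior = spec.tau_prior

    # parts = (E_D, E_W, aug) — everything theta-dependent
    def parts(self, theta):
        s = self.spec
        return (s.data_misfit(theta), s.penalty(theta), s._aug_neg_logprior(theta))

    def log_post(self, parts, tau):
        E_D, E_W, aug = parts
        val = -E_D - tau * E_W - aug
        if self.tau_sampled:
            val += 0.5 * self.n_penalized * np.log(tau) + self.tau_prior.log_pdf(tau)
        return float(val)

    def grad_parts(self, theta):
        """tau-independent gradient/metric pieces from one sensitivity solve."""
        s = self.spec
        J, yhat = s.jacobian(theta, with_predictions=True)
        g_data = J.T @ s.noise.dneg_loglik_dyhat(s.values, yhat)
        G_data = (J.T * s.noise.fisher_weights(yhat)) @ J
        E_D = s.noise.neg_loglik(s.values, yhat)
        return g_data, G_data, E_D

    def gradient(self, theta, tau, g_data):
        s = self.spec
        from .basis import AUGMENTATION_PRECISION

        g_prior = s.precision() @ np.asarray(theta, dtype=float)
        aug = np.zeros(self.n_theta, dtype=bool)
        aug[s.input_template.basis.n_basis :] = True
        g_aug = np.where(aug, AUGMENTATION_PRECISION * np.asarray(theta), 0.0)
        return -(g_data + tau * g_prior + g_aug)

    def metric(self, theta, tau, G_data):
        from .basis import AUGMENTATION_PRECISION

        s = self.spec
        G = G_data + tau * s.precision()
        aug = np.zeros(self.n_theta, dtype=bool)
        aug[s.input_template.basis.n_basis :] = True
        G[aug, aug] += AUGMENTATION_PRECISION
        return G

    def penalized_sq(self, theta):
        return float(np.sum(np.asarray(theta)[: self.n_penalized] ** 2))


class CallableTarget:
    """Wrap plain log-density callables (no ODE, no tau) for kernel tests."""

    def __init__(self, log_pdf, grad=None, metric=None, n_theta=None):
        self._log_pdf = log_pdf
        self._grad = grad
        self._metric = metric
        self.n_theta = n_theta
        self.n_penalized = n_theta
        self.tau_sampled = False
        self.tau_prior = None

    def parts(self, theta):
        return (-float(self._log_pdf(np.asarray(theta, dtype=float))), 0.0, 0.0)

    def log_post(self, parts, tau):
        return -parts[0]

    def grad_parts(self, theta):
        theta = np.asarray(theta, dtype=float)
        g = self._grad(theta) if self._grad is not None else None
        G = self._metric(theta) if self._metric is not None else None
        return -g if g is not None else None, G, -float(self._log_pdf(theta))

    def gradient(self, theta, tau, g_data):
        return -g_data

    def metric(self, theta, tau, G_data):
        return G_data

    def penalized_sq(self, theta):
        return float(np.sum(np.asarray(theta) ** 2))


# ---------------------------------------------------------------------------
# Chain containers
# ---------------------------------------------------------------------------


@dataclass
class ChainState:
    theta: np.ndarray
    tau: float
    log_post: float
    parts: tuple = None
    g_data: np.ndarray = None
    G_data: np.ndarray = None

    def invalidate_derivatives(self):
        self.g_data = None
        self.G_data = None


@dataclass
class MCMCChain:
    """Ordered posterior samples with acceptance and tuning provenance."""

    samples: np.ndarray  # (N, n_theta)
    taus: np.ndarray  # (N,)
    log_posts: np.ndarray  # (N,)
    accepts: dict  # block name -> (N,) or (N, n_theta) 0/1 array
    tuning_history: list
    seed: int
    sampler: str
    burn_in: int
    n_failures: int = 0

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def post_burn_in(self):
        return self.samples[self.burn_in :], self.taus[self.burn_in :]

    def acceptance_rate(self, block: str = "theta", after_burn_in: bool = True):
        a = np.asarray(self.accepts[block], dtype=float)
        if after_burn_in:
            a = a[self.burn_in :]
        return float(np.mean(a))

    def to_frame(self):
        import pandas as pd

        n = self.samples.shape[1]
        df = pd.DataFrame(self.samples, columns=[f"theta_{i}" for i in range(n)])
        df.insert(0, "iteration", np.arange(self.n_samples))
        df.insert(1, "tau", self.taus)
        df["log_posterior"] = self.log_posts
        return df


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------


def _try_parts(target, theta):
    try:
        return target.parts(theta)
    except Exception:
        return None


def rwmh_componentwise(target, state: ChainState, scales, rng):
    """One sweep of single-coordinate Gaussian random-walk updates.

    Proposals are symmetric, so the MH ratio is the posterior ratio.  A
    failed model evaluation at a proposal counts as rejection.
    """
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("proposal scales must be positive")
    theta = state.theta.copy()
    parts = state.parts
    lp = state.log_post
    flags = np.zeros(theta.size, dtype=int)
    n_fail = 0
    for i in range(theta.size):
        prop = theta.copy()
        prop[i] += scales[i] * rng.standard_normal()
        new_parts = _try_parts(target, prop)
        if new_parts is None:
            n_fail += 1
            continue
        lp_new = target.log_post(new_parts, state.tau)
        if np.log(rng.uniform()) < lp_new - lp:
            theta, parts, lp = prop, new_parts, lp_new
            flags[i] = 1
    new_state = ChainState(theta=theta, tau=state.tau, log_post=lp, parts=parts)
    return new_state, flags, n_fail


def tune_scales(accept_counts, scales, window: int = 100):
    """Per-parameter doubling/halving rule on a 100-sweep window."""
    rates = np.asarray(accept_counts, dtype=float) / window
    scales = np.asarray(scales, dtype=float).copy()
    scales[rates > 0.5] *= 2.0
    scales[rates < 0.2] /= 2.0
    return scales


def rwmh_joint(target, state: ChainState, chol_cov, rng):
    """Joint Gaussian random-walk step; chol_cov is the (lower) Cholesky
    factor of the proposal covariance."""
    step = chol_cov @ rng.standard_normal(state.theta.size)
    prop = state.theta + step
    new_parts = _try_parts(target, prop)
    if new_parts is None:
        return state, 0, 1
    lp_new = target.log_post(new_parts, state.tau)
    if np.log(rng.uniform()) < lp_new - state.log_post:
        return ChainState(theta=prop, tau=state.tau, log_post=lp_new, parts=new_parts), 1, 0
    return state, 0, 0


def _chol_with_jitter(G):
    d = G.shape[0]
    jitter = METRIC_JITTER * np.trace(G) / d
    return cho_factor(G + jitter * np.eye(d), lower=True)


def _smmala_moments(target, theta, tau, g_data, G_data, epsilon):
    grad = target.gradient(theta, tau, g_data)
    G = target.metric(theta, tau, G_data)
    cf = _chol_with_jitter(G)
    mu = theta + 0.5 * epsilon**2 * cho_solve(cf, grad)
    return mu, cf, G


def _gauss_logpdf(x, mu, G, cf, epsilon):
    # density of N(mu, eps^2 G^-1); cf is the Cholesky of (G + jitter)
    d = x.size
    diff = (x - mu) / epsilon
    quad = -0.5 * float(diff @ (G @ diff))
    logdet_G = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return -0.5 * d * np.log(2 * np.pi) + 0.5 * logdet_G - d * np.log(epsilon) + quad


def smmala_step(target, state: ChainState, epsilon: float, rng):
    """One SMMALA step with the full asymmetric MH correction."""
    if state.g_data is None or state.G_data is None:
        state.g_data, state.G_data, _ = target.grad_parts(state.theta)
    try:
        mu, cf, G = _smmala_moments(
            target, state.theta, state.tau, state.g_data, state.G_data, epsilon
        )
    except np.linalg.LinAlgError:
        return state, 0, 1
    # sample from N(mu, eps^2 G^-1): with G = L L', L^-T xi has cov G^-1
    xi = rng.standard_normal(state.theta.size)
    L = np.tril(cf[0])  # cho_factor leaves junk in the unused triangle
    prop = mu + epsilon * np.linalg.solve(L.T, xi)

    new_parts = _try_parts(target, prop)
    if new_parts is None:
        return state, 0, 1
    lp_new = target.log_post(new_parts, state.tau)
    try:
        g_new, G_new, _ = target.grad_parts(prop)
        mu_rev, cf_rev, G_rev = _smmala_moments(target, prop, state.tau, g_new, G_new, epsilon)
    except Exception:
        return state, 0, 1
    log_q_fwd = _gauss_logpdf(prop, mu, G, cf, epsilon)
    log_q_rev = _gauss_logpdf(state.theta, mu_rev, G_rev, cf_rev, epsilon)
    log_A = lp_new - state.log_post + log_q_rev - log_q_fwd
    if np.log(rng.uniform()) < log_A:
        return (
            ChainState(
                theta=prop, tau=state.tau, log_post=lp_new, parts=new_parts,
                g_data=g_new, G_data=G_new,
            ),
            1,
            0,
        )
    return state, 0, 0


def gibbs_tau(theta_penalized, prior: TauPrior, rng) -> float:
    """Exact draw from the conjugate Gamma full conditional of tau."""
    theta_penalized = np.asarray(theta_penalized, dtype=float)
    shape = prior.a0 + 0.5 * theta_penalized.size
    rate = prior.b0 + 0.5 * float(np.sum(theta_penalized**2))
    return float(rng.gamma(shape, 1.0 / rate))


# ---------------------------------------------------------------------------
# Schemes
# ---------------------------------------------------------------------------

SCHEMES = ("componentwise", "joint_rwmh", "smmala_gibbs")


def run_sampler(
    spec_or_target,
    scheme: str,
    n_samples: int,
    init=None,
    rng_seed: int = 0,
    burn_in: Optional[int] = None,
    scales0=None,
    proposal_cov=None,
    epsilon: float = 1.0,
    tau0: Optional[float] = None,
) -> MCMCChain:
    """Run the selected scheme for n_samples iterations.

    init may be a MAPResult (chains are initialised at the MAP estimate) or a
    coefficient vector.  Fully reproducible given rng_seed.  The smmala_gibbs
    scheme updates tau by Gibbs first, then theta by SMMALA; tau-updates
    reuse the cached Jacobian products, so only theta-updates pay for a
    sensitivity solve.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme '{scheme}'")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    target = SpecTarget(spec_or_target) if isinstance(spec_or_target, PosteriorSpec) else spec_or_target
    rng = np.random.default_rng(rng_seed)
    burn_in = n_samples // 3 if burn_in is None else int(burn_in)

    if isinstance(init, MAPResult):
        theta0 = init.theta_hat.copy()
    elif init is not None:
        theta0 = np.asarray(init, dtype=float).copy()
    else:
        theta0 = np.zeros(target.n_theta)
    tau = float(
        tau0
        if tau0 is not None
        else getattr(getattr(target, "spec", None), "tau", 1.0)
    )

    parts0 = target.parts(theta0)
    state = ChainState(theta=theta0, tau=tau, log_post=target.log_post(parts0, tau), parts=parts0)

    n_theta = theta0.size
    samples = np.empty((n_samples, n_theta))
    taus = np.empty(n_samples)
    log_posts = np.empty(n_samples)
    tuning_history = []
    n_failures = 0
    consecutive_failures = 0

    def _note_failures(k):
        nonlocal n_failures, consecutive_failures
        if k:
            n_failures += k
            consecutive_failures += k
            if consecutive_failures > max(50, n_samples // 2):
                raise ChainAborted(
                    f"aborted after {consecutive_failures} consecutive evaluation failures"
                )
        else:
            consecutive_failures = 0

    if scheme == "componentwise":
        scales = (
            np.full(n_theta, 0.1) if scales0 is None else np.asarray(scales0, dtype=float).copy()
        )
        accepts = np.zeros((n_samples, n_theta), dtype=int)
        window_counts = np.zeros(n_theta)
        for it in range(n_samples):
            if target.tau_sampled:
                state.tau = gibbs_tau(state.theta[: target.n_penalized], target.tau_prior, rng)
                state.log_post = target.log_post(state.parts, state.tau)
            state, flags, nf = rwmh_componentwise(target, state, scales, rng)
            _note_failures(nf)
            accepts[it] = flags
            window_counts += flags
            if (it + 1) % 100 == 0 and it < burn_in:
                scales = tune_scales(window_counts, scales)
                tuning_history.append((it + 1, scales.copy()))
                window_counts[:] = 0
            samples[it] = state.theta
            taus[it] = state.tau
            log_posts[it] = state.log_post
        accept_log = {"theta": accepts}

    elif scheme == "joint_rwmh":
        if proposal_cov is None:
            g0, G0, _ = target.grad_parts(state.theta)
            cf = _chol_with_jitter(target.metric(state.theta, state.tau, G0))
            cov0 = cho_solve(cf, np.eye(n_theta))
            s = 2.38 / np.sqrt(n_theta)
        else:
            cov0 = np.asarray(proposal_cov, dtype=float)
            if not np.all(np.isfinite(cov0)) or np.any(np.linalg.eigvalsh(cov0) <= 0):
                raise ValueError("proposal covariance must be positive-definite")
            s = 1.0
        chol0 = cholesky(cov0 + METRIC_JITTER * np.trace(cov0) / n_theta * np.eye(n_theta), lower=True)
        accepts = np.zeros(n_samples, dtype=int)
        window = 0
        for it in range(n_samples):
            if target.tau_sampled:
                state.tau = gibbs_tau(state.theta[: target.n_penalized], target.tau_prior, rng)
                state.log_post = target.log_post(state.parts, state.tau)
            state, acc, nf = rwmh_joint(target, state, s * chol0, rng)
            _note_failures(nf)
            accepts[it] = acc
            window += acc
            if (it + 1) % 100 == 0 and it < burn_in:
                rate = window / 100.0
                if rate < 0.2:
                    s /= 1.5
                elif rate > 0.3:
                    s *= 1.5
                tuning_history.append((it + 1, s))
                window = 0
            samples[it] = state.theta
            taus[it] = state.tau
            log_posts[it] = state.log_post
        accept_log = {"theta": accepts}

    else:  # smmala_gibbs
        eps = float(epsilon)
        accepts = np.zeros(n_samples, dtype=int)
        window = 0
        for it in range(n_samples):
            if target.tau_sampled:
                # tau-update: log target and metric change, Jacobian reused
                state.tau = gibbs_tau(state.theta[: target.n_penalized], target.tau_prior, rng)
                state.log_post = target.log_post(state.parts, state.tau)
            state, acc, nf = smmala_step(target, state, eps, rng)
            _note_failures(nf)
            accepts[it] = acc
            window += acc
            if (it + 1) % 100 == 0 and it < burn_in:
                if window / 100.0 < 0.3:
                    eps /= 2.0
                    tuning_history.append((it + 1, eps))
                window = 0
            samples[it] = state.theta
            taus[it] = state.tau
            log_posts[it] = state.log_post
        accept_log = {"theta": accepts}

    return MCMCChain(
        samples=samples,
        taus=taus,
        log_posts=log_posts,
        accepts=accept_log,
        tuning_history=tuning_history,
        seed=rng_seed,
        sampler=scheme,
        burn_in=burn_in,
        n_failures=n_failures,
    )
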