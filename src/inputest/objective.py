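"""Statistical objective: likelihood, smoothness priors and derivatives.

The estimation target is the posterior over basis coefficients theta (and
optionally the regularisation parameter tau),

    ln p(theta, tau | y) = -E_D - tau * E_W  [+ tau-dependent terms],

where E_D is the negative log likelihood of the measurements and E_W the
smoothness penalty.  Conventions:

* KL bases: coefficients are a-priori N(0, 1/tau), so E_W = 0.5 * sum(theta_p^2)
  and the prior precision on the penalised block is the identity.  When tau
  is sampled, the Gaussian normalisation (N_p/2) ln tau and the
  Gamma(a0, b0) hyperprior are included — both are required for the Gibbs
  conditional on tau to be correct.
* Spline bases: E_W = theta' W theta with W_kl = int B_k^(j) B_l^(j) dt, the
  literal integrated squared j-th derivative (prior precision 2 tau W).
* Piecewise-constant bases: discrete-difference penalty (a random-walk prior);
  the continuous derivative of a step function is undefined.

Gradients of the data term come from forward sensitivity equations (the
states are augmented with d x / d theta); the prior gradient is analytic.
The SMMALA metric tensor is the Gauss-Newton curvature
J' Sigma^-1 J + tau * P.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .basis import AUGMENTATION_PRECISION, InputFunction
from .dynamics import DynamicalSystem, SimulationError, simulate, _integration_segments
from .dynamics import DEFAULT_ATOL, DEFAULT_RTOL


@dataclass
class NoiseModel:
    """Measurement-noise description.

    kind 'additive': y_i = yhat_i + N(0, sigma^2), sigma in measurement units.
    kind 'proportional': y_i = yhat_i (1 + sigma * N(0,1)), sigma a unitless
    fraction evaluated at the *predicted* value (keeps the likelihood proper).
    """

    kind: str
    sigma: float

    def __post_init__(self):
        if self.kind not in ("additive", "proportional"):
            raise ValueError("noise kind must be 'additive' or 'proportional'")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def neg_loglik(self, y, yhat):
        r = y - yhat
        if self.kind == "additive":
            return float(np.sum(r**2) / (2 * self.sigma**2))
        if np.any(yhat == 0):
            raise ValueError("proportional noise undefined at zero prediction")
        s = self.sigma * yhat
        return float(np.sum(r**2 / (2 * s**2) + np.log(np.abs(s))))

    def dneg_loglik_dyhat(self, y, yhat):
        r = y - yhat
        if self.kind == "additive":
            return -r / self.sigma**2
        return -r / (self.sigma**2 * yhat**2) - r**2 / (self.sigma**2 * yhat**3) + 1.0 / yhat

    def fisher_weights(self, yhat):
        """Per-point Fisher information of yhat (expected-curvature weights)."""
        if self.kind == "additive":
            return np.full_like(np.atleast_1d(yhat), 1.0 / self.sigma**2)
        return 1.0 / (self.sigma**2 * yhat**2) + 2.0 / yhat**2

    def sample(self, yhat, rng):
        if self.kind == "additive":
            return yhat + self.sigma * rng.standard_normal(np.shape(yhat))
        return yhat * (1.0 + self.sigma * rng.standard_normal(np.shape(yhat)))


# ---------------------------------------------------------------------------
# Penalties
# ---------------------------------------------------------------------------


def _spline_penalty_matrix(basis, j: int) -> np.ndarray:
    """W_kl = int B_k^(j) B_l^(j) dt by per-span Gauss-Legendre (exact)."""
    a, b = basis.domain
    spans = basis._spans if basis._spans is not None else np.linspace(a, b, 41)
    # derivative products are polynomial within each knot span, so per-span
    # Gauss-Legendre with 8 points is exact for cubic splines
    nodes, weights = np.polynomial.legendre.leggauss(8)
    n = basis.n_total
    W = np.zeros((n, n))
    for lo, hi in zip(spans[:-1], spans[1:]):
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        t = mid + half * nodes
        D = basis.deriv_matrix(t, j)
        W += half * (D.T * weights) @ D
    return W


def _pc_penalty_matrix(basis, j: int) -> np.ndarray:
    """Discrete difference penalty for piecewise-constant bases.

    j=1: sum (u_{k+1} - u_k)^2 / dt  (random-walk prior on the steps);
    j=2: sum (u_{k+1} - 2 u_k + u_{k-1})^2 / dt^3.
    """
    n = basis.n_basis
    a, b = basis.domain
    dt = (b - a) / n
    if j == 1:
        D = np.diff(np.eye(n), axis=0)
        W = D.T @ D / dt
    else:
        D = np.diff(np.eye(n), n=2, axis=0)
        W = D.T @ D / dt**3
    if basis.n_aug:
        full = np.zeros((basis.n_total, basis.n_total))
        full[:n, :n] = W
        W = full
    return W


def penalty_precision(basis, j: int) -> np.ndarray:
    """Prior precision P (at tau=1) over all coefficients, aug block zero.

    Defined so that -ln p(theta | tau) = (tau/2) theta' P theta + const, i.e.
    E_W = 0.5 theta' P theta.
    """
    n_tot = basis.n_total
    P = np.zeros((n_tot, n_tot))
    if basis.kind == "karhunen_loeve":
        P[: basis.n_penalized, : basis.n_penalized] = np.eye(basis.n_penalized)
    elif basis.kind == "bspline":
        P = 2.0 * _spline_penalty_matrix(basis, j)
        if basis.n_aug:
            P[basis.n_basis :, :] = 0.0
            P[:, basis.n_basis :] = 0.0
    elif basis.kind == "piecewise_constant":
        P = 2.0 * _pc_penalty_matrix(basis, j)
    else:
        raise ValueError(f"unknown basis kind {basis.kind}")
    return P


def derivative_penalty(input_fn: InputFunction, j: int) -> float:
    """E_W = int (d^j u / dt^j)^2 dt (log scale: the derivative of ln u).

    KL bases return 0.5 * sum(theta_penalised^2) — the equivalent quadratic
    form under the precision-tau convention; piecewise-constant bases use the
    discrete-difference form.
    """
    basis = input_fn.basis
    theta = input_fn.coeffs
    if basis.kind == "karhunen_loeve":
        return 0.5 * float(np.sum(theta[: basis.n_penalized] ** 2))
    if basis.kind == "bspline":
        W = _spline_penalty_matrix(basis, j)
        return float(theta @ W @ theta)
    if basis.kind == "piecewise_constant":
        W = _pc_penalty_matrix(basis, j)
        return float(theta @ W @ theta)
    raise ValueError(f"unknown basis kind {basis.kind}")


def entropy_penalty(u_k, m_k=None) -> float:
    """Entropy prior term sum_k u_k ln(u_k / m_k) with 0 ln 0 = 0.

    m_k defaults to the average of each point's nearest neighbours.
    """
    u = np.asarray(u_k, dtype=float)
    if np.any(u < 0):
        raise ValueError("entropy penalty requires u_k >= 0")
    if m_k is None:
        m = np.empty_like(u)
        if u.size == 1:
            m[:] = u
        else:
            m[0] = u[1]
            m[-1] = u[-2]
            if u.size > 2:
                m[1:-1] = 0.5 * (u[:-2] + u[2:])
    else:
        m = np.asarray(m_k, dtype=float)
    if np.any(m <= 0):
        raise ValueError("baselines m_k must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(u > 0, u * np.log(np.where(u > 0, u, 1.0) / m), 0.0)
    return float(np.sum(terms))


# ---------------------------------------------------------------------------
# Posterior specification
# ---------------------------------------------------------------------------


@dataclass
class TauPrior:
    """Gamma(shape a0, rate b0) hyperprior on the regularisation parameter."""

    a0: float = 0.001
    b0: float = 0.001

    def __post_init__(self):
        if self.a0 <= 0 or self.b0 <= 0:
            raise ValueError("Gamma hyperparameters must be positive")

    def log_pdf(self, tau):
        return (self.a0 - 1.0) * np.log(tau) - self.b0 * tau


@dataclass
class PosteriorSpec:
    """Dataset + noise model + prior: everything defining ln p(theta, tau | y)."""

    system: DynamicalSystem
    times: np.ndarray
    values: np.ndarray
    noise: NoiseModel
    input_template: InputFunction
    penalty_order: int = 2
    tau: float = 1.0
    tau_prior: Optional[TauPrior] = None
    prior_kind: str = "derivative"  # derivative | entropy
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL

    _P: np.ndarray = field(default=None, repr=False)
    _lin_J: np.ndarray = field(default=None, repr=False)
    _lin_y0: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("measurement times must be strictly increasing")
        a, b = self.input_template.basis.domain
        if self.times[0] < a - 1e-9 or self.times[-1] > b + 1e-9:
            raise ValueError("measurement times outside the basis domain")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.prior_kind == "entropy" and self.input_template.basis.kind != "piecewise_constant":
            raise ValueError("entropy prior is only defined for piecewise-constant bases")

    # -- structural helpers -------------------------------------------------

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def n_theta(self) -> int:
        return self.input_template.basis.n_total

    @property
    def n_penalized(self) -> int:
        return self.input_template.basis.n_penalized

    @property
    def tau_sampled(self) -> bool:
        return self.tau_prior is not None

    def precision(self) -> np.ndarray:
        """Prior precision at tau = 1 over the penalised block (aug zero)."""
        if self._P is None:
            self._P = penalty_precision(self.input_template.basis, self.penalty_order)
        return self._P

    def _aug_mask(self):
        m = np.zeros(self.n_theta, dtype=bool)
        m[self.input_template.basis.n_basis :] = True
        return m

    # -- forward model ------------------------------------------------------

    @property
    def _linearizable(self) -> bool:
        return self.system.linear and self.input_template.scale == "linear"

    def _linear_map(self):
        """Cache (y0, J): predictions = y0 + J theta by superposition."""
        if self._lin_J is None:
            zero = self.input_template.with_coeffs(np.zeros(self.n_theta))
            _, out0 = simulate(self.system, zero, self.times, self.rtol, self.atol)
            y0 = out0[:, 0]
            cols = np.empty((self.n, self.n_theta))
            for i in range(self.n_theta):
                e = np.zeros(self.n_theta)
                e[i] = 1.0
                _, out = simulate(
                    self.system, self.input_template.with_coeffs(e), self.times, self.rtol, self.atol
                )
                cols[:, i] = out[:, 0] - y0
            self._lin_y0, self._lin_J = y0, cols
        return self._lin_y0, self._lin_J

    def predictions(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if self._linearizable:
            y0, J = self._linear_map()
            return y0 + J @ theta
        fn = self.input_template.with_coeffs(theta)
        _, out = simulate(self.system, fn, self.times, self.rtol, self.atol)
        return out[:, 0]

    def jacobian(self, theta, with_predictions: bool = False):
        """d yhat / d theta via forward sensitivities (or the linear cache)."""
        theta = np.asarray(theta, dtype=float)
        if self._linearizable:
            y0, J = self._linear_map()
            if with_predictions:
                return J, y0 + J @ theta
            return J
        yhat, J = _sensitivity_jacobian(self, theta)
        if with_predictions:
            return J, yhat
        return J

    # -- objective terms ----------------------------------------------------

    def data_misfit(self, theta) -> float:
        return self.noise.neg_loglik(self.values, self.predictions(theta))

    def penalty(self, theta) -> float:
        """E_W evaluated at theta (excluding the weak augmentation prior)."""
        if self.prior_kind == "entropy":
            fn = self.input_template.with_coeffs(np.asarray(theta, dtype=float))
            return entropy_penalty(fn.coeffs[: fn.basis.n_basis])
        P = self.precision()
        th = np.asarray(theta, dtype=float)
        return 0.5 * float(th @ P @ th)

    def _aug_neg_logprior(self, theta):
        m = self._aug_mask()
        return 0.5 * AUGMENTATION_PRECISION * float(np.sum(np.asarray(theta)[m] ** 2))

    def log_posterior(self, theta, tau=None) -> float:
        tau = self.tau if tau is None else tau
        val = -self.data_misfit(theta) - tau * self.penalty(theta) - self._aug_neg_logprior(theta)
        if self.tau_sampled:
            val += 0.5 * self.n_penalized * np.log(tau) + self.tau_prior.log_pdf(tau)
        return float(val)

    def log_posterior_gradient(self, theta, tau=None) -> np.ndarray:
        tau = self.tau if tau is None else tau
        theta = np.asarray(theta, dtype=float)
        J, yhat = self.jacobian(theta, with_predictions=True)
        g_data = J.T @ self.noise.dneg_loglik_dyhat(self.values, yhat)
        if self.prior_kind == "entropy":
            g_prior = _entropy_gradient(self, theta)
        else:
            g_prior = self.precision() @ theta
        g_aug = np.where(self._aug_mask(), AUGMENTATION_PRECISION * theta, 0.0)
        return -(g_data + tau * g_prior + g_aug)

    def metric_tensor(self, theta, tau=None) -> np.ndarray:
        """G = J' Sigma^-1 J + tau P (+ weak augmentation precision)."""
        tau = self.tau if tau is None else tau
        theta = np.asarray(theta, dtype=float)
        J, yhat = self.jacobian(theta, with_predictions=True)
        if not np.all(np.isfinite(J)):
            raise FloatingPointError("non-finite sensitivity Jacobian")
        w = self.noise.fisher_weights(yhat)
        G = (J.T * w) @ J + tau * self.precision()
        G[self._aug_mask(), self._aug_mask()] += AUGMENTATION_PRECISION
        return G


def _entropy_gradient(spec, theta, eps=1e-6):
    # m_k depends on neighbouring u_k, so differentiate numerically
    g = np.zeros_like(theta)
    for i in range(theta.size):
        tp, tm = theta.copy(), theta.copy()
        h = eps * max(1.0, abs(theta[i]))
        tp[i] += h
        tm[i] -= h
        g[i] = (spec.penalty(tp) - spec.penalty(tm)) / (2 * h)
    return g


# ---------------------------------------------------------------------------
# Forward sensitivities
# ---------------------------------------------------------------------------


def _sensitivity_jacobian(spec: PosteriorSpec, theta):
    """Predictions and d yhat / d theta from the augmented ODE system.

    The augmented state is [x, vec(S)] with S = dx/dtheta (d_x x n_theta),
    dS/dt = f_x S + f_u (du/dtheta), S(t0) = 0.  Integration restarts at
    input breakpoints so sensitivities stay accurate across jumps.
    """
    sys_ = spec.system
    fn = spec.input_template.with_coeffs(np.asarray(theta, dtype=float))
    d_x, n_th = sys_.d_x, spec.n_theta
    times = spec.times

    if sys_.rhs_jac_x is None or sys_.rhs_jac_u is None:
        raise NotImplementedError("system lacks rhs Jacobians for sensitivities")

    log_scale = fn.scale == "log"
    coeffs = fn.coeffs
    basis_row = fn.basis.eval_matrix  # one basis evaluation serves u and du/dtheta

    def aug_rhs(t, z):
        x = z[:d_x]
        S = z[d_x:].reshape(d_x, n_th)
        row = basis_row(np.array([t]))[0]
        w = float(row @ coeffs)
        u = np.exp(w) if log_scale else w
        du = u * row if log_scale else row
        f = sys_.rhs(t, x, u, sys_.params)
        fx = sys_.rhs_jac_x(t, x, u, sys_.params)
        fu = sys_.rhs_jac_u(t, x, u, sys_.params)  # (d_x, 1)
        dS = fx @ S + fu @ du[None, :]
        return np.concatenate([f, dS.ravel()])

    z = np.concatenate([sys_.x0, np.zeros(d_x * n_th)])
    states = np.empty((times.size, d_x))
    sens = np.empty((times.size, d_x, n_th))
    filled = 0
    if abs(times[0] - sys_.t0) <= 1e-12:
        states[0] = sys_.x0
        sens[0] = 0.0
        filled = 1
    for a, b in _integration_segments(sys_.t0, times[-1], fn.breakpoints, sys_.rhs_breakpoints):
        requested = times[(times > a + 1e-15) & (times <= b + 1e-15)]
        t_eval = np.unique(np.append(requested, b))
        sol = solve_ivp(
            aug_rhs, (a, b), z, method="LSODA", rtol=spec.rtol, atol=spec.atol, t_eval=t_eval
        )
        if not sol.success:
            raise SimulationError(
                f"sensitivity solve failed near t={sol.t[-1]}: {sol.message}", sol.t[-1]
            )
        for j, te in enumerate(sol.t):
            if filled < times.size and abs(te - times[filled]) <= 1e-12 + 1e-12 * abs(te):
                states[filled] = sol.y[:d_x, j]
                sens[filled] = sol.y[d_x:, j].reshape(d_x, n_th)
                filled += 1
        z = sol.y[:, -1]
    if filled != times.size:
        raise SimulationError("internal error: not all requested times reached")

    yhat = np.empty(times.size)
    Jac = np.empty((times.size, n_th))
    for i, t in enumerate(times):
        u = float(fn.evaluate(t))
        gx = sys_.measure_jac_x(t, states[i], u, sys_.params)  # (1, d_x)
        gu = sys_.measure_jac_u(t, states[i], u, sys_.params)  # (1, 1)
        yhat[i] = np.atleast_1d(sys_.measure(t, states[i], u, sys_.params))[0]
        Jac[i] = gx @ sens[i] + gu[0, 0] * fn.du_dcoeffs(np.atleast_1d(t))[0]
    return yhat, Jac


# -- spec-level thin wrappers ------------------------------------------------


def data_misfit(spec: PosteriorSpec, theta) -> float:
    """Negative log likelihood E_D at theta (additive constants dropped)."""
    return spec.data_misfit(theta)


def log_posterior(spec: PosteriorSpec, theta, tau=None) -> float:
    return spec.log_posterior(theta, tau)


def log_posterior_gradient(spec: PosteriorSpec, theta, tau=None) -> np.ndarray:
    return spec.log_posterior_gradient(theta, tau)


def metric_tensor(spec: PosteriorSpec, theta, tau=None) -> np.ndarray:
    return spec.metric_tensor(theta, tau)
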