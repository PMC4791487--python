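"""Scikit-learn style estimators: the package's primary public API.

Input estimation is a regression-shaped problem — measurements in, a fitted
input function out — so the estimators follow the sklearn contract:
constructor stores hyperparameters untouched, ``fit(t, y)`` does the work and
sets trailing-underscore attributes, ``predict`` maps times to predicted
measurements, and ``get_params``/``set_params`` make the classes compose
with sklearn model selection.

>>> est = MAPInputEstimator(system=linear_test_system(), basis=kl_basis(1, 10, (0, 10)))
>>> est.fit(t, y).predict_input(grid)
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .basis import BasisSet, InputFunction
from .diagnostics import bioavailability, summarize_input, summarize_output
from .dynamics import DynamicalSystem, simulate
from .map_control import (
    LCurveResult,
    l_curve_select,
    map_collocation,
    map_single_shooting,
)
from .objective import NoiseModel, PosteriorSpec, TauPrior
from .samplers import run_sampler


class _SpecBuilderMixin:
    """Shared input validation and PosteriorSpec construction."""

    def _validate_ty(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.size != y.size or t.size == 0:
            raise ValueError("t and y must be non-empty arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("measurement times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in the measurement table")
        return t, y

    def _make_spec(self, t, y, tau, tau_prior=None):
        if not isinstance(self.system, DynamicalSystem):
            raise ValueError("system must be a DynamicalSystem instance")
        if not isinstance(self.basis, BasisSet):
            raise ValueError("basis must be a BasisSet instance")
        template = InputFunction(self.basis, np.zeros(self.basis.n_total), self.scale)
        noise = NoiseModel(self.noise, self.sigma)
        return PosteriorSpec(
            system=self.system,
            times=t,
            values=y,
            noise=noise,
            input_template=template,
            penalty_order=self.penalty_order,
            tau=tau,
            tau_prior=tau_prior,
            prior_kind=getattr(self, "prior_kind", "derivative"),
        )


class MAPInputEstimator(BaseEstimator, _SpecBuilderMixin):
    """MAP (penalised maximum-likelihood) input estimation.

    Parameters
    ----------
    system : the known DynamicalSystem.
    basis : finite basis for u(t).
    scale : 'linear' or 'log' (log enforces u > 0 and applies the prior to
        ln u).
    noise, sigma : measurement-noise model ('additive'|'proportional') and
        its standard deviation.
    tau : regularisation parameter (prior precision).
    penalty_order : derivative order j penalised (1 or 2).
    method : 'shooting' (ODE solver in the loop) or 'collocation'
        (simultaneous transcription; supports bound constraints).
    prior_kind : 'derivative' or 'entropy' (entropy needs a
        piecewise-constant basis).

    Attributes
    ----------
    theta_ : fitted coefficients.
    E_D_, E_W_, objective_ : objective decomposition at the optimum.
    converged_, n_iter_ : optimiser diagnostics.
    input_fn_ : the fitted InputFunction.
    """

    def __init__(
        self,
        system=None,
        basis=None,
        scale: str = "linear",
        noise: str = "additive",
        sigma: float = 1.0,
        tau: float = 1.0,
        penalty_order: int = 2,
        method: str = "shooting",
        prior_kind: str = "derivative",
        theta0=None,
        collocation_mesh=None,
        max_iter: int = 500,
    ):
        self.system = system
        self.basis = basis
        self.scale = scale
        self.noise = noise
        self.sigma = sigma
        self.tau = tau
        self.penalty_order = penalty_order
        self.method = method
        self.prior_kind = prior_kind
        self.theta0 = theta0
        self.collocation_mesh = collocation_mesh
        self.max_iter = max_iter

    def fit(self, t, y):
        t, y = self._validate_ty(t, y)
        spec = self._make_spec(t, y, self.tau)
        if self.method == "shooting":
            res = map_single_shooting(spec, theta0=self.theta0, max_iter=self.max_iter)
        elif self.method == "collocation":
            res = map_collocation(
                spec, theta0=self.theta0, mesh=self.collocation_mesh, max_iter=self.max_iter
            )
        else:
            raise ValueError("method must be 'shooting' or 'collocation'")
        self.spec_ = spec
        self.result_ = res
        self.theta_ = res.theta_hat
        self.E_D_ = res.E_D
        self.E_W_ = res.E_W
        self.objective_ = res.objective
        self.converged_ = res.converged
        self.n_iter_ = res.n_iterations
        self.input_fn_ = spec.input_template.with_coeffs(res.theta_hat)
        return self

    def predict_input(self, t):
        """Fitted u(t) on a time grid."""
        self._check_fitted()
        return self.input_fn_.evaluate(np.asarray(t, dtype=float))

    def predict(self, t):
        """Noise-free predicted measurements at times t."""
        self._check_fitted()
        t = np.asarray(t, dtype=float)
        _, out = simulate(self.system, self.input_fn_, t)
        return out[:, 0]

    def _check_fitted(self):
        if not hasattr(self, "theta_"):
            raise AttributeError("estimator is not fitted; call fit(t, y) first")


class BayesianInputEstimator(BaseEstimator, _SpecBuilderMixin):
    """Full Bayesian input estimation by MCMC, initialised at the MAP.

    tau handling: pass ``tau_prior=(a0, b0)`` to sample the regularisation
    parameter by Gibbs (conjugate Gamma), or leave None to keep tau fixed.
    ``scheme`` selects the kernel: 'componentwise' | 'joint_rwmh' |
    'smmala_gibbs'.

    Attributes
    ----------
    chain_ : the MCMCChain (samples, acceptance and tuning provenance).
    theta_map_ : the MAP initialiser.
    samples_, tau_samples_ : post-burn-in draws.
    """

    def __init__(
        self,
        system=None,
        basis=None,
        scale: str = "linear",
        noise: str = "additive",
        sigma: float = 1.0,
        tau: float = 1.0,
        tau_prior=None,
        penalty_order: int = 2,
        scheme: str = "smmala_gibbs",
        n_samples: int = 5000,
        burn_in: Optional[int] = None,
        epsilon: float = 1.0,
        random_state: int = 0,
        map_max_iter: int = 500,
    ):
        self.system = system
        self.basis = basis
        self.scale = scale
        self.noise = noise
        self.sigma = sigma
        self.tau = tau
        self.tau_prior = tau_prior
        self.penalty_order = penalty_order
        self.scheme = scheme
        self.n_samples = n_samples
        self.burn_in = burn_in
        self.epsilon = epsilon
        self.random_state = random_state
        self.map_max_iter = map_max_iter

    def fit(self, t, y):
        t, y = self._validate_ty(t, y)
        tp = TauPrior(*self.tau_prior) if self.tau_prior is not None else None
        # the MAP start fixes tau high when it is to be sampled, mirroring the
        # "fix the regularisation parameter to a high value, optimise, then
        # sample" initialisation strategy
        tau_start = self.tau if tp is None else max(self.tau, 100.0)
        spec_map = self._make_spec(t, y, tau_start)
        map_res = map_single_shooting(spec_map, max_iter=self.map_max_iter)
        spec = self._make_spec(t, y, self.tau, tau_prior=tp)
        chain = run_sampler(
            spec,
            scheme=self.scheme,
            n_samples=self.n_samples,
            init=map_res,
            rng_seed=self.random_state,
            burn_in=self.burn_in,
            epsilon=self.epsilon,
            tau0=self.tau,
        )
        self.spec_ = spec
        self.map_result_ = map_res
        self.theta_map_ = map_res.theta_hat
        self.chain_ = chain
        self.samples_, self.tau_samples_ = chain.post_burn_in()
        self.theta_ = self.samples_.mean(axis=0)
        self.input_fn_ = spec.input_template.with_coeffs(self.theta_)
        return self

    def predict_input(self, t):
        """Posterior-mean u(t) (mean of per-sample curves)."""
        self._check_fitted()
        t = np.asarray(t, dtype=float)
        return summarize_input(self.chain_, self.spec_.input_template, t).mean

    def predict(self, t):
        """Predicted measurements at the posterior-mean coefficients."""
        self._check_fitted()
        fn = self.spec_.input_template.with_coeffs(self.theta_)
        _, out = simulate(self.system, fn, np.asarray(t, dtype=float))
        return out[:, 0]

    def input_summary(self, grid):
        self._check_fitted()
        return summarize_input(self.chain_, self.spec_.input_template, grid)

    def output_summary(self, grid, thin: int = 10):
        self._check_fitted()
        return summarize_output(self.chain_, self.spec_, grid, thin=thin)

    def bioavailability(self, dose: float, horizon=None):
        self._check_fitted()
        if horizon is None:
            horizon = self.spec_.input_template.basis.domain
        return bioavailability(self.chain_, dose, horizon, self.spec_.input_template)

    def _check_fitted(self):
        if not hasattr(self, "chain_"):
            raise AttributeError("estimator is not fitted; call fit(t, y) first")


class LCurveSelector(BaseEstimator, _SpecBuilderMixin):
    """Regularisation-parameter selection by the L-curve corner.

    Fits MAP estimates across a log-spaced tau grid and locates the corner of
    the (ln E_W, ln E_D) trade-off curve.  ``tau_`` is the corner value;
    ``selected_taus_`` additionally holds one grid neighbour on each side for
    sensitivity analysis.
    """

    def __init__(
        self,
        system=None,
        basis=None,
        scale: str = "linear",
        noise: str = "additive",
        sigma: float = 1.0,
        penalty_order: int = 2,
        tau_grid=None,
        method: str = "shooting",
    ):
        self.system = system
        self.basis = basis
        self.scale = scale
        self.noise = noise
        self.sigma = sigma
        self.penalty_order = penalty_order
        self.tau_grid = tau_grid
        self.method = method

    def fit(self, t, y):
        t, y = self._validate_ty(t, y)

        def factory(tau):
            return self._make_spec(t, y, tau)

        res: LCurveResult = l_curve_select(factory, tau_grid=self.tau_grid, method=self.method)
        self.result_ = res
        self.taus_ = res.taus
        self.E_D_curve_ = res.E_D_curve
        self.E_W_curve_ = res.E_W_curve
        self.corner_index_ = res.corner_index
        self.selected_taus_ = res.selected_taus
        self.tau_ = float(res.selected_taus[1])
        return self
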