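# inputest

Nonparametric estimation of unknown input functions to known (possibly
nonlinear) ODE systems from sparse, noisy measurements.

## The problem

Many questions in pharmacokinetics and quantitative physiology reduce to
*input estimation* (nonlinear deconvolution): the system dynamics are known,

```
dx/dt = f(t, x(t), u(t)),      x(t0) = x0,
y_i   = g(t_i, x(t_i)) + v_i,  i = 1..n,
```

but the driving function u(t) is not — the oral absorption rate of a drug
given plasma-concentration measurements, or the energy intake of a mouse
given body-mass measurements.  Because u(t) is infinite-dimensional and the
data are finite, the problem is ill-posed; it is regularised with a
smoothness prior, giving the estimator

```
û(t) = argmin_u ( E_D + τ E_W ),
```

where `E_D` is the negative log likelihood, `E_W` penalises the first or
second derivative of u (or of ln u, for inputs that must stay positive), and
τ trades data fit against regularity.  Read as a Bayesian posterior
(`ln p(y|u) = −E_D`, `ln p(u) = −τ E_W`), the same objective yields not just
the MAP estimate but pointwise credible bands and posteriors of derived
quantities such as oral bioavailability `F = ∫ u dt / dose`.

## What the package provides

* **Bases for u(t)** — piecewise-constant indicators, cubic B-splines with
  breakpoints at the measurement times, and Karhunen–Loève (KL) expansions
  of the derivative-penalty Gaussian-process priors (Nyström solution of the
  Fredholm eigenproblem; coefficients are a-priori independent N(0, 1/τ)),
  optionally augmented with unpenalised constant/linear terms.
* **MAP estimation by optimal control** — single shooting (ODE solver in
  the loop, gradients by forward sensitivity equations, trust-region Newton
  with the Gauss–Newton Hessian) and direct collocation (degree-3 Radau
  transcription to an NLP with defect equality constraints; supports
  non-negativity bounds).
* **Regularisation-parameter selection** — the L-curve: MAP across a
  log-spaced τ grid, automatic maximum-curvature corner detection, and the
  corner ± one neighbour returned for sensitivity analysis; or fully
  Bayesian τ via a conjugate Gamma prior.
* **Posterior sampling** — component-wise adaptive random-walk
  Metropolis–Hastings (acceptance tuned into 0.2–0.5), joint RWMH with a
  metric-based proposal covariance, and SMMALA (simplified manifold MALA,
  metric tensor = Fisher information + prior precision), with Gibbs updates
  of τ interleaved.
* **Diagnostics** — autocorrelation-based effective sample size, pointwise
  95 % credible bands for u(t) and the predicted outputs, bioavailability
  posteriors.
* **Models** — a nonlinear three-compartment PK model with saturable
  binding (eflornithine-like), the Guo–Hall energy-partitioning model for
  body composition, and a linear one-compartment benchmark with a
  closed-form posterior used throughout the tests.  Shipped model parameter
  values are synthetic placeholders chosen for physiological plausibility.

The public API follows scikit-learn conventions: `MAPInputEstimator`,
`BayesianInputEstimator` and `LCurveSelector` are estimators with
`fit(t, y)`, `predict`, and `get_params`/`set_params`.

## Worked example

Estimate an oral absorption-rate curve and its bioavailability from
synthetic concentration data on the three-compartment PK model:

```python
import numpy as np
from inputest import (BayesianInputEstimator, eflornithine_system,
                      bspline_basis, simulate)
from inputest.synthgen import case1_schedule, first_order_absorption

system = eflornithine_system()           # placeholder PK parameters
times = case1_schedule()                 # dense early, sparse late (minutes)
truth = first_order_absorption(dose=20.0, F=0.35, k_a=0.012)
_, clean = simulate(system, truth, times)
rng = np.random.default_rng(0)
y = clean[:, 0] + 0.004 * rng.standard_normal(times.size)

basis = bspline_basis(np.unique(np.concatenate([[0.0], times])))
est = BayesianInputEstimator(
    system=system, basis=basis, scale="log", noise="additive", sigma=0.004,
    tau=1e4, penalty_order=2, scheme="joint_rwmh", n_samples=3000, random_state=0,
)
est.fit(times, y)
F = est.bioavailability(dose=20.0)
print(f"MAP objective: {est.map_result_.objective:.3f} "
      f"(E_D = {est.map_result_.E_D:.3f}, E_W = {est.map_result_.E_W:.6f})")
print(f"acceptance rate: {est.chain_.acceptance_rate():.2f}")
print(f"bioavailability F: mean {F['mean']:.3f}, "
      f"95% CI [{F['lower95']:.3f}, {F['upper95']:.3f}]  (truth 0.35)")
```

Output:

```
MAP objective: 1.813 (E_D = 1.268, E_W = 0.000055)
acceptance rate: 0.42
bioavailability F: mean 0.343, 95% CI [0.334, 0.353]  (truth 0.35)
```

The MAP stage fits the log-scale spline input by single shooting
(`E_D` ≈ n/2 · noise-consistent misfit, `E_W` the integrated squared second
derivative of ln u); the chain is initialised at the MAP and the
bioavailability posterior concentrates near the generating value 0.35.

A YAML-configured pipeline (τ selection → MAP → MCMC → summaries → plots)
is available from the command line:

```
inputest pipeline --config src/inputest/configs/case2_synthetic.yaml --out results/case2
```

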