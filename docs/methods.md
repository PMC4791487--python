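# Methods

## Model and statistical formulation

The estimation target is the input u(t) of a known ODE system
`dx/dt = f(t, x, u)` with initial state `x0`, observed through a measurement
function at discrete times with noise.  Two noise models are supported:
additive Gaussian with standard deviation σ in measurement units, and
proportional Gaussian with unitless σ evaluated at the *predicted* value
(so the likelihood remains a proper density in y; evaluating at the
measurement instead would make the normalisation data-dependent).

The input is expanded in a finite basis, `u(t) = Σ θ_i B_i(t)`, or
`u(t) = exp(Σ θ_i B_i(t))` for the log-scale model that enforces positivity
and applies the smoothness prior to ln u.  The posterior over coefficients
(and optionally the regularisation parameter τ) is

    ln p(θ, τ | y) = −E_D(θ) − τ E_W(θ) [+ (N_p/2) ln τ + ln Gamma(τ; a0, b0)],

with the bracketed terms present only when τ is sampled.  The Gaussian
normalisation `(N_p/2) ln τ` over the N_p penalised coefficients is
essential: without it the Gamma full conditional used for Gibbs updates of τ
would be wrong.

### Penalty conventions

* **KL bases.** Coefficients are a-priori independent N(0, 1/τ), so
  `E_W = ½ Σ θ_p²` and the prior precision at τ = 1 is the identity.  The
  posterior precision of the linear-Gaussian configuration is then exactly
  `JᵀΣ⁻¹J + τI`, which is what the closed-form oracle and the estimator
  tests use.  (The alternative convention without the ½ merely rescales τ
  by 2; the precision-τ convention was chosen because it makes the Gibbs
  conditional `Gamma(a0 + N_p/2, b0 + ½Σθ²)` exact.)
* **Spline bases.** `E_W = θᵀWθ` with `W_kl = ∫ B_k^(j) B_l^(j) dt`
  computed exactly by per-knot-span Gauss–Legendre quadrature — the literal
  integrated squared j-th derivative.  The prior precision is therefore 2τW.
* **Piecewise-constant bases.** The continuous derivative of a step
  function is undefined, so the discrete-difference form is used:
  `Σ (u_{k+1} − u_k)²/Δt` for j = 1 (a random-walk prior on the steps) and
  `Σ (u_{k+1} − 2u_k + u_{k−1})²/Δt³` for j = 2.
* **Entropy prior.** `Σ u_k ln(u_k/m_k)` with the convention 0·ln 0 = 0 and
  baselines m_k defaulting to nearest-neighbour averages; defined only for
  the piecewise-constant representation, where the u_k are the interval
  values.
* **Augmentation columns** (unpenalised constant/linear terms that let KL
  inputs start at nonzero values) carry a weak fixed Gaussian precision of
  1e-8 — not scaled by τ — purely to keep the posterior proper.

## Karhunen–Loève bases

The KL eigenproblem `∫ k(s,t) φ(s) ds = λ φ(t)` is solved numerically by
Nyström discretisation: uniform grid, trapezoid weights, symmetrised dense
eigenproblem.  One code path serves both penalty orders; the covariance
kernels on the unit interval are `min(s, t)` (first-derivative penalty:
Brownian motion, the process and hence the input starts at 0) and
`min²(3·max − min)/6` (second-derivative penalty: integrated Brownian
motion, where the derivative too starts at 0).  Eigenvalues rescale by
L^(2j) on a domain of length L and eigenfunctions by 1/√L.

Off-grid evaluation interpolates the grid eigenvectors with cubic splines
rather than using the raw Nyström extension: for these kernels the Nyström
extension is only piecewise linear between grid points, which silently caps
the accuracy of any downstream high-order quadrature or collocation at
O(grid⁻²), whereas the true eigenfunctions are smooth.  With the default
grid of 400 points the first ten eigenpairs of the j = 1 kernel match the
closed form λ_i = ((i+½)π)⁻², φ_i = √2 sin((i+½)πt) to better than 1e-3
relative.

## Forward simulation and sensitivities

ODE solves use `scipy.integrate.solve_ivp` with LSODA (variable-order,
stiff-capable) at rtol 1e-8 / atol 1e-10 by default — the case-study systems
are mildly stiff and gradient quality requires tight forward solves.
Integration restarts at every discontinuity: piecewise-constant input
breakpoints and model-intrinsic jumps (the physical-activity term of the
energy-balance model jumps at treatment start), since multistep methods
lose order across jumps.

Gradients of the log posterior come from the forward sensitivity equations:
the state is augmented with S = ∂x/∂θ obeying
`dS/dt = f_x S + f_u ∂u/∂θ`, S(t0) = 0, giving the prediction Jacobian
`J = g_x S + g_u ∂u/∂θ` at the measurement times.  Model Jacobians f_x, f_u
are analytic for the PK and linear models; the energy-balance model uses
tight central differences of its (smooth) right-hand side, which is
accurate to ~1e-9 and much less error-prone than hand-expanding the Forbes
function algebra.  The SMMALA metric tensor is the Gauss–Newton curvature
`G = Jᵀ diag(w) J + τP` with w the per-point Fisher weights of the noise
model; a relative jitter of 1e-8·trace(G)/dim is added only at
factorisation time, so the returned tensor is the exact Fisher-plus-prior
expression.

One caveat established during development: finite-difference *validation*
of these gradients must use tighter solver tolerances (rtol ~1e-11) than
production runs, because an FD step of 1e-5 amplifies solver noise of
rtol·|y| into O(1) relative errors in the FD reference — the sensitivity
gradients themselves are self-converged to ~1e-8 at default tolerances.

## MAP estimation

**Single shooting** optimises the coefficients with the ODE solver in the
loop, using a trust-region Newton method (`trust-constr`) whose Hessian is
the Gauss–Newton metric; objective, gradient and Hessian share one
sensitivity solve per iterate via a small cache.  This exploits the
least-squares structure and converges in tens of iterations where
quasi-Newton methods crawl.  Initial guess: zeros on the linear scale; a
constant input level matching the first measurement's magnitude on the log
scale.  Non-convergence is reported in the result object, never raised.

**Direct collocation** transcribes the dynamics into equality constraints:
each mesh interval carries a degree-3 polynomial interpolated at Radau IIA
points (stiff-stable, right endpoint included, so interval chaining needs
no separate continuity constraints), decision variables are all collocation
states plus θ, and the NLP is solved by SLSQP with analytic constraint
Jacobian and objective gradient.  Measurement times are required to
coincide with mesh nodes (the default mesh refines the measurement grid to
at least 40 intervals).  Lower bounds on states and inputs are supported in
this form.  The transcription is dense; problems up to a few hundred
intervals solve in seconds for one-state systems, while the 100-interval
three-state PK problem takes minutes rather than the seconds a sparse
interior-point solver would need — an accepted trade-off documented in the
test suite's problem sizes.  The log-scale piecewise-constant combination
is flagged as unsupported (a documented warning): its collocation NLP is
badly conditioned and convergence is not guaranteed.

**L-curve.** MAP is computed over a log-spaced τ grid (default 25 points
spanning 1e-3..1e3), warm-starting each solve from the previous solution.
After monotone cleanup (E_D non-decreasing, E_W non-increasing in τ), the
(ln E_W, ln E_D) curve is interpolated with cubic splines in ln τ and the
corner taken as the curvature maximum of the interpolant — this makes the
detected corner nearly independent of the grid spacing, which matters
because centered differences on a coarse grid can displace a flat corner by
several grid steps.  Three τ values are returned: the corner and one grid
neighbour on either side, mirroring manual knee-picking practice; failed
MAP solves exclude their τ from the curve.

## MCMC

* **Component-wise RWMH**: one Gaussian proposal per coefficient per sweep;
  symmetric, so the acceptance ratio is the posterior ratio.  Scales adapt
  every 100 sweeps (×2 above 0.5 acceptance, ÷2 below 0.2) during burn-in
  only; continual adaptation would break invariance.
* **Joint RWMH**: a single multivariate Gaussian proposal with covariance
  s²G(θ_MAP)⁻¹ by default; s starts at 2.38/√d and adapts toward 20–30 %
  acceptance during burn-in.
* **SMMALA**: proposal mean θ + ½ε²G⁻¹∇ln p, covariance ε²G⁻¹, with the
  full asymmetric acceptance ratio (metric recomputed at the proposal for
  the reverse density).  Default ε = 1, halved automatically whenever a
  100-iteration burn-in window shows acceptance below 0.3 — a safe
  auto-rule standing in for manual ε choice.
* **Gibbs update of τ**: exact draw from Gamma(a0 + N_p/2, b0 + ½Σθ_p²),
  performed once per iteration *before* the θ-update (order fixed for
  reproducibility).  In the alternating scheme the τ-update reuses the
  cached Jacobian products, so only θ-updates pay for a sensitivity solve.

Burn-in defaults to the first third of the chain; burn-in samples are
recorded (for tuning provenance) but excluded from every summary.  Failed
ODE solves during proposals count as zero-probability proposals
(rejections); a long run of consecutive failures aborts the chain with a
diagnostic.  Chains are bit-reproducible given the seed.

For linear systems with linear-scale inputs the forward map is linear in θ,
so the posterior specification caches `ŷ(θ) = y0 + Jθ` (J built once by
superposition, one ODE solve per basis column).  Samplers and MAP then run
without per-evaluation ODE solves.  The closed-form oracle used to *check*
these paths builds its J independently, by panel Gauss–Legendre quadrature
of the variation-of-constants integral with panels aligned to the basis's
polynomial pieces.

## Diagnostics

Effective sample size uses `ESS = N / (1 + 2Σρ_k)` with the
autocorrelation sum truncated by Geyer's initial-positive-sequence rule on
paired autocorrelations (conservative for reversible chains); a constant
series is assigned ESS = 1 by convention.  Function summaries evaluate
u(t; θ⁽ⁱ⁾) on a grid for every post-burn-in sample and report pointwise
means and empirical 2.5/97.5 percentiles; predicted-output bands simulate a
thinned subset (default every 10th sample) since each curve costs an ODE
solve, and record a warning if more than 10 % of those solves fail.
Credible intervals are pointwise, not simultaneous.  Bioavailability is
`∫u dt / dose`, exact for step functions and by 2001-point trapezoid
otherwise; chain versions return the full posterior sample set with mean
and central 95 % interval.

## Synthetic data

The generators emulate the two study designs rather than shipping data:

* **PK design** (`case1_*`): sampling every 20 min to 4 h (around the
  absorption peak), then 2-hourly to 24 h; truth input is first-order
  absorption `u(t) = F·dose·k_a·e^(−k_a t)` with F = 0.35 (a test design
  constant) and k_a = 0.012 /min; additive noise at ~1.5 % of the
  respective dose's concentration peak (σ = 0.004 mg/L low dose,
  0.3 mg/L high dose).  Intravenous bolus inputs are represented exactly as
  an initial-condition increment dose/V_c rather than a delta function.
* **Energy-balance design** (`case2_group`): body mass at day −9, then
  daily to day 14 and every second day to day 30 (no measurements in the
  pre-treatment gap), proportional 0.5 % noise; truth intake is constant
  before treatment with a sharp drop at t = 0 recovering exponentially over
  ~10 days.

Model parameter values shipped with the package are *synthetic
placeholders*: self-consistent, physiologically plausible values (PK in
minutes/L/mg; DIO-mouse energy balance in days/g/kcal with the reference
intake at 12 kcal/day and near energy balance pre-treatment).  They are not
the published estimates, which live in the original study's supplement.
Consequently the tests demonstrate recovery of *known synthetic* inputs
under realistic designs and noise — they do not certify performance on the
real datasets, nor do the synthetic series reproduce features such as
inter-animal variability, assay-specific error structure, or model
misspecification.

## Problem sizes and numerical choices

The validation suite runs on one CPU in minutes; sizes were chosen as the
smallest that make each statistical check sharp: the linear-Gaussian
benchmark uses 25 measurements and 10 KL modes with 20 000 post-burn-in
samples per sampler; nonlinear recovery uses the full 22-point PK schedule
with 5 (MAP) and 10 (coverage) replicate seeds; Gibbs and ESS checks use
1e5 and 5e4 draws.  Monte-Carlo assertions are stated as z-scores against
ESS-based standard errors with a 3σ bound.  Ties and degenerate inputs:
piecewise-constant intervals are half-open with the last closed (every t
maps to exactly one interval); spline derivative rows at the right endpoint
take the left limit; a constant chain series yields ESS 1; τ grids must
contain at least 5 points and corners are clamped away from the grid ends
so a neighbour exists on both sides.

## Known limitations

* System parameters (volumes, clearances, energy densities …) are treated
  as known constants; joint estimation with the input is out of scope, as
  is population-level (NLME) modelling.
* Non-negativity is available through the log-scale model or collocation
  bounds, not through proposal rejection in MCMC.
* The dense SLSQP collocation does not match sparse interior-point speed on
  large multi-state transcriptions.
* Credible bands are pointwise; simultaneous coverage is not controlled.
* The entropy prior supports MAP estimation only in the piecewise-constant
  representation, with numerically differentiated prior gradients.
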