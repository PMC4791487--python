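"""Dynamical-system abstraction and built-in models.

A :class:`DynamicalSystem` bundles the state equations ``dx/dt = f(t, x, u)``,
a noise-free measurement map ``y = g(t, x, u)``, the initial state and named
parameters.  Three models are registered:

``linear1c``
    One-compartment elimination ``dC/dt = u/V - k*C`` — the linear oracle
    model used throughout the test suite.
``eflornithine``
    Nonlinear three-compartment PK model (central, peripheral and saturable
    binding compartments) for an anti-trypanosomal drug; the estimated input
    is the absorption rate after oral dosing.
``guo_hall``
    Two-state energy-balance model (fat-free mass / fat mass) for
    diet-induced obese mice; the estimated input is the energy intake.

Analytic Jacobians of ``f`` and ``g`` with respect to the state and the
input are carried alongside the right-hand sides so that forward
sensitivity equations can be assembled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failing time."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass
class DynamicalSystem:
    """A known ODE system driven by an unknown input function.

    Attributes
    ----------
    state_names : names of the state variables (length ``d_x``).
    input_dim : dimension of the input (all built-in models use 1).
    rhs : ``f(t, x, u, params) -> dx/dt``.
    measure : ``g(t, x, u, params) -> y`` (noise-free outputs).
    x0 : initial state at ``t0``.
    t0 : initial time.
    params : named parameter values.
    rhs_jac_x, rhs_jac_u : Jacobians of ``f`` w.r.t. ``x`` and ``u``.
    measure_jac_x, measure_jac_u : Jacobians of ``g``.
    constraints : optional per-state lower bounds.
    linear : True if ``f`` and ``g`` are linear in ``(x, u)`` — enables the
        cached superposition forward map in :mod:`inputest.objective`.
    """

    state_names: Sequence[str]
    input_dim: int
    rhs: Callable
    measure: Callable
    x0: np.ndarray
    t0: float
    params: dict
    rhs_jac_x: Optional[Callable] = None
    rhs_jac_u: Optional[Callable] = None
    measure_jac_x: Optional[Callable] = None
    measure_jac_u: Optional[Callable] = None
    constraints: Optional[np.ndarray] = None
    linear: bool = False
    name: str = "custom"
    #: times where f itself is discontinuous (integration restarts there)
    rhs_breakpoints: Optional[Sequence[float]] = None

    def __post_init__(self):
        self.x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        if len(self.x0) != len(self.state_names):
            raise ValueError("x0 length does not match state_names")

    @property
    def d_x(self) -> int:
        return len(self.state_names)

    @property
    def d_y(self) -> int:
        y = self.measure(self.t0, self.x0, np.zeros(self.input_dim), self.params)
        return np.atleast_1d(np.asarray(y)).size

    def with_x0(self, x0) -> "DynamicalSystem":
        """Return a copy with a different initial state (e.g. an IV bolus)."""
        import dataclasses

        return dataclasses.replace(self, x0=np.asarray(x0, dtype=float))


# ---------------------------------------------------------------------------
# Eflornithine three-compartment model
# ---------------------------------------------------------------------------

EFLORNITHINE_STATES = ("C_p", "C_t", "C_b")

#: Synthetic placeholder parameter values (the published values live in the
#: original study's supplement).  Units: volumes in L, flows/clearance in
#: L/min, rates in 1/min, R_max in mg; concentrations in mg/L, time in min.
EFLORNITHINE_DEFAULTS = {
    "V_c": 9.0,
    "V_t": 13.0,
    "CL": 0.06,
    "Q": 0.04,
    "k_on": 0.002,
    "k_off": 0.005,
    "R_max": 20.0,
}


def _validate_finite(*arrays):
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite state or input value")


def eflornithine_rhs(t, state, u, params):
    """Central/peripheral/binding compartment derivatives.

    dC_p/dt = u/V_c - (CL/V_c + Q/V_c) C_p + (Q/V_c) C_t
              - k_on C_p (R_max/V_c - C_b) + k_off C_b
    dC_t/dt = (Q/V_t) C_p - (Q/V_t) C_t
    dC_b/dt = k_on C_p (R_max/V_c - C_b) - k_off C_b
    """
    state = np.asarray(state, dtype=float)
    u = float(np.atleast_1d(u)[0])
    _validate_finite(state, u)
    C_p, C_t, C_b = state
    V_c, V_t = params["V_c"], params["V_t"]
    CL, Q = params["CL"], params["Q"]
    k_on, k_off, R_max = params["k_on"], params["k_off"], params["R_max"]
    free = R_max / V_c - C_b
    bind = k_on * C_p * free
    dC_p = u / V_c - (CL / V_c + Q / V_c) * C_p + (Q / V_c) * C_t - bind + k_off * C_b
    dC_t = (Q / V_t) * C_p - (Q / V_t) * C_t
    dC_b = bind - k_off * C_b
    return np.array([dC_p, dC_t, dC_b])


def eflornithine_jac_x(t, state, u, params):
    C_p, C_t, C_b = np.asarray(state, dtype=float)
    V_c, V_t = params["V_c"], params["V_t"]
    CL, Q = params["CL"], params["Q"]
    k_on, k_off, R_max = params["k_on"], params["k_off"], params["R_max"]
    free = R_max / V_c - C_b
    return np.array(
        [
            [-(CL + Q) / V_c - k_on * free, Q / V_c, k_on * C_p + k_off],
            [Q / V_t, -Q / V_t, 0.0],
            [k_on * free, 0.0, -k_on * C_p - k_off],
        ]
    )


def eflornithine_jac_u(t, state, u, params):
    return np.array([[1.0 / params["V_c"]], [0.0], [0.0]])


def _measure_first_state(t, x, u, params):
    return np.atleast_1d(x[0])


def _measure_first_state_jac_x(t, x, u, params):
    J = np.zeros((1, len(np.atleast_1d(x))))
    J[0, 0] = 1.0
    return J


def _measure_jac_u_zero(t, x, u, params):
    return np.zeros((1, 1))


def eflornithine_system(params: dict | None = None, x0=None) -> DynamicalSystem:
    """Three-compartment eflornithine model measuring central concentration."""
    p = dict(EFLORNITHINE_DEFAULTS)
    if params:
        p.update(params)
    for k, v in p.items():
        if v <= 0:
            raise ValueError(f"eflornithine parameter {k} must be positive")
    return DynamicalSystem(
        state_names=EFLORNITHINE_STATES,
        input_dim=1,
        rhs=eflornithine_rhs,
        measure=_measure_first_state,
        x0=np.zeros(3) if x0 is None else x0,
        t0=0.0,
        params=p,
        rhs_jac_x=eflornithine_jac_x,
        rhs_jac_u=eflornithine_jac_u,
        measure_jac_x=_measure_first_state_jac_x,
        measure_jac_u=_measure_jac_u_zero,
        constraints=np.zeros(3),
        name="eflornithine",
    )


# ---------------------------------------------------------------------------
# Guo–Hall energy-balance model
# ---------------------------------------------------------------------------

GUO_HALL_STATES = ("FFM", "FM")

#: Synthetic placeholder values in DIO-mouse units (mass g, energy kcal,
#: time days).  rho_* are tissue energy densities; q1..q3 the Forbes-curve
#: constants; gamma_* metabolic-rate/mass slopes; eta_* synthesis
#: efficiencies; lambda0..lambda3 the per-group physical-activity constants
#: (treated as known, pre-estimated inputs to the analysis).
GUO_HALL_DEFAULTS = {
    "rho_FFM": 1.8,
    "rho_FM": 9.4,
    "q1": 0.05,
    "q2": 2.0,
    "q3": -0.15,
    "K": 2.0,
    "beta": 0.24,
    "gamma_FFM": 0.18,
    "gamma_FM": 0.02,
    "eta_FFM": 0.18,
    "eta_FM": 0.16,
    "EI_ref": 12.0,
    "lambda0": 0.05,
    "lambda1": 0.02,
    "lambda2": 0.25,
    "lambda3": 0.03,
}


def guo_hall_alpha(FM, params):
    """Forbes function alpha = q1 + q2 * exp(q3 * FM)."""
    return params["q1"] + params["q2"] * np.exp(params["q3"] * FM)


def guo_hall_lambda(t, params):
    """Piecewise physical-activity term: lambda0 before treatment (t < 0),
    lambda0 + lambda3 + lambda1*lambda2*t*exp(-lambda2*t) from t = 0 on."""
    l0, l1, l2, l3 = (params["lambda" + str(i)] for i in range(4))
    if t >= 0:
        return l0 + l3 + l1 * l2 * t * np.exp(-l2 * t)
    return l0


def guo_hall_ee(t, state, EI, params):
    """Energy expenditure (kcal/day) at the given state and intake."""
    FFM, FM = state
    alpha = guo_hall_alpha(FM, params)
    denom_g = alpha * params["rho_FFM"] + params["rho_FM"]
    if denom_g <= 0:
        raise ValueError("non-positive alpha*rho_FFM + rho_FM")
    g = 1.0 / denom_g
    lam = guo_hall_lambda(t, params)
    dEI = EI - params["EI_ref"]
    num = (
        params["K"]
        + params["beta"] * dEI
        + (params["gamma_FFM"] + lam) * FFM
        + (params["gamma_FM"] + lam) * FM
        + params["eta_FFM"] * alpha * g * EI
        + params["eta_FM"] * g * EI
    )
    den = 1.0 + params["eta_FM"] * g + params["eta_FFM"] * alpha * g
    if den <= 0:
        raise ValueError("non-positive EE denominator")
    return num / den


def guo_hall_rhs(t, state, EI, params):
    """Energy-partitioning derivatives: both states share the factor (EI - EE)."""
    state = np.asarray(state, dtype=float)
    EI = float(np.atleast_1d(EI)[0])
    _validate_finite(state, EI)
    FFM, FM = state
    alpha = guo_hall_alpha(FM, params)
    denom_g = alpha * params["rho_FFM"] + params["rho_FM"]
    if denom_g <= 0:
        raise ValueError("non-positive alpha*rho_FFM + rho_FM")
    g = 1.0 / denom_g
    balance = EI - guo_hall_ee(t, state, EI, params)
    return np.array([alpha * g * balance, g * balance])


def _guo_hall_jacobians(t, state, EI, params):
    """Closed-form Jacobians of the energy-partitioning rhs (machine-generated
    from the symbolic derivatives of Eqs. for dFFM/dt, dFM/dt)."""
    FFM, FM = np.asarray(state, dtype=float)
    EI = float(np.atleast_1d(EI)[0])
    p = params
    lam = guo_hall_lambda(t, p)
    x0 = np.exp(FM * p["q3"])
    x1 = p["q2"] * x0
    x2 = p["q1"] + x1
    x3 = p["rho_FFM"] * x2
    x4 = p["rho_FM"] + x3
    x5 = 1.0 / x4
    x6 = x2 * x5
    x7 = p["gamma_FFM"] + lam
    x8 = p["eta_FM"] * x5
    x9 = p["eta_FFM"] * x6
    x10 = x8 + x9
    x11 = 1.0 / (x10 + 1.0)
    x12 = x11 * x7
    x13 = p["gamma_FM"] + lam
    x14 = x11 * (
        EI * x8 + EI * x9 + FFM * x7 + FM * x13 + p["K"] + p["beta"] * (EI - p["EI_ref"])
    )
    x15 = EI - x14
    x16 = p["q3"] * x1
    x17 = x15 * x16 * x5
    x18 = p["eta_FFM"] * x5
    x19 = EI * x16
    x20 = x19 / x4**2
    x21 = x11 * (
        -p["eta_FFM"] * x20 * x3
        - p["eta_FM"] * p["rho_FFM"] * x20
        + x13
        + x14 * x16 * x5 * (-p["eta_FFM"] + p["rho_FFM"] * x8 + x18 * x3)
        + x18 * x19
    )
    x22 = x5 * (x11 * (p["beta"] + x10) - 1.0)
    Jx = np.array(
        [
            [-x12 * x6, x5 * (p["q2"] * p["q3"] * x0 * x15 - x17 * x3 - x2 * x21)],
            [-x12 * x5, -x5 * (p["rho_FFM"] * x17 + x21)],
        ]
    )
    Ju = np.array([[-x2 * x22], [-x22]])
    return Jx, Ju


def guo_hall_jac_x(t, state, u, params):
    return _guo_hall_jacobians(t, state, u, params)[0]


def guo_hall_jac_u(t, state, u, params):
    return _guo_hall_jacobians(t, state, u, params)[1]


def _measure_total_mass(t, x, u, params):
    return np.atleast_1d(x[0] + x[1])


def _measure_total_mass_jac_x(t, x, u, params):
    return np.array([[1.0, 1.0]])


def guo_hall_system(params: dict | None = None, x0=(30.0, 15.0)) -> DynamicalSystem:
    """Energy-balance model measuring total body mass FFM + FM."""
    p = dict(GUO_HALL_DEFAULTS)
    if params:
        p.update(params)
    if p["rho_FFM"] <= 0 or p["rho_FM"] <= 0:
        raise ValueError("tissue energy densities must be positive")
    return DynamicalSystem(
        state_names=GUO_HALL_STATES,
        input_dim=1,
        rhs=guo_hall_rhs,
        measure=_measure_total_mass,
        x0=np.asarray(x0, dtype=float),
        t0=-9.0,
        params=p,
        rhs_jac_x=guo_hall_jac_x,
        rhs_jac_u=guo_hall_jac_u,
        measure_jac_x=_measure_total_mass_jac_x,
        measure_jac_u=_measure_jac_u_zero,
        constraints=np.zeros(2),
        name="guo_hall",
        rhs_breakpoints=(0.0,),  # lambda(t) jumps by lambda3 at treatment start
    )


# ---------------------------------------------------------------------------
# Linear one-compartment test model
# ---------------------------------------------------------------------------


def linear_test_system(k: float = 0.5, V: float = 1.0, C0: float = 0.0) -> DynamicalSystem:
    """One-compartment model dC/dt = u/V - k*C measuring C.

    The linear special case used as the analytically tractable benchmark.
    """
    if k <= 0 or V <= 0:
        raise ValueError("k and V must be positive")
    params = {"k": k, "V": V}

    def rhs(t, x, u, p):
        u = float(np.atleast_1d(u)[0])
        _validate_finite(x, u)
        return np.atleast_1d(u / p["V"] - p["k"] * x[0])

    def jac_x(t, x, u, p):
        return np.array([[-p["k"]]])

    def jac_u(t, x, u, p):
        return np.array([[1.0 / p["V"]]])

    return DynamicalSystem(
        state_names=("C",),
        input_dim=1,
        rhs=rhs,
        measure=_measure_first_state,
        x0=np.array([C0]),
        t0=0.0,
        params=params,
        rhs_jac_x=jac_x,
        rhs_jac_u=jac_u,
        measure_jac_x=_measure_first_state_jac_x,
        measure_jac_u=_measure_jac_u_zero,
        linear=True,
        name="linear1c",
    )


MODEL_REGISTRY = {
    "eflornithine": eflornithine_system,
    "guo_hall": guo_hall_system,
    "linear1c": linear_test_system,
}


def get_system(name: str, params: dict | None = None, **kwargs) -> DynamicalSystem:
    """Instantiate a registered model by name."""
    if name not in MODEL_REGISTRY:
        raise KeyError(f"unknown model '{name}'; known: {sorted(MODEL_REGISTRY)}")
    if name == "linear1c":
        return linear_test_system(**(params or {}), **kwargs)
    return MODEL_REGISTRY[name](params, **kwargs)


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


def _integration_segments(t_start, t_end, breakpoints, rhs_breakpoints=None):
    """Split [t_start, t_end] at input-function and rhs breakpoints
    (restarting the multistep solver there avoids order loss across jumps)."""
    pts = []
    for bp in (breakpoints, rhs_breakpoints):
        if bp is not None:
            pts.extend(b for b in np.asarray(bp) if t_start < b < t_end)
    edges = [t_start] + sorted(set(pts)) + [t_end]
    return list(zip(edges[:-1], edges[1:]))


def simulate(
    system: DynamicalSystem,
    input_fn,
    times,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
):
    """Simulate the system driven by ``input_fn`` and report states/outputs.

    Parameters
    ----------
    input_fn : an :class:`~inputest.basis.InputFunction`, a plain callable
        ``u(t)``, or None (zero input).
    times : strictly increasing evaluation times with ``times[0] >= t0``.

    Returns
    -------
    states : array (len(times), d_x)
    outputs : array (len(times), d_y)
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size == 0:
        raise ValueError("empty time vector")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < system.t0 - 1e-12:
        raise ValueError(f"times[0]={times[0]} precedes t0={system.t0}")

    if input_fn is None:
        u_of_t = lambda t: 0.0
        breakpoints = None
    elif callable(input_fn) and not hasattr(input_fn, "evaluate"):
        u_of_t = input_fn
        breakpoints = None
    else:
        u_of_t = lambda t: float(input_fn.evaluate(t))
        breakpoints = getattr(input_fn, "breakpoints", None)

    def odefun(t, x):
        return system.rhs(t, x, u_of_t(t), system.params)

    jac = None
    if system.rhs_jac_x is not None:
        jac = lambda t, x: system.rhs_jac_x(t, x, u_of_t(t), system.params)

    states = np.empty((times.size, system.d_x))
    x = system.x0.copy()
    filled = 0
    if abs(times[0] - system.t0) <= 1e-12:
        states[0] = x
        filled = 1
    for a, b in _integration_segments(system.t0, times[-1], breakpoints, system.rhs_breakpoints):
        requested = times[(times > a + 1e-15) & (times <= b + 1e-15)]
        t_eval = np.unique(np.append(requested, b))
        sol = solve_ivp(
            odefun,
            (a, b),
            x,
            method=method,
            rtol=rtol,
            atol=atol,
            jac=jac,
            t_eval=t_eval,
        )
        if not sol.success:
            raise SimulationError(
                f"ODE solver failed near t={sol.t[-1]}: {sol.message}", sol.t[-1]
            )
        for j, te in enumerate(sol.t):
            if filled < times.size and abs(te - times[filled]) <= 1e-12 + 1e-12 * abs(te):
                states[filled] = sol.y[:, j]
                filled += 1
        x = sol.y[:, -1]
    if filled != times.size:
        raise SimulationError("internal error: not all requested times reached")

    outputs = np.array(
        [
            np.atleast_1d(system.measure(t, s, u_of_t(t), system.params))
            for t, s in zip(times, states)
        ]
    )
    return states, outputs
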