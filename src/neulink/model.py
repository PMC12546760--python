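"""Single-compartment conductance-based neuron model.

The model is a Hodgkin-Huxley-type point neuron with seven membrane currents
(two sodium, three potassium, one high-threshold calcium, one leak) and 13
free parameters: passive properties (capacitance density C, input resistance
R_input, charging time constant tau, leak reversal E_leak), six maximal
conductance densities, the M-current time-constant scale tau_max, a
spike-threshold shift V_T, and a kinetic rate scale r_SS that multiplies the
gate rates of the gbar_Na and gbar_Kd currents.

Membrane equation (currents written so positive injected current
depolarizes)::

    C dV/dt = I_Na + I_Nat + I_Kd + I_M + I_Kv31 + I_L + I_leak + I_inj + I_noise

with each ionic current I_x = gbar_x * gates * (E_x - V).  Gates follow
first-order kinetics dx/dt = alpha_x(V)(1-x) - beta_x(V) x, integrated with
an exponential-Euler step; the voltage uses forward Euler.

Units: mV, ms, uF/cm^2 (C), mS/cm^2 (gbar), MOhm (R_input), pA (currents).
C and the conductances are densities while R_input and I_inj are absolute,
so an effective membrane area A = 1e-3 * tau / (R_input * C) cm^2 ties them
together: it is the unique area for which the passive time constant equals
tau and total leak conductance equals 1/R_input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "PRIOR_LOW",
    "PRIOR_HIGH",
    "PriorBox",
    "PhysConstants",
    "StimulusProtocol",
    "HHParameters",
    "sample_prior",
    "simulate",
    "simulate_batch",
    "steady_state_init",
    "passive_closed_form",
    "gate_rates",
    "GATE_NAMES",
]

#: canonical parameter order used by every matrix in the package
PARAM_NAMES = (
    "C",
    "R_input",
    "tau",
    "gbar_Nat",
    "gbar_Na",
    "gbar_Kd",
    "gbar_M",
    "gbar_Kv31",
    "gbar_L",
    "E_leak",
    "tau_max",
    "V_T",
    "r_SS",
)

PRIOR_LOW = np.array(
    [0.1, 20.0, 0.1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, -130.0, 50.0, -90.0, 0.1]
)
PRIOR_HIGH = np.array(
    [15.0, 1000.0, 70.0, 250.0, 100.0, 30.0, 3.0, 250.0, 3.0, -50.0, 4000.0, -35.0, 3.0]
)

GATE_NAMES = ("m", "h", "mt", "ht", "n", "p", "v", "q", "r")


@dataclass(frozen=True)
class HHParameters:
    """One point in the 13-dimensional biophysical parameter space."""

    C: float
    R_input: float
    tau: float
    gbar_Nat: float
    gbar_Na: float
    gbar_Kd: float
    gbar_M: float
    gbar_Kv31: float
    gbar_L: float
    E_leak: float
    tau_max: float
    V_T: float
    r_SS: float

    def __post_init__(self):
        if self.C <= 0 or self.R_input <= 0 or self.tau <= 0 or self.r_SS <= 0:
            raise ValueError("C, R_input, tau and r_SS must be positive")
        for g in ("gbar_Nat", "gbar_Na", "gbar_Kd", "gbar_M", "gbar_Kv31", "gbar_L"):
            if getattr(self, g) < 0:
                raise ValueError(f"conductance density {g} must be nonnegative")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "HHParameters":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (13,):
            raise ValueError("expected a length-13 parameter vector")
        return cls(**dict(zip(PARAM_NAMES, arr)))


@dataclass(frozen=True)
class PriorBox:
    """Axis-aligned uniform prior over the 13 parameters."""

    low: np.ndarray = field(default_factory=lambda: PRIOR_LOW.copy())
    high: np.ndarray = field(default_factory=lambda: PRIOR_HIGH.copy())

    def __post_init__(self):
        object.__setattr__(self, "low", np.atleast_1d(np.asarray(self.low, dtype=float)))
        object.__setattr__(self, "high", np.atleast_1d(np.asarray(self.high, dtype=float)))
        if self.low.shape != self.high.shape or self.low.ndim != 1:
            raise ValueError("bounds must be 1-D arrays of equal length")
        if not np.all(self.low < self.high):
            raise ValueError("every lower bound must be below its upper bound")

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        return np.all((theta >= self.low) & (theta <= self.high), axis=1)

    def replace(self, **bounds) -> "PriorBox":
        """New box with named parameter bounds overridden, e.g. gbar_Na=(0, 0.0001)."""
        low, high = self.low.copy(), self.high.copy()
        for name, (lo, hi) in bounds.items():
            i = PARAM_NAMES.index(name)
            low[i], high[i] = lo, hi
        return PriorBox(low, high)


@dataclass(frozen=True)
class PhysConstants:
    """Non-inferred physical constants of the model."""

    E_Na: float = 69.0       # mV, sodium reversal for the recording solutions used
    E_K: float = -90.0       # mV
    E_Ca: float = 120.0      # mV
    Q10: float = 2.3         # kinetic rate scaling per 10 degC
    T_experiment: float = 25.0   # degC, recording temperature
    T_ref_kinetics: float = 36.0  # degC, temperature the rate formulas are stated at
    I_inj: float = 300.0     # pA, step amplitude
    noise_mean: float = 10.0  # pA, mean of per-step current noise
    noise_sd: float = 1.0    # pA, SD of per-step current noise

    def __post_init__(self):
        if self.Q10 <= 0:
            raise ValueError("Q10 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def rate_scale(self) -> float:
        """Q10 temperature factor applied to all gate rates."""
        return self.Q10 ** ((self.T_experiment - self.T_ref_kinetics) / 10.0)


@dataclass(frozen=True)
class StimulusProtocol:
    """Square current step on a uniform time grid."""

    t_total: float = 800.0
    t_on: float = 100.0
    t_off: float = 700.0
    dt: float = 0.05
    noise_enabled: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.t_on < self.t_off <= self.t_total):
            raise ValueError("need 0 <= t_on < t_off <= t_total")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt


@dataclass
class VoltageTrace:
    """Membrane potential on a uniform grid, plus provenance."""

    t: np.ndarray
    vm: np.ndarray
    protocol: StimulusProtocol
    params: np.ndarray | None = None
    diverged: bool = False

    @property
    def dt(self) -> float:
        return self.protocol.dt


def sample_prior(n: int, box: PriorBox | None = None, seed: int | None = None) -> np.ndarray:
    """Draw ``n`` parameter vectors uniformly from the prior box.

    Returns an (n, 13) matrix in :data:`PARAM_NAMES` order.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    box = box or PriorBox()
    rng = np.random.default_rng(seed)
    u = rng.random((n, len(box.low)))
    return box.low + u * (box.high - box.low)


# ---------------------------------------------------------------------------
# Gate kinetics.  All rates in 1/ms, voltages in mV.  The m/h/n/p/q/r forms
# are those of the minimal cortical point-neuron model (with the V_T threshold
# shift and the tau_max M-current scale); mt/ht (fast transient Na) and v
# (Kv3.1) are the perisomatic channel forms.  `vtrap(x, y) = x / (exp(x/y)-1)`
# singularities are removed analytically.
# ---------------------------------------------------------------------------


def _exprel(x):
    """x / (exp(x) - 1), stable at x ~ 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7
    safe = np.where(small, 1.0, x)
    out = safe / np.expm1(safe)
    return np.where(small, 1.0 - x / 2.0, out)


def gate_rates(V, params_cols, constants: PhysConstants):
    """Opening/closing rates for all nine gates at membrane voltage ``V``.

    ``V`` is an array (any shape); ``params_cols`` maps parameter name ->
    array broadcastable against ``V`` (only tau_max, V_T, r_SS are used).
    Returns dict gate -> (alpha, beta), already scaled by the Q10 temperature
    factor, with r_SS applied to the m, h (gbar_Na current) and n (gbar_Kd
    current) gates.
    """
    V = np.asarray(V, dtype=float)
    VT = params_cols["V_T"]
    tau_max = params_cols["tau_max"]
    r_ss = params_cols["r_SS"]
    qt = constants.rate_scale

    rates = {}

    # transient Na of the minimal model (m, h), V_T-shifted
    u = V - VT
    a_m = 0.32 * 4.0 * _exprel(-(u - 13.0) / 4.0)
    b_m = 0.28 * 5.0 * _exprel((u - 40.0) / 5.0)
    a_h = 0.128 * np.exp(-(u - 17.0) / 18.0)
    b_h = 4.0 / (1.0 + np.exp(-(u - 40.0) / 5.0))
    rates["m"] = (r_ss * qt * a_m, r_ss * qt * b_m)
    rates["h"] = (r_ss * qt * a_h, r_ss * qt * b_h)

    # delayed-rectifier K (n), V_T-shifted
    a_n = 0.032 * 5.0 * _exprel(-(u - 15.0) / 5.0)
    b_n = 0.5 * np.exp(-(u - 10.0) / 40.0)
    rates["n"] = (r_ss * qt * a_n, r_ss * qt * b_n)

    # slow muscarinic K (p): steady-state/time-constant form
    p_inf = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    tau_p = tau_max / (3.3 * np.exp((V + 35.0) / 20.0) + np.exp(-(V + 35.0) / 20.0))
    rates["p"] = (qt * p_inf / tau_p, qt * (1.0 - p_inf) / tau_p)

    # fast transient Na, perisomatic form (mt, ht)
    a_mt = 0.182 * 6.0 * _exprel(-(V + 38.0) / 6.0)
    b_mt = 0.124 * 6.0 * _exprel((V + 38.0) / 6.0)
    a_ht = 0.015 * 6.0 * _exprel((V + 66.0) / 6.0)
    b_ht = 0.015 * 6.0 * _exprel(-(V + 66.0) / 6.0)
    rates["mt"] = (qt * a_mt, qt * b_mt)
    rates["ht"] = (qt * a_ht, qt * b_ht)

    # fast non-inactivating K, Kv3.1 (v): steady-state/time-constant form
    v_inf = 1.0 / (1.0 + np.exp(-(V - 18.7) / 9.7))
    tau_v = 4.0 / (1.0 + np.exp(-(V + 46.56) / 44.14))
    rates["v"] = (qt * v_inf / tau_v, qt * (1.0 - v_inf) / tau_v)

    # high-threshold Ca (q activation, r inactivation)
    a_q = 0.055 * 3.8 * _exprel((-27.0 - V) / 3.8)
    b_q = 0.94 * np.exp((-75.0 - V) / 17.0)
    a_r = 0.000457 * np.exp((-13.0 - V) / 50.0)
    b_r = 0.0065 / (np.exp((-15.0 - V) / 28.0) + 1.0)
    rates["q"] = (qt * a_q, qt * b_q)
    rates["r"] = (qt * a_r, qt * b_r)

    return rates


def _steady_gates(V, params_cols, constants):
    rates = gate_rates(V, params_cols, constants)
    return {g: a / (a + b) for g, (a, b) in rates.items()}


def steady_state_init(params, constants: PhysConstants | None = None):
    """Resting state: V0 = E_leak, every gate at its steady state there.

    ``params`` may be an :class:`HHParameters` or a length-13 vector.
    Returns ``(V0, gates)`` where gates maps gate name to open fraction.
    """
    constants = constants or PhysConstants()
    theta = params.to_array() if isinstance(params, HHParameters) else np.asarray(params, float)
    cols = {k: theta[i] for i, k in enumerate(PARAM_NAMES)}
    V0 = cols["E_leak"]
    return V0, _steady_gates(V0, cols, constants)


def passive_closed_form(params, protocol: StimulusProtocol,
                        constants: PhysConstants | None = None) -> VoltageTrace:
    """Analytic RC response to the current step (all active conductances zero).

    Charging from E_leak with time constant tau toward
    ``E_leak + R_input * I_inj`` during the step, discharging after it.  Used
    as the oracle for the passive limit of the numerical integrator; by
    construction the deflection at ``t_on + tau`` is ``(1 - 1/e)`` of the
    steady-state deflection ``R_input * I_inj``.
    """
    constants = constants or PhysConstants()
    if protocol.noise_enabled:
        raise ValueError("closed form is only defined for the noise-free protocol")
    theta = params.to_array() if isinstance(params, HHParameters) else np.asarray(params, float)
    cols = dict(zip(PARAM_NAMES, theta))
    t = protocol.time_grid()
    # MOhm * pA = 1e6 * 1e-12 V = 1e-6 V -> 1e-3 mV
    dV_ss = cols["R_input"] * constants.I_inj * 1e-3
    tau = cols["tau"]
    vm = np.full_like(t, cols["E_leak"])
    on = (t >= protocol.t_on) & (t < protocol.t_off)
    vm[on] += dV_ss * (1.0 - np.exp(-(t[on] - protocol.t_on) / tau))
    after = t >= protocol.t_off
    v_off = dV_ss * (1.0 - np.exp(-(protocol.t_off - protocol.t_on) / tau))
    vm[after] += v_off * np.exp(-(t[after] - protocol.t_off) / tau)
    return VoltageTrace(t=t, vm=vm, protocol=protocol, params=theta.copy())


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

_V_DIVERGE = 500.0  # |mV| beyond which the trace is flagged as diverged

# currents: (conductance param, reversal attr, gate expression)
_GATE_ORDER = list(GATE_NAMES)


def _noise_streams(master_seed: int, indices: np.ndarray, n_steps: int,
                   mean: float, sd: float) -> np.ndarray:
    """Per-simulation counter-based noise, invariant to batching.

    Simulation i always sees the stream keyed by (master_seed, i), so a
    campaign sharded into any batch sizes reproduces identical traces.
    """
    out = np.empty((len(indices), n_steps))
    for row, i in enumerate(indices):
        bg = np.random.Philox(key=np.array([master_seed, int(i)], dtype=np.uint64))
        out[row] = np.random.Generator(bg).normal(mean, sd, n_steps)
    return out


def simulate_batch(theta: np.ndarray, protocol: StimulusProtocol | None = None,
                   constants: PhysConstants | None = None,
                   sim_indices: np.ndarray | None = None,
                   record_gate_range: bool = False):
    """Integrate a batch of parameter vectors under the same protocol.

    Parameters
    ----------
    theta : (n, 13) array in PARAM_NAMES order.
    sim_indices : optional global simulation indices for the counter-based
        noise streams (defaults to 0..n-1).
    record_gate_range : if True, also return per-gate running (min, max)
        over all steps and simulations — used by invariant tests.

    Returns
    -------
    vm : (n, n_steps+1) float array of membrane voltage
    diverged : (n,) bool
    gate_range : dict gate -> (min, max), only if requested
    """
    protocol = protocol or StimulusProtocol()
    constants = constants or PhysConstants()
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    n, d = theta.shape
    if d != 13:
        raise ValueError("theta must have 13 columns")
    dt = protocol.dt
    n_steps = protocol.n_steps

    cols = {k: theta[:, i].copy() for i, k in enumerate(PARAM_NAMES)}
    # effective membrane area (cm^2) reconciling density and absolute units
    area = 1e-3 * cols["tau"] / (cols["R_input"] * cols["C"])
    cap = cols["C"] * area * 1e6          # pF
    g_abs = {g: cols[g] * area * 1e6 for g in
             ("gbar_Nat", "gbar_Na", "gbar_Kd", "gbar_M", "gbar_Kv31", "gbar_L")}  # nS
    g_leak = 1e3 / cols["R_input"]        # nS

    V = cols["E_leak"].copy()
    gates = _steady_gates(V, cols, constants)

    if protocol.noise_enabled:
        idx = np.arange(n) if sim_indices is None else np.asarray(sim_indices)
        noise = _noise_streams(protocol.seed, idx, n_steps,
                               constants.noise_mean, constants.noise_sd)
    else:
        noise = None

    vm = np.empty((n, n_steps + 1))
    vm[:, 0] = V
    alive = np.ones(n, dtype=bool)
    # integer step window for the stimulus avoids float accumulation drift
    step_on = int(round(protocol.t_on / dt))
    step_off = int(round(protocol.t_off / dt))
    E_Na, E_K, E_Ca = constants.E_Na, constants.E_K, constants.E_Ca

    if record_gate_range:
        gmin = {g: np.inf for g in GATE_NAMES}
        gmax = {g: -np.inf for g in GATE_NAMES}

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for step in range(n_steps):
            Vc = np.clip(V, -200.0, 200.0)
            rates = gate_rates(Vc, cols, constants)
            for g in _GATE_ORDER:
                a, b = rates[g]
                s = a + b
                x_inf = a / s
                gates[g] = x_inf + (gates[g] - x_inf) * np.exp(-dt * s)
            if record_gate_range:
                for g in GATE_NAMES:
                    gmin[g] = min(gmin[g], float(np.min(gates[g][alive], initial=np.inf)))
                    gmax[g] = max(gmax[g], float(np.max(gates[g][alive], initial=-np.inf)))

            m, h, mt, ht = gates["m"], gates["h"], gates["mt"], gates["ht"]
            nn, p, v, q, r = gates["n"], gates["p"], gates["v"], gates["q"], gates["r"]
            # with gates frozen over the step the membrane equation is linear
            # in V; integrate it exactly (exponential Euler), which keeps the
            # smallest-tau cells of the prior stable at the default dt
            g_na = g_abs["gbar_Na"] * m ** 3 * h + g_abs["gbar_Nat"] * mt ** 3 * ht
            g_k = (g_abs["gbar_Kd"] * nn ** 4 + g_abs["gbar_M"] * p
                   + g_abs["gbar_Kv31"] * v)
            g_ca = g_abs["gbar_L"] * q ** 2 * r
            G = g_na + g_k + g_ca + g_leak
            S = g_na * E_Na + g_k * E_K + g_ca * E_Ca + g_leak * cols["E_leak"]
            if step_on <= step < step_off:
                S = S + constants.I_inj
            if noise is not None:
                S = S + noise[:, step]

            V_inf = S / G
            V = V_inf + (V - V_inf) * np.exp(-dt * G / cap)
            bad = ~np.isfinite(V) | (np.abs(V) > _V_DIVERGE)
            if np.any(bad & alive):
                alive &= ~bad
                V = np.where(bad, vm[:, step], V)  # freeze diverged cells
            vm[:, step + 1] = V

    diverged = ~alive
    vm[diverged] = np.nan
    if record_gate_range:
        return vm, diverged, {g: (gmin[g], gmax[g]) for g in GATE_NAMES}
    return vm, diverged


def simulate(params, protocol: StimulusProtocol | None = None,
             constants: PhysConstants | None = None) -> VoltageTrace:
    """Integrate a single parameter set; see :func:`simulate_batch`."""
    protocol = protocol or StimulusProtocol()
    constants = constants or PhysConstants()
    theta = params.to_array() if isinstance(params, HHParameters) else np.asarray(params, float)
    vm, diverged = simulate_batch(theta[None, :], protocol, constants)
    return VoltageTrace(t=protocol.time_grid(), vm=vm[0], protocol=protocol,
                        params=theta.copy(), diverged=bool(diverged[0]))
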