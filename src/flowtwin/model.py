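"""Closed-loop 0-D hemodynamic model and forward simulation.

Network (nine states, volumes in mL and flows in mL/s)::

    reservoir (C_ven) --R_pv--> LA (E_la(t)) --[mitral R_mv,L_mv,diode]-->
    LV (E_lv(t)) --[aortic valve: energy-loss gradient, B_av, diode]-->
    ascending aorta (C_aa, measurement plane) --R_ao,L_ao-->
    arch/descending (C_dsc) --R_dsc--> peripheral Windkessel (C_art)
    --R_p--> reservoir

The loop is closed: the sum of the six compartment volume derivatives is
identically zero, so total blood volume is conserved to integration
tolerance.  Valves are diodes realized as a smooth reverse-blocking
resistance ``R_leak * sigma(-(Q + q0)/q_s)`` that is negligible for forward
flow and blocks reverse flow beyond a small leakage ``epsilon`` of order
|dP|/R_leak ~ 0.1-1 mL/s (see docs/methods.md).  The convective aortic
gradient follows the energy-loss formulation exactly:
``rho/(2*ELCo^2) * Q*|Q| * (0.06/133.322)`` in mmHg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .parameters import ElastanceParams, ModelParameters, ValveParams
from .units import CONVECTIVE_MMHG

# diode smoothing: resistance ramps up over a q_s-wide window centred q0
# below zero flow, so forward flow sees essentially no extra resistance
_DIODE_Q0 = 1.0   # mL/s
_DIODE_QS = 0.2   # mL/s

#: documented numerical leakage bound for closed valves, mL/s
VALVE_LEAK_EPS = 1.5

STATE_NAMES = ("V_la", "V_lv", "V_aa", "V_dsc", "V_art", "V_ven",
               "Q_mv", "Q_av", "Q_aa")


def normalized_activation(t, p: ElastanceParams, T: float):
    """Normalized double-Hill activation g(t) = h(t)/h(t_max) on [0, T).

    ``h(t) = [(t/(alpha_S*T))^R_C / (1 + (t/(alpha_S*T))^R_C)] *
    [1 / (1 + (t/(alpha_D*T))^R_R)]``.  g(0) = 0 and g(t_max) = 1 by
    construction; g stays within [0, 1] when ``t_max`` sits at the
    intrinsic peak of h (the default parameter sets are chosen that way).

    Accepts scalar or array ``t``; raises on a non-finite result, naming
    the offending exponent.
    """
    p.validate(T)
    t = np.asarray(t, dtype=float)
    with np.errstate(over="raise", invalid="raise"):
        try:
            xs = (t / (p.alpha_S * T)) ** p.R_C
        except FloatingPointError as exc:
            raise FloatingPointError(
                f"contraction exponent R_C={p.R_C} overflows at t={t}"
            ) from exc
        try:
            xd = (t / (p.alpha_D * T)) ** p.R_R
        except FloatingPointError as exc:
            raise FloatingPointError(
                f"relaxation exponent R_R={p.R_R} overflows at t={t}"
            ) from exc
    h = xs / (1.0 + xs) / (1.0 + xd)
    xm_s = (p.t_max / (p.alpha_S * T)) ** p.R_C
    xm_d = (p.t_max / (p.alpha_D * T)) ** p.R_R
    h_max = xm_s / (1.0 + xm_s) / (1.0 + xm_d)
    g = h / h_max
    if not np.all(np.isfinite(g)):
        raise FloatingPointError(
            f"non-finite activation for R_C={p.R_C}, R_R={p.R_R}"
        )
    return g if g.ndim else float(g)


def intrinsic_peak_time(p: ElastanceParams, T: float, n: int = 20001) -> float:
    """Dense-grid argmax of the unnormalized double-Hill curve h(t)."""
    t = np.linspace(T / n, T, n)
    xs = (t / (p.alpha_S * T)) ** p.R_C
    xd = (t / (p.alpha_D * T)) ** p.R_R
    h = xs / (1.0 + xs) / (1.0 + xd)
    return float(t[np.argmax(h)])


def elastance(t, p: ElastanceParams, T: float):
    """Time-varying elastance E(t) = E_min + (E_max - E_min) * g(t), mmHg/mL."""
    return p.E_min + (p.E_max - p.E_min) * normalized_activation(t, p, T)


def valve_pressure_gradient(Q, dQdt, v: ValveParams, B: float | None = None):
    """Net transvalvular pressure gradient, mmHg.

    ``dP = rho/(2*ELCo^2) * Q*|Q| * (0.06/133.322) + B*dQdt``.  The
    convective part is antisymmetric in Q; the inertial coefficient B
    defaults to ``2*pi*rho/sqrt(EOA) * (0.06/133.322)`` and can be
    disabled by passing ``B=0``.
    """
    K = v.rho / (2.0 * v.ELCo**2) * CONVECTIVE_MMHG
    if B is None:
        B = default_inertial_coefficient(v)
    Q = np.asarray(Q, dtype=float)
    out = K * Q * np.abs(Q) + B * np.asarray(dQdt, dtype=float)
    return out if out.ndim else float(out)


def default_inertial_coefficient(v: ValveParams) -> float:
    """Garcia-type inertial coefficient B = 2*pi*rho/sqrt(EOA), in mmHg*s^2/mL."""
    return 2.0 * math.pi * v.rho / math.sqrt(v.EOA) * CONVECTIVE_MMHG


# ---------------------------------------------------------------------------
# compiled right-hand side
# ---------------------------------------------------------------------------

# indices into the packed parameter vector
_PV_FIELDS = (
    "E_max_lv", "E_min_lv", "R_C_lv", "R_R_lv", "alpha_S_lv", "alpha_D_lv",
    "t_max_lv", "V0_lv",
    "E_max_la", "E_min_la", "R_C_la", "R_R_la", "alpha_S_la", "alpha_D_la",
    "t_max_la", "V0_la",
    "K_av", "B_av", "R_mv", "L_mv",
    "C_aa", "V0_aa", "R_ao", "L_ao",
    "C_dsc", "V0_dsc", "R_dsc",
    "C_art", "V0_art", "R_p",
    "C_ven", "V0_ven", "R_pv",
    "R_leak", "t_onset_la", "T",
)
_PV_INDEX = {name: i for i, name in enumerate(_PV_FIELDS)}


def pack_parameter_vector(params: ModelParameters) -> np.ndarray:
    """Flatten a ModelParameters into the vector the compiled RHS consumes."""
    valve = params.valve
    K_av = valve.rho / (2.0 * valve.ELCo**2) * CONVECTIVE_MMHG
    pv = np.empty(len(_PV_FIELDS))
    for name, i in _PV_INDEX.items():
        if name == "K_av":
            pv[i] = K_av
        else:
            pv[i] = params[name]
    return pv


@njit(cache=True)
def _activation(tc, aS, aD, RC, RR, tmax, T):
    if tc <= 0.0:
        return 0.0
    xs = (tc / (aS * T)) ** RC
    xd = (tc / (aD * T)) ** RR
    h = xs / (1.0 + xs) / (1.0 + xd)
    xms = (tmax / (aS * T)) ** RC
    xmd = (tmax / (aD * T)) ** RR
    hm = xms / (1.0 + xms) / (1.0 + xmd)
    return h / hm


@njit(cache=True)
def _rhs(t, y, pv):
    T = pv[35]
    tc = t % T
    g_lv = _activation(tc, pv[4], pv[5], pv[2], pv[3], pv[6], T)
    tla = (tc - pv[34]) % T
    g_la = _activation(tla, pv[12], pv[13], pv[10], pv[11], pv[14], T)

    E_lv = pv[1] + (pv[0] - pv[1]) * g_lv
    E_la = pv[9] + (pv[8] - pv[9]) * g_la

    V_la, V_lv, V_aa, V_dsc, V_art, V_ven, Q_mv, Q_av, Q_aa = (
        y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7], y[8])

    P_la = E_la * (V_la - pv[15])
    P_lv = E_lv * (V_lv - pv[7])
    P_aa = (V_aa - pv[21]) / pv[20]
    P_dsc = (V_dsc - pv[25]) / pv[24]
    P_art = (V_art - pv[28]) / pv[27]
    P_ven = (V_ven - pv[31]) / pv[30]

    # smooth diodes: reverse-blocking resistance
    a_mv = (Q_mv + _DIODE_Q0) / _DIODE_QS
    a_av = (Q_av + _DIODE_Q0) / _DIODE_QS
    sig_mv = 1.0 / (1.0 + math.exp(min(a_mv, 50.0)))
    sig_av = 1.0 / (1.0 + math.exp(min(a_av, 50.0)))

    dQ_mv = (P_la - P_lv - pv[18] * Q_mv - pv[33] * sig_mv * Q_mv) / pv[19]
    dQ_av = (P_lv - P_aa - pv[16] * Q_av * abs(Q_av) - pv[33] * sig_av * Q_av) / pv[17]
    dQ_aa = (P_aa - P_dsc - pv[22] * Q_aa) / pv[23]
    Q_dsc = (P_dsc - P_art) / pv[26]
    Q_per = (P_art - P_ven) / pv[29]
    Q_pv = (P_ven - P_la) / pv[32]

    out = np.empty(9)
    out[0] = Q_pv - Q_mv
    out[1] = Q_mv - Q_av
    out[2] = Q_av - Q_aa
    out[3] = Q_aa - Q_dsc
    out[4] = Q_dsc - Q_per
    out[5] = Q_per - Q_pv
    out[6] = dQ_mv
    out[7] = dQ_av
    out[8] = dQ_aa
    return out


def ode_rhs(t: float, state: np.ndarray, params: ModelParameters) -> np.ndarray:
    """State derivative of the closed-loop model at time ``t``.

    Thin, validated wrapper over the compiled kernel; chamber volume
    derivatives are inflow minus outflow and their sum is exactly zero.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (9,):
        raise ValueError(f"state must have 9 entries {STATE_NAMES}, got {state.shape}")
    if not np.all(np.isfinite(state)):
        raise FloatingPointError(f"non-finite state at t={t}: {state}")
    return _rhs(float(t), state, pack_parameter_vector(params))


def initial_state(params: ModelParameters) -> np.ndarray:
    """A physiological cold-start state.

    Stressed volumes are built from fixed parameters only, so the total
    (conserved) blood volume is a study constant and does not shift when
    subject-specific parameters are optimized.
    """
    v = params.values
    y = np.empty(9)
    y[0] = v["V0_la"] + 60.0
    y[1] = 120.0  # nominal end-diastolic LV volume, mL
    y[2] = v["V0_aa"] + 25.0
    y[3] = v["V0_dsc"] + 50.0
    y[4] = v["V0_art"] + 85.0
    y[5] = v["V0_ven"] + v["P_ven0"] * v["C_ven"]
    y[6:] = 0.0
    return y


@dataclass
class SimulationResult:
    """Hemodynamics over one converged cardiac cycle."""

    time: np.ndarray        # s, uniform over [0, T]
    p_lv: np.ndarray        # LV pressure, mmHg
    p_la: np.ndarray        # LA pressure, mmHg
    p_ao: np.ndarray        # ascending-aorta pressure, mmHg
    p_art: np.ndarray       # peripheral arterial pressure, mmHg
    v_lv: np.ndarray        # LV volume, mL
    v_la: np.ndarray        # LA volume, mL
    q_mv: np.ndarray        # mitral flow, mL/s
    q_av: np.ndarray        # aortic-valve flow, mL/s
    q_aa: np.ndarray        # ascending-aorta plane flow, mL/s
    converged: bool
    n_cycles: int
    drift_history: list = field(default_factory=list)
    final_state: np.ndarray | None = None

    @property
    def T(self) -> float:
        return float(self.time[-1])

    @property
    def sbp(self) -> float:
        """Peak aortic pressure, mmHg."""
        return float(np.max(self.p_ao))

    @property
    def dbp(self) -> float:
        """Minimum aortic pressure, mmHg."""
        return float(np.min(self.p_ao))

    @property
    def esv(self) -> float:
        """LV end-systolic (minimum) volume, mL."""
        return float(np.min(self.v_lv))

    @property
    def edv(self) -> float:
        return float(np.max(self.v_lv))

    def mean_flow(self, site: str) -> float:
        q = {"mitral_valve": self.q_mv, "aortic_valve": self.q_av,
             "ascending_aorta": self.q_aa}[site]
        return float(np.trapezoid(q, self.time) / self.T)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_s": self.time,
            "p_lv_mmHg": self.p_lv, "p_la_mmHg": self.p_la,
            "p_ao_mmHg": self.p_ao, "p_art_mmHg": self.p_art,
            "v_lv_mL": self.v_lv, "v_la_mL": self.v_la,
            "q_mv_mL_s": self.q_mv, "q_av_mL_s": self.q_av,
            "q_aa_mL_s": self.q_aa,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class SimulationError(RuntimeError):
    pass


def simulate(
    params: ModelParameters,
    n_cycles_max: int = 30,
    periodicity_tol: float = 1e-3,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    n_samples: int = 241,
    y0: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate cycle by cycle to periodic steady state and return one cycle.

    Convergence: the maximum relative change of the state between
    consecutive cycle starts falls below ``periodicity_tol`` (state scaled
    by max(|y|, 1)).  ``y0`` allows warm-starting from a previous converged
    state, which typically cuts the transient to 1-3 cycles.
    """
    params.validate()
    pv = pack_parameter_vector(params)
    T = params["T"]
    y = initial_state(params) if y0 is None else np.asarray(y0, dtype=float).copy()

    ts = np.linspace(0.0, T, n_samples)
    drift_history: list[float] = []
    converged = False
    n_cycles = 0
    Y = None
    for _ in range(n_cycles_max):
        # every cycle is sampled on the report grid, so the cycle that
        # satisfies the periodicity check is itself the reported cycle
        sol = solve_ivp(_rhs, (0.0, T), y, args=(pv,), method="LSODA",
                        rtol=rtol, atol=atol, t_eval=ts)
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            raise SimulationError(
                f"integration failed at cycle {n_cycles + 1}, t={sol.t[-1]:.4f}: "
                f"{sol.message}"
            )
        y_new = sol.y[:, -1]
        drift = float(np.max(np.abs(y_new - y) / np.maximum(np.abs(y), 1.0)))
        drift_history.append(drift)
        y = y_new
        Y = sol.y
        n_cycles += 1
        if drift < periodicity_tol:
            converged = True
            break

    lv, la = params.lv_elastance, params.la_elastance
    E_lv = elastance(ts, lv, T)
    tla = np.mod(ts - params["t_onset_la"], T)
    E_la = elastance(tla, la, T)
    v = params.values
    res = SimulationResult(
        time=ts,
        p_lv=E_lv * (Y[1] - lv.V0),
        p_la=E_la * (Y[0] - la.V0),
        p_ao=(Y[2] - v["V0_aa"]) / v["C_aa"],
        p_art=(Y[4] - v["V0_art"]) / v["C_art"],
        v_lv=Y[1],
        v_la=Y[0],
        q_mv=Y[6],
        q_av=Y[7],
        q_aa=Y[8],
        converged=converged,
        n_cycles=n_cycles,
        drift_history=drift_history,
        final_state=y.copy(),
    )
    if np.any(Y[:6] <= 0):
        raise SimulationError("non-physical state: a compartment volume went <= 0")
    return res


__all__ = [
    "normalized_activation", "elastance", "intrinsic_peak_time",
    "valve_pressure_gradient", "default_inertial_coefficient",
    "ode_rhs", "initial_state", "simulate",
    "SimulationResult", "SimulationError", "STATE_NAMES", "VALVE_LEAK_EPS",
]
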