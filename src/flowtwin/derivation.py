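"""Derivation of model inputs from measured waveforms and scalars.

Mirrors the image-analysis outputs an observer produces per analysis
occasion: cycle length T, effective orifice area EOA (stroke volume over
velocity-time integral), the energy-loss coefficient ELCo, and the directly
estimated maximal LV elastance, which anchor the personalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .parameters import (
    MEASUREMENT_ANCHORED,
    ModelParameters,
    derive_elco,
)
from .units import CONVECTIVE_MMHG

SITES = ("mitral_valve", "aortic_valve", "ascending_aorta")

#: systolic support for the VTI: samples where q_av exceeds this fraction of
#: its peak (avoids counting diastolic noise in the integral)
SYSTOLE_FLOW_FRACTION = 0.01

#: default LV unstressed volume used in the E_max derivation, mL
V0_LV_DEFAULT = 10.0


@dataclass(frozen=True)
class FlowWaveform:
    """One periodic volumetric flow trace at a named site."""

    site: str            # mitral_valve | aortic_valve | ascending_aorta
    time: np.ndarray     # s, strictly increasing, last sample < T
    flow: np.ndarray     # mL/s
    T: float             # cycle length, s

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}, expected one of {SITES}")
        t = np.asarray(self.time, dtype=float)
        q = np.asarray(self.flow, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "flow", q)
        if t.ndim != 1 or t.shape != q.shape:
            raise ValueError("time and flow must be matching 1-D arrays")
        if len(t) < 20:
            raise ValueError(f"need >= 20 samples per cycle, got {len(t)}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if not (self.T > 0 and t[-1] < self.T):
            raise ValueError(f"last sample time {t[-1]} must be < T={self.T}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(q))):
            raise ValueError("waveform contains non-finite values")

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.flow)))


@dataclass(frozen=True)
class VelocityTrace:
    """Instantaneous maximal velocity at the aortic valve, cm/s."""

    time: np.ndarray   # s
    velocity: np.ndarray  # cm/s

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.velocity, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "velocity", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time and velocity must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")


@dataclass(frozen=True)
class MeasurementBundle:
    """All per-subject model inputs for one analysis occasion."""

    subject_id: str
    occasion: str          # observer1_a | observer1_b | observer2 | sgre | epi
    T: float               # cardiac cycle length, s
    ESV: float             # LV end-systolic volume, mL
    EOA: float             # aortic-valve effective orifice area, cm^2
    A_LVOT: float          # LV outflow-tract area, cm^2
    SBP: float             # brachial systolic pressure, mmHg
    DBP: float             # brachial diastolic pressure, mmHg
    waveforms: dict = field(default_factory=dict)  # site -> FlowWaveform
    velocity: VelocityTrace | None = None

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"T must be > 0, got {self.T}")
        if self.ESV <= 0:
            raise ValueError(f"ESV must be > 0, got {self.ESV}")
        if not (0 < self.EOA < self.A_LVOT):
            raise ValueError(
                f"need 0 < EOA < A_LVOT, got EOA={self.EOA}, A_LVOT={self.A_LVOT}"
            )
        if not (self.SBP > self.DBP > 0):
            raise ValueError(f"need SBP > DBP > 0, got {self.SBP}/{self.DBP}")
        for site, w in self.waveforms.items():
            if w.site != site:
                raise ValueError(f"waveform stored under {site} is tagged {w.site}")
            if abs(w.T - self.T) > 1e-9 * max(1.0, self.T):
                raise ValueError(
                    f"waveform at {site} has cycle length {w.T}, bundle has {self.T}"
                )


def derive_eoa(q_av: FlowWaveform, v: VelocityTrace) -> float:
    """Effective orifice area EOA = SV / VTI, cm^2.

    SV is the trapezoidal time integral of the aortic-valve flow over the
    cycle (mL); VTI integrates the peak-velocity trace over the systolic
    support, defined as the contiguous samples where the flow exceeds 1 % of
    its peak (cm).
    """
    if q_av.site != "aortic_valve":
        raise ValueError(f"EOA needs the aortic-valve waveform, got {q_av.site}")
    if len(q_av.time) != len(v.time) or not np.allclose(q_av.time, v.time):
        raise ValueError("flow and velocity traces must share the sample grid")
    sv = float(np.trapezoid(q_av.flow, q_av.time))
    support = q_av.flow > SYSTOLE_FLOW_FRACTION * np.max(q_av.flow)
    if support.sum() < 2:
        raise ValueError("no systolic support found in the aortic-valve flow")
    vti = float(np.trapezoid(np.where(support, v.velocity, 0.0), v.time))
    if vti <= 0:
        raise ValueError(f"velocity-time integral must be > 0, got {vti}")
    return sv / vti


def max_pressure_gradient(q_av_peak: float, EOA: float, A_LVOT: float,
                          rho: float = 1.06) -> float:
    """Peak convective transvalvular gradient, mmHg.

    ``rho/(2*ELCo^2) * max(AV flow)^2 * (0.06/133.322)``.
    """
    elco = derive_elco(EOA, A_LVOT)
    return rho / (2.0 * elco**2) * q_av_peak**2 * CONVECTIVE_MMHG


def derive_emax_lv(bundle: MeasurementBundle, V0_lv: float = V0_LV_DEFAULT,
                   rho: float = 1.06) -> float:
    """Directly estimated maximal LV elastance, mmHg/mL.

    ``E_max = 0.9 * (SBP + PG_max) / (ESV - V0_lv)`` with PG_max the peak
    convective transvalvular gradient from the aortic-valve flow waveform.
    """
    if "aortic_valve" not in bundle.waveforms:
        raise ValueError("bundle lacks the aortic-valve flow waveform")
    if bundle.ESV <= V0_lv:
        raise ValueError(
            f"ESV={bundle.ESV} must exceed V0_lv={V0_lv} for the elastance estimate"
        )
    q_peak = float(np.max(bundle.waveforms["aortic_valve"].flow))
    pg = max_pressure_gradient(q_peak, bundle.EOA, bundle.A_LVOT, rho)
    return 0.9 * (bundle.SBP + pg) / (bundle.ESV - V0_lv)


def assemble_parameters(
    bundle: MeasurementBundle,
    defaults: ModelParameters | None = None,
    V0_lv: float | None = None,
    anchor_window: float = 0.10,
) -> ModelParameters:
    """Build the starting parameter set for one occasion.

    T is copied from the bundle and never optimized.  EOA, A_LVOT and
    E_max_lv are set to their derived values with +/-``anchor_window``
    (default 10 %) bounds.  The remaining 20 free parameters keep the
    supplied defaults and documented bounds; the 17 fixed parameters are
    untouched.  Pure function: ``defaults`` is not modified.
    """
    if defaults is None:
        defaults = ModelParameters()
    if V0_lv is None:
        V0_lv = defaults["V0_lv"]
    emax = derive_emax_lv(bundle, V0_lv=V0_lv, rho=defaults["rho"])
    # rescale cycle-phase parameters given in seconds to the measured T
    scale = bundle.T / defaults["T"]
    updates = {
        "T": bundle.T,
        "t_max_lv": defaults["t_max_lv"] * scale,
        "t_max_la": defaults["t_max_la"] * scale,
        "t_onset_la": defaults["t_onset_la"] * scale,
        "EOA": bundle.EOA,
        "A_LVOT": bundle.A_LVOT,
        "E_max_lv": emax,
    }
    out = defaults.with_values(**updates)
    windows = {
        name: (out[name] * (1 - anchor_window), out[name] * (1 + anchor_window))
        for name in MEASUREMENT_ANCHORED
    }
    return out.with_bounds(**windows)


__all__ = [
    "FlowWaveform", "VelocityTrace", "MeasurementBundle", "SITES",
    "derive_eoa", "derive_elco", "derive_emax_lv", "max_pressure_gradient",
    "assemble_parameters", "V0_LV_DEFAULT", "replace",
]
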