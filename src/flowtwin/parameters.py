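"""The 40-parameter closed-loop circulation parameter set.

The model couples a pulmonary-venous/venous reservoir, a left atrium and a
left ventricle (both time-varying elastance chambers), a mitral valve
(resistance + inertance, diode), an energy-loss aortic valve, an
ascending-aorta compliance with a flow measurement plane upstream of the
brachiocephalic trunk, an arch/descending RLC segment, and a peripheral
Windkessel that returns blood to the reservoir.

Exactly 23 of the 40 parameters are flagged subject-specific (free): the
three measurement-anchored parameters (``EOA``, ``A_LVOT``, ``E_max_lv``,
each given a +/-10 % window around its derived value) plus 20 tuned by the
optimizer.  The remaining 17 — cycle length ``T`` among them — are fixed:
``T`` is copied directly from the measurements and never optimized, and the
other 16 are population-level constants taken from the modelling literature
for healthy adults.  All defaults can be overridden.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping


@dataclass(frozen=True)
class ElastanceParams:
    """Shape parameters of one time-varying-elastance chamber.

    The normalized activation is a double-Hill curve: a rising Hill factor
    with exponent ``R_C`` (rate of contraction) and characteristic time
    ``alpha_S * T`` (systolic time constant), multiplied by a falling Hill
    factor with exponent ``R_R`` (rate of relaxation) and characteristic
    time ``alpha_D * T`` (diastolic time constant).  Maximal elastance
    ``E_max`` occurs at the time of end-systole ``t_max`` where the
    activation is normalized to one.
    """

    E_max: float  # maximal (end-systolic) elastance, mmHg/mL
    E_min: float  # minimal (passive) elastance, mmHg/mL
    R_C: float    # contraction-rate Hill exponent, dimensionless
    R_R: float    # relaxation-rate Hill exponent, dimensionless
    alpha_S: float  # systolic time constant, fraction of cycle
    alpha_D: float  # diastolic time constant, fraction of cycle
    t_max: float    # time of end-systole (maximal elastance), s
    V0: float = 0.0  # unstressed chamber volume, mL

    def validate(self, T: float) -> None:
        if not (self.E_max > self.E_min > 0):
            raise ValueError(
                f"need E_max > E_min > 0, got E_max={self.E_max}, E_min={self.E_min}"
            )
        if self.R_C <= 0 or self.R_R <= 0:
            raise ValueError(f"Hill exponents must be > 0 (R_C={self.R_C}, R_R={self.R_R})")
        if not (0 < self.alpha_S < 1 and 0 < self.alpha_D < 1):
            raise ValueError(
                f"time constants must lie in (0, 1): alpha_S={self.alpha_S}, alpha_D={self.alpha_D}"
            )
        if not (0 < self.t_max < T):
            raise ValueError(f"t_max={self.t_max} must lie in (0, T={T})")
        if self.V0 < 0:
            raise ValueError(f"V0 must be >= 0, got {self.V0}")


@dataclass(frozen=True)
class ValveParams:
    """Energy-loss description of the aortic valve.

    ``ELCo = EOA * A_LVOT / (A_LVOT - EOA)`` is the effective area governing
    the net transvalvular pressure loss.
    """

    EOA: float      # effective orifice area, cm^2
    A_LVOT: float   # LV outflow tract area, cm^2
    rho: float = 1.06  # blood density, g/mL

    def __post_init__(self) -> None:
        if not (0 < self.EOA < self.A_LVOT):
            raise ValueError(
                f"need 0 < EOA < A_LVOT (valve area exceeds outflow tract): "
                f"EOA={self.EOA}, A_LVOT={self.A_LVOT}"
            )
        if self.rho <= 0:
            raise ValueError(f"rho must be > 0, got {self.rho}")

    @property
    def ELCo(self) -> float:
        """Energy-loss coefficient, cm^2."""
        return self.EOA * self.A_LVOT / (self.A_LVOT - self.EOA)


@dataclass(frozen=True)
class ParamSpec:
    """Metadata for one scalar model parameter."""

    name: str
    default: float
    lower: float
    upper: float
    free: bool
    unit: str
    doc: str


# name, default, lower, upper, free, unit, description
_SPECS = [
    # --- left-ventricular elastance ------------------------------------
    ("E_max_lv", 2.0, 1.0, 4.0, True, "mmHg/mL", "maximal LV elastance"),
    ("E_min_lv", 0.06, 0.02, 0.15, True, "mmHg/mL", "passive LV elastance"),
    ("R_C_lv", 1.9, 1.0, 4.0, True, "-", "LV contraction-rate exponent"),
    ("R_R_lv", 21.9, 8.0, 40.0, True, "-", "LV relaxation-rate exponent"),
    ("alpha_S_lv", 0.22, 0.10, 0.40, True, "-", "LV systolic time constant (fraction of T)"),
    ("alpha_D_lv", 0.40, 0.25, 0.60, True, "-", "LV diastolic time constant (fraction of T)"),
    ("t_max_lv", 0.34, 0.20, 0.50, True, "s", "time of LV end-systole"),
    # --- left-atrial elastance (on a clock shifted by t_onset_la) ------
    ("E_max_la", 0.30, 0.12, 0.60, True, "mmHg/mL", "maximal LA elastance"),
    ("E_min_la", 0.15, 0.05, 0.28, True, "mmHg/mL", "passive LA elastance"),
    ("R_C_la", 1.9, 1.0, 4.0, True, "-", "LA contraction-rate exponent"),
    ("R_R_la", 13.0, 6.0, 25.0, True, "-", "LA relaxation-rate exponent"),
    ("alpha_S_la", 0.09, 0.04, 0.20, True, "-", "LA systolic time constant (fraction of T)"),
    ("alpha_D_la", 0.16, 0.08, 0.30, True, "-", "LA diastolic time constant (fraction of T)"),
    ("t_max_la", 0.13, 0.05, 0.25, True, "s", "LA end-systole on the shifted clock"),
    # --- aortic valve ---------------------------------------------------
    ("EOA", 3.0, 1.5, 5.0, True, "cm^2", "aortic-valve effective orifice area"),
    ("A_LVOT", 4.5, 2.5, 7.0, True, "cm^2", "LV outflow-tract area"),
    # --- aorta and systemic circulation --------------------------------
    ("C_aa", 0.30, 0.05, 1.0, True, "mL/mmHg", "ascending-aorta compliance"),
    ("R_ao", 0.03, 0.005, 0.15, True, "mmHg*s/mL", "ascending-aorta/arch resistance"),
    ("L_ao", 5e-4, 1e-4, 5e-3, True, "mmHg*s^2/mL", "ascending-aorta/arch inertance"),
    ("C_art", 1.2, 0.3, 3.0, True, "mL/mmHg", "peripheral Windkessel compliance"),
    ("R_p", 0.9, 0.4, 2.0, True, "mmHg*s/mL", "peripheral Windkessel resistance"),
    ("R_mv", 0.004, 0.001, 0.02, True, "mmHg*s/mL", "mitral-valve resistance"),
    ("L_mv", 2e-4, 5e-5, 2e-3, True, "mmHg*s^2/mL", "mitral-valve inertance"),
    # --- fixed population-level parameters -----------------------------
    ("T", 1.0, 0.4, 2.0, False, "s", "cardiac cycle length (set from measurement)"),
    ("rho", 1.06, 1.0, 1.12, False, "g/mL", "blood density"),
    ("B_av", 0.0017, 2e-4, 0.02, False, "mmHg*s^2/mL", "aortic-valve inertial coefficient"),
    ("V0_lv", 10.0, 2.0, 25.0, False, "mL", "LV unstressed volume (fixed; also used in the E_max derivation)"),
    ("V0_la", 10.0, 2.0, 30.0, False, "mL", "LA unstressed volume"),
    ("V0_aa", 50.0, 10.0, 120.0, False, "mL", "ascending-aorta unstressed volume"),
    ("V0_dsc", 150.0, 50.0, 300.0, False, "mL", "arch/descending-aorta unstressed volume"),
    ("V0_art", 600.0, 200.0, 1200.0, False, "mL", "peripheral arterial unstressed volume"),
    ("V0_ven", 2500.0, 1000.0, 4000.0, False, "mL", "venous/pulmonary reservoir unstressed volume"),
    ("C_dsc", 0.6, 0.1, 2.0, False, "mL/mmHg", "arch/descending-aorta compliance"),
    ("R_dsc", 0.05, 0.01, 0.3, False, "mmHg*s/mL", "arch/descending-aorta resistance"),
    ("C_ven", 30.0, 10.0, 100.0, False, "mL/mmHg", "venous/pulmonary reservoir compliance"),
    ("R_pv", 0.03, 0.005, 0.15, False, "mmHg*s/mL", "pulmonary-venous return resistance"),
    ("R_leak", 1000.0, 100.0, 1e4, False, "mmHg*s/mL", "closed-valve reverse-blocking resistance"),
    ("P_ven0", 10.0, 4.0, 20.0, False, "mmHg", "initial reservoir (pulmonary-venous) pressure"),
    ("P_art0", 80.0, 40.0, 120.0, False, "mmHg", "initial arterial pressure"),
    ("t_onset_la", 0.80, 0.5, 0.95, False, "s", "onset of atrial activation (fraction-of-default-T clock shift)"),
]

PARAM_SPECS: dict[str, ParamSpec] = {
    name: ParamSpec(name, default, lo, hi, free, unit, doc)
    for name, default, lo, hi, free, unit, doc in _SPECS
}

PARAM_NAMES: tuple[str, ...] = tuple(PARAM_SPECS)
FREE_NAMES: tuple[str, ...] = tuple(s.name for s in PARAM_SPECS.values() if s.free)
FIXED_NAMES: tuple[str, ...] = tuple(s.name for s in PARAM_SPECS.values() if not s.free)

assert len(PARAM_NAMES) == 40
assert len(FREE_NAMES) == 23
assert len(FIXED_NAMES) == 17

#: parameters anchored to derived measurements, free within +/-10 %
MEASUREMENT_ANCHORED: tuple[str, ...] = ("EOA", "A_LVOT", "E_max_lv")

#: the seven headline subject-specific parameters the variability study tracks
HEADLINE_PARAMS: tuple[str, ...] = (
    "E_min_lv", "E_max_lv", "R_C_lv", "R_R_lv", "alpha_S_lv", "alpha_D_lv", "C_aa",
)


@dataclass(frozen=True)
class ModelParameters(Mapping):
    """Immutable named collection of all 40 scalar model parameters.

    Behaves as a read-only mapping ``name -> value``; per-parameter
    free/fixed flags and bounds live in :attr:`specs`.  Bounds may be
    overridden per instance (e.g. the +/-10 % windows around derived
    measurement values).
    """

    values: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(PARAM_SPECS)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        merged = {name: spec.default for name, spec in PARAM_SPECS.items()}
        merged.update(self.values)
        object.__setattr__(self, "values", merged)
        b = {name: (spec.lower, spec.upper) for name, spec in PARAM_SPECS.items()}
        b.update(self.bounds)
        object.__setattr__(self, "bounds", b)
        self.validate()

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        self.lv_elastance.validate(v["T"])
        self.la_elastance.validate(v["T"])
        _ = self.valve  # runs ValveParams invariants
        for name in PARAM_NAMES:
            spec = PARAM_SPECS[name]
            if ("R_" in name or name.startswith(("C_", "L_", "B_"))) and v[name] <= 0:
                raise ValueError(f"{name} must be > 0, got {v[name]}")
            lo, hi = self.bounds[name]
            if not lo <= hi:
                raise ValueError(f"bounds for {name} inverted: ({lo}, {hi})")
            del spec

    @property
    def lv_elastance(self) -> ElastanceParams:
        v = self.values
        return ElastanceParams(
            v["E_max_lv"], v["E_min_lv"], v["R_C_lv"], v["R_R_lv"],
            v["alpha_S_lv"], v["alpha_D_lv"], v["t_max_lv"], v["V0_lv"],
        )

    @property
    def la_elastance(self) -> ElastanceParams:
        v = self.values
        return ElastanceParams(
            v["E_max_la"], v["E_min_la"], v["R_C_la"], v["R_R_la"],
            v["alpha_S_la"], v["alpha_D_la"], v["t_max_la"], v["V0_la"],
        )

    @property
    def valve(self) -> ValveParams:
        v = self.values
        return ValveParams(v["EOA"], v["A_LVOT"], v["rho"])

    @property
    def free_names(self) -> tuple[str, ...]:
        return FREE_NAMES

    def with_values(self, **updates: float) -> "ModelParameters":
        vals = dict(self.values)
        vals.update(updates)
        return ModelParameters(values=vals, bounds=dict(self.bounds))

    def with_bounds(self, **updates: tuple[float, float]) -> "ModelParameters":
        b = dict(self.bounds)
        b.update(updates)
        return ModelParameters(values=dict(self.values), bounds=b)

    # serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            name: {
                "value": self.values[name],
                "free": PARAM_SPECS[name].free,
                "lower": self.bounds[name][0],
                "upper": self.bounds[name][1],
            }
            for name in PARAM_NAMES
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParameters":
        values = {k: float(v["value"]) for k, v in d.items()}
        bounds = {k: (float(v["lower"]), float(v["upper"])) for k, v in d.items()}
        return cls(values=values, bounds=bounds)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def default_parameters(**overrides: float) -> ModelParameters:
    """The documented healthy-adult default parameter set."""
    return ModelParameters(values=dict(overrides))


def derive_elco(EOA: float, A_LVOT: float) -> float:
    """Energy-loss coefficient ELCo = EOA*A_LVOT/(A_LVOT - EOA), cm^2."""
    if not (0 < EOA < A_LVOT) or not (math.isfinite(EOA) and math.isfinite(A_LVOT)):
        raise ValueError(
            f"valve area exceeds outflow tract (need 0 < EOA < A_LVOT): "
            f"EOA={EOA}, A_LVOT={A_LVOT}"
        )
    return EOA * A_LVOT / (A_LVOT - EOA)


__all__ = [
    "ElastanceParams", "ValveParams", "ParamSpec", "ModelParameters",
    "PARAM_SPECS", "PARAM_NAMES", "FREE_NAMES", "FIXED_NAMES",
    "MEASUREMENT_ANCHORED", "HEADLINE_PARAMS",
    "default_parameters", "derive_elco", "replace",
]
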