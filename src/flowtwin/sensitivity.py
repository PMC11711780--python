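"""One-at-a-time sensitivity of model outputs to the measured inputs.

Perturbs EOA, A_LVOT, or the directly estimated maximal LV elastance over a
symmetric fractional grid (default +/-10 % in 2.5 % steps, mirroring the
optimization window) and quantifies the effect on the mitral and
aortic-valve flows and the aortic pressure, both as waveform RMSE against
baseline and as relative changes of scalar summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import SimulationError, simulate
from .parameters import ModelParameters

SWEEPABLE = {"EOA": "EOA", "A_LVOT": "A_LVOT", "Emax_LV": "E_max_lv"}

#: traces compared by RMSE and the scalar summaries reported
_TRACE_OUTPUTS = ("q_mv", "q_av", "p_ao")
_SCALAR_OUTPUTS = ("peak_q_mv", "peak_q_av", "sbp", "dbp")

DEFAULT_GRID = np.round(np.arange(-0.10, 0.101, 0.025), 10)


def _scalars(sim) -> dict:
    return {
        "peak_q_mv": float(np.max(sim.q_mv)),
        "peak_q_av": float(np.max(sim.q_av)),
        "sbp": sim.sbp,
        "dbp": sim.dbp,
    }


@dataclass
class SensitivityResult:
    """Long-format effect table for one swept input."""

    input_name: str
    grid: np.ndarray
    table: pd.DataFrame  # columns: input, perturbation, output, effect
    failed: list         # grid points whose simulation did not complete

    def effect(self, output: str, agg=np.max) -> float:
        """Aggregate effect magnitude of this input on one output."""
        sub = self.table[self.table["output"] == output]
        return float(agg(np.abs(sub["effect"].to_numpy())))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sweep_input(
    baseline: ModelParameters,
    input_name: str,
    grid=DEFAULT_GRID,
    **sim_kwargs,
) -> SensitivityResult:
    """Re-simulate with one input scaled by (1 + delta) for each grid delta.

    The energy-loss coefficient is recomputed implicitly whenever EOA or
    A_LVOT changes.  RMSE effects are in the trace's own units (mL/s or
    mmHg); scalar effects are relative changes.  Non-convergent grid
    points are flagged and skipped rather than aborting the sweep.
    """
    if input_name not in SWEEPABLE:
        raise ValueError(f"input must be one of {sorted(SWEEPABLE)}, got {input_name!r}")
    pname = SWEEPABLE[input_name]
    grid = np.asarray(grid, dtype=float)

    base_sim = simulate(baseline, **sim_kwargs)
    base_traces = {k: getattr(base_sim, k) for k in _TRACE_OUTPUTS}
    base_scalars = _scalars(base_sim)

    rows, failed = [], []
    for delta in grid:
        if delta == 0.0:
            sim = base_sim  # identity perturbation: exactly zero effect
        else:
            value = baseline[pname] * (1.0 + delta)
            try:
                p = baseline.with_values(**{pname: value})
                sim = simulate(p, y0=base_sim.final_state, **sim_kwargs)
            except (SimulationError, ValueError) as exc:
                failed.append((float(delta), str(exc)))
                continue
        for k in _TRACE_OUTPUTS:
            rmse = float(np.sqrt(np.mean((getattr(sim, k) - base_traces[k]) ** 2)))
            rows.append({"input": input_name, "perturbation": float(delta),
                         "output": f"rmse_{k}", "effect": rmse})
        s = _scalars(sim)
        for k in _SCALAR_OUTPUTS:
            rows.append({"input": input_name, "perturbation": float(delta),
                         "output": k, "effect": s[k] / base_scalars[k] - 1.0})
    return SensitivityResult(
        input_name=input_name, grid=grid, table=pd.DataFrame(rows), failed=failed)


def sweep_all(baseline: ModelParameters, grid=DEFAULT_GRID, **sim_kwargs) -> dict:
    """Sweep every supported input; returns name -> SensitivityResult."""
    return {name: sweep_input(baseline, name, grid, **sim_kwargs)
            for name in SWEEPABLE}


__all__ = ["SensitivityResult", "sweep_input", "sweep_all", "SWEEPABLE",
           "DEFAULT_GRID"]
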