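"""Personalization of the 23 subject-specific parameters.

Bound-constrained nonlinear least squares against the three measured flow
waveforms and the cuff pressures.  Residuals live on the measurement grid
(periodic linear interpolation of the simulated cycle), each site
normalized by its peak measured flow, so the cost is invariant to solver
step control and grid refinement.  Cuff pressures enter as two extra
residuals — without them the pressure scale (and hence C_aa and the
resistances) would only be identifiable up to a gauge.  The measured
end-systolic volume enters as one further scalar residual: flow waveforms
determine chamber volumes only up to an offset, so without ESV the
elastance scale (E_max, E_min) is left nearly free along a compensation
valley; anchoring the one measured volume closes that gauge too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .derivation import MeasurementBundle, SITES, assemble_parameters
from .model import SimulationError, simulate
from .parameters import FREE_NAMES, ModelParameters

log = logging.getLogger(__name__)

#: residual value substituted when the forward model fails (optimizer-safe
#: finite stand-in for an infinite cost)
_FAILED_RESIDUAL = 1e3


@dataclass
class CostBreakdown:
    """Decomposition of the waveform-matching cost."""

    flow_rss: dict          # site -> residual sum of squares, mL^2/s^2
    flow_norm: dict         # site -> normalized mean-square component (dimensionless)
    sbp_residual: float     # max simulated aortic pressure - SBP, mmHg
    dbp_residual: float     # min simulated aortic pressure - DBP, mmHg
    esv_residual: float     # simulated minus measured end-systolic volume, mL
    weights: dict           # per-term weights used
    total: float            # weighted sum of normalized components

    @classmethod
    def from_components(cls, flow_rss, flow_norm, sbp_res, dbp_res, esv_res,
                        weights, sbp, esv):
        total = sum(weights[s] * flow_norm[s] for s in flow_norm)
        total += weights["pressure"] * ((sbp_res / sbp) ** 2 + (dbp_res / sbp) ** 2)
        total += weights["esv"] * (esv_res / esv) ** 2
        return cls(flow_rss, flow_norm, sbp_res, dbp_res, esv_res,
                   dict(weights), float(total))


def default_weights(bundle: MeasurementBundle) -> dict:
    """Equal flow-site weights; pressure weighted so a 1-mmHg error counts
    like a 1 % peak-flow error."""
    w = {site: 1.0 for site in SITES}
    w["pressure"] = (bundle.SBP / 100.0) ** 2
    w["esv"] = 1.0  # a 1 % ESV error counts like a 1 % peak-flow error
    return w


def _residual_vector(sim, bundle: MeasurementBundle, weights: dict):
    parts = []
    flow_rss, flow_norm = {}, {}
    sim_q = {"mitral_valve": sim.q_mv, "aortic_valve": sim.q_av,
             "ascending_aorta": sim.q_aa}
    for site in SITES:
        w = bundle.waveforms[site]
        q_hat = np.interp(w.time, sim.time, sim_q[site], period=sim.T)
        diff = q_hat - w.flow
        peak = w.peak
        n = len(diff)
        flow_rss[site] = float(np.sum(diff**2))
        flow_norm[site] = float(np.mean((diff / peak) ** 2))
        parts.append(np.sqrt(weights[site] / n) * diff / peak)
    sbp_res = sim.sbp - bundle.SBP
    dbp_res = sim.dbp - bundle.DBP
    esv_res = sim.esv - bundle.ESV
    wp = np.sqrt(weights["pressure"])
    we = np.sqrt(weights["esv"])
    parts.append(np.array([wp * sbp_res / bundle.SBP, wp * dbp_res / bundle.SBP,
                           we * esv_res / bundle.ESV]))
    breakdown = CostBreakdown.from_components(
        flow_rss, flow_norm, sbp_res, dbp_res, esv_res, weights,
        bundle.SBP, bundle.ESV)
    return np.concatenate(parts), breakdown


def cost(
    params: ModelParameters,
    bundle: MeasurementBundle,
    weights: dict | None = None,
    y0: np.ndarray | None = None,
    **sim_kwargs,
) -> CostBreakdown:
    """Evaluate the waveform-matching cost of ``params`` against ``bundle``.

    On simulation failure returns a breakdown with ``total = inf`` so that
    optimizers treat the point as infeasible rather than crashing.
    """
    if weights is None:
        weights = default_weights(bundle)
    missing = [s for s in SITES if s not in bundle.waveforms]
    if missing:
        raise ValueError(f"bundle lacks waveform(s) for {missing}")
    try:
        sim = simulate(params, y0=y0, **sim_kwargs)
    except SimulationError as exc:
        log.warning("simulation failed during cost evaluation: %s", exc)
        return CostBreakdown({}, {}, np.nan, np.nan, np.nan, dict(weights),
                             float("inf"))
    _, breakdown = _residual_vector(sim, bundle, weights)
    return breakdown


@dataclass
class EstimationResult:
    """Outcome of one personalization run."""

    params: ModelParameters
    breakdown: CostBreakdown
    converged: bool
    n_iterations: int
    n_starts: int
    start_costs: list = field(default_factory=list)
    at_bounds: tuple = ()
    seed: int | None = None

    @property
    def total_cost(self) -> float:
        return self.breakdown.total


class EstimationError(RuntimeError):
    pass


def estimate(
    bundle: MeasurementBundle,
    defaults: ModelParameters | None = None,
    seed: int = 0,
    n_starts: int = 20,
    weights: dict | None = None,
    max_nfev: int = 60,
    diff_step: float = 1e-4,
    xtol: float = 1e-12,
    ftol: float = 1e-12,
    periodicity_tol: float = 3e-4,
    n_cycles_max: int = 40,
    max_restarts: int = 4,
) -> EstimationResult:
    """Personalize the subject-specific parameters for one occasion.

    Multi-start bound-constrained least squares: the first start is the
    assembled measurement-anchored set, the remaining ``n_starts - 1``
    come from a Latin-hypercube draw within the bounds (deterministic
    under ``seed``).  T is copied from the bundle and never optimized.
    Forward simulations are warm-started from the best previous periodic
    state, which keeps each cost evaluation at a few cycles.

    The cost surface has long curved valleys (elastance shape parameters
    compensate each other almost exactly), along which a single
    trust-region run stalls; each start is therefore re-launched from its
    own solution until the cost stops improving by at least 30 %
    (``max_restarts`` caps the loop).
    """
    assembled = assemble_parameters(bundle, defaults)
    if weights is None:
        weights = default_weights(bundle)

    names = list(FREE_NAMES)
    lower = np.array([assembled.bounds[n][0] for n in names])
    upper = np.array([assembled.bounds[n][1] for n in names])
    x_assembled = np.array([assembled[n] for n in names])
    x_assembled = np.clip(x_assembled, lower, upper)

    sim_kwargs = dict(periodicity_tol=periodicity_tol, n_cycles_max=n_cycles_max)
    warm: dict = {"y0": None}
    n_fail = {"count": 0}

    def make_params(x: np.ndarray) -> ModelParameters:
        return assembled.with_values(**dict(zip(names, x)))

    def fun(x: np.ndarray) -> np.ndarray:
        try:
            p = make_params(x)
            sim = simulate(p, y0=warm["y0"], **sim_kwargs)
        except (SimulationError, ValueError, FloatingPointError):
            n_fail["count"] += 1
            m = sum(len(bundle.waveforms[s].time) for s in SITES) + 3
            return np.full(m, _FAILED_RESIDUAL)
        warm["y0"] = sim.final_state
        r, _ = _residual_vector(sim, bundle, weights)
        return r

    starts = [x_assembled]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        unit = sampler.random(n_starts - 1)
        starts.extend(lower + unit * (upper - lower))

    best = None
    start_costs: list[float] = []
    total_nfev = 0
    for i, x0 in enumerate(starts):
        warm["y0"] = None
        x, res, prev_cost = x0, None, np.inf
        try:
            for restart in range(max_restarts):
                res = least_squares(
                    fun, x, bounds=(lower, upper), method="trf",
                    diff_step=diff_step, xtol=xtol, ftol=ftol, gtol=1e-12,
                    max_nfev=max_nfev, x_scale="jac",
                )
                total_nfev += res.nfev
                c = 2.0 * res.cost  # least_squares cost = 0.5 * sum r^2
                log.debug("start %d restart %d: cost %.6g (nfev %d)",
                          i, restart, c, res.nfev)
                x = res.x
                if c > 0.7 * prev_cost:
                    break
                prev_cost = c
        except Exception as exc:  # optimizer-internal failure on this start
            log.warning("start %d failed: %s", i, exc)
            start_costs.append(float("inf"))
            continue
        c = 2.0 * res.cost
        start_costs.append(float(c))
        log.info("start %d/%d: cost %.6g", i + 1, len(starts), c)
        if np.any(res.fun >= _FAILED_RESIDUAL):
            continue
        if best is None or c < best[0]:
            best = (float(c), res)

    if best is None:
        raise EstimationError(
            f"all {len(starts)} optimization starts failed "
            f"({n_fail['count']} simulation failures)"
        )

    _, res = best
    fitted = make_params(res.x)
    warm["y0"] = None
    final_breakdown = cost(fitted, bundle, weights, **sim_kwargs)
    span = upper - lower
    at_bounds = tuple(
        names[j] for j in range(len(names))
        if min(res.x[j] - lower[j], upper[j] - res.x[j]) < 1e-6 * max(span[j], 1e-12)
    )
    return EstimationResult(
        params=fitted,
        breakdown=final_breakdown,
        converged=bool(res.status > 0),
        n_iterations=total_nfev,
        n_starts=len(starts),
        start_costs=start_costs,
        at_bounds=at_bounds,
        seed=seed,
    )


__all__ = [
    "CostBreakdown", "EstimationResult", "EstimationError",
    "cost", "estimate", "default_weights",
]
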