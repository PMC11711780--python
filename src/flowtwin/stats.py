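"""Repeatability statistics over paired analysis occasions.

Implements the study-level statistical toolkit: Bland-Altman bias and
limits of agreement, the repeatability coefficient of variation (root-mean-
square within-subject SD over the grand mean), two-sided Wilcoxon rank-sum
comparison of the two occasions, per-site waveform RMSE on a common
cycle-fraction grid, and net flow volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .derivation import FlowWaveform, SITES
from .parameters import HEADLINE_PARAMS
from .units import P_SIGNIFICANT


@dataclass(frozen=True)
class PairedSeries:
    """Per-subject value pairs of one quantity across two occasions."""

    name: str
    units: str
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired series need matching 1-D arrays")
        if len(a) < 2:
            raise ValueError(f"need >= 2 complete pairs, got {len(a)}")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired series contain non-finite values")


def bland_altman(pairs: PairedSeries) -> tuple[float, tuple[float, float]]:
    """Bias (mean difference a - b) and 1.96-SD limits of agreement.

    SD is the sample standard deviation (n - 1 denominator).
    """
    d = pairs.a - pairs.b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def cov_repeatability(pairs: PairedSeries) -> float:
    """Repeatability CoV in percent.

    Within-subject variance for a pair is d_i^2 / 2; the CoV is the RMS
    within-subject SD over the grand mean of all values.
    """
    grand_mean = float(np.mean(np.concatenate([pairs.a, pairs.b])))
    if grand_mean <= 0:
        raise ValueError(f"grand mean must be > 0 for a CoV, got {grand_mean}")
    d = pairs.a - pairs.b
    rms_sd = float(np.sqrt(np.mean(d**2 / 2.0)))
    return 100.0 * rms_sd / grand_mean


def cov_pairwise(pairs: PairedSeries) -> float:
    """Alternative CoV: SD of the paired differences over the grand mean
    (in percent); available for sensitivity to the CoV definition."""
    grand_mean = float(np.mean(np.concatenate([pairs.a, pairs.b])))
    if grand_mean <= 0:
        raise ValueError(f"grand mean must be > 0 for a CoV, got {grand_mean}")
    return 100.0 * float(np.std(pairs.a - pairs.b, ddof=1)) / grand_mean


def rank_test(pairs: PairedSeries) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing occasion A against B.

    Exact enumeration for combined n <= 20 without ties; normal
    approximation with tie correction otherwise.  Fully degenerate data
    (every value identical) returns p = 1.
    """
    a, b = pairs.a, pairs.b
    if np.all(a == a[0]) and np.all(b == a[0]):
        return 1.0
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def net_flow(w: FlowWaveform) -> float:
    """Net volume per cycle, mL (trapezoidal integral, closing the period)."""
    t = np.concatenate([w.time, [w.time[0] + w.T]])
    q = np.concatenate([w.flow, [w.flow[0]]])
    return float(np.trapezoid(q, t))


def waveform_rmse(a: FlowWaveform, b: FlowWaveform) -> float:
    """RMSE between two same-site waveforms, mL/s.

    Time is normalized to cycle fraction (handles unequal cycle lengths,
    e.g. between acquisition sequences) and both waveforms are resampled
    by periodic linear interpolation onto a common uniform grid with
    ``max(len(a), len(b))`` points.
    """
    if a.site != b.site:
        raise ValueError(f"site mismatch: {a.site} vs {b.site}")
    n = max(len(a.time), len(b.time))
    frac = np.linspace(0.0, 1.0, n, endpoint=False)
    qa = np.interp(frac, a.time / a.T, a.flow, period=1.0)
    qb = np.interp(frac, b.time / b.T, b.flow, period=1.0)
    return float(np.sqrt(np.mean((qa - qb) ** 2)))


# ---------------------------------------------------------------------------
# study-level report
# ---------------------------------------------------------------------------

_INPUT_SCALARS = (
    ("A_LVOT", "cm^2"), ("ESV", "mL"), ("EOA", "cm^2"), ("T", "s"),
)
_PARAM_UNITS = {
    "E_min_lv": "mmHg/mL", "E_max_lv": "mmHg/mL", "R_C_lv": "-", "R_R_lv": "-",
    "alpha_S_lv": "-", "alpha_D_lv": "-", "C_aa": "mL/mmHg",
}


def summarize_pairs(pairs: PairedSeries) -> dict:
    bias, (lo, hi) = bland_altman(pairs)
    return {
        "quantity": pairs.name,
        "units": pairs.units,
        "bias": bias,
        "loa_low": lo,
        "loa_high": hi,
        "p_value": rank_test(pairs),
        "cov_percent": cov_repeatability(pairs),
    }


@dataclass
class VariabilityReport:
    """Per-quantity agreement table plus waveform RMSE summaries."""

    comparison: str
    table: pd.DataFrame          # one row per quantity
    rmse: pd.DataFrame           # per-site, per-subject waveform RMSE, mL/s

    @property
    def significant(self) -> pd.Series:
        return self.table["p_value"] < P_SIGNIFICANT

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_variability_study(
    cohort,
    comparison: str,
    estimates: dict | None = None,
) -> VariabilityReport:
    """Agreement statistics for one paired comparison of a cohort.

    ``estimates`` maps occasion tag -> list of fitted ModelParameters (one
    per subject, cohort order).  When given, the seven headline model
    parameters are included alongside the input measures; otherwise the
    report covers the input scalars and net flows only.
    """
    if comparison not in {"intra", "inter", "sequence"}:
        raise ValueError(f"unknown comparison {comparison!r}")
    from .synthetic import COMPARISONS  # local import to avoid a cycle

    occ_a, occ_b = COMPARISONS[comparison]
    for occ in (occ_a, occ_b):
        if any(occ not in s.bundles for s in cohort.subjects):
            raise ValueError(f"cohort is missing occasion {occ!r}")

    bundles_a = [s.bundles[occ_a] for s in cohort.subjects]
    bundles_b = [s.bundles[occ_b] for s in cohort.subjects]

    rows = []
    for name, unit in _INPUT_SCALARS:
        a = np.array([getattr(x, name) for x in bundles_a])
        b = np.array([getattr(x, name) for x in bundles_b])
        rows.append(summarize_pairs(PairedSeries(name, unit, a, b)))
    for site in SITES:
        a = np.array([net_flow(x.waveforms[site]) for x in bundles_a])
        b = np.array([net_flow(x.waveforms[site]) for x in bundles_b])
        rows.append(summarize_pairs(PairedSeries(f"net_flow_{site}", "mL", a, b)))

    if estimates is not None:
        fits_a, fits_b = estimates[occ_a], estimates[occ_b]
        if len(fits_a) != len(bundles_a) or len(fits_b) != len(bundles_b):
            raise ValueError("estimates must hold one fit per subject and occasion")
        for name in HEADLINE_PARAMS:
            a = np.array([p[name] for p in fits_a])
            b = np.array([p[name] for p in fits_b])
            rows.append(summarize_pairs(
                PairedSeries(name, _PARAM_UNITS[name], a, b)))

    rmse_rows = [
        {"subject": s.subject_id, "site": site,
         "rmse_mL_s": waveform_rmse(s.bundles[occ_a].waveforms[site],
                                    s.bundles[occ_b].waveforms[site])}
        for s in cohort.subjects for site in SITES
    ]
    return VariabilityReport(
        comparison=comparison,
        table=pd.DataFrame(rows),
        rmse=pd.DataFrame(rmse_rows),
    )


__all__ = [
    "PairedSeries", "VariabilityReport",
    "bland_altman", "cov_repeatability", "cov_pairwise", "rank_test",
    "net_flow", "waveform_rmse", "summarize_pairs", "run_variability_study",
]
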