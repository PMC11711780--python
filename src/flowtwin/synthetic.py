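"""Synthetic measurement bundles with the study's variability structure.

Each subject is a ground-truth parameter set of the circulation model; an
"occasion" is one observer analysis (or one acquisition sequence) of that
subject, produced by perturbing the true scalars and waveforms with noise
calibrated to the published repeatability of the input measures:

* scalar coefficients of variation (intra / inter / sequence):
  A_LVOT 2.8 / 12 / 12 %, ESV 3 / 3.8 / — %, EOA 1.5 / 8.6 / 8.6 %
* net-flow CoVs per site: mitral 4.1 / 9.1 / 13 %, aortic valve
  1.2 / 2.7 / 9.1 %, ascending aorta 1.8 / 3.4 / 4.2 %
* heart-rate CoV between sequences 3.7 %; sampling interval 40 ms
  (SGRE-like) vs 30 ms (EPI-like)

Scalars receive multiplicative Gaussian noise truncated at +/-3 SD.
Waveforms receive a multiplicative net-flow factor plus smooth additive
shape noise (moving-average-filtered white noise, default 60 ms correlation
time) whose cycle mean is removed, so net volumes carry only the calibrated
multiplicative variability.  For inter-sequence occasions the cycle length
is rescaled and the true model re-simulated before observation, emulating
physiological heart-rate change between scans; the ESV perturbation is
omitted there because the end-systolic segmentation is shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .derivation import FlowWaveform, MeasurementBundle, SITES, VelocityTrace
from .model import SimulationError, SimulationResult, intrinsic_peak_time, simulate
from .parameters import FREE_NAMES, ModelParameters


@dataclass(frozen=True)
class NoiseModel:
    """Perturbation settings for one analysis occasion."""

    cov_a_lvot: float = 0.0        # fractional CoV of A_LVOT
    cov_esv: float = 0.0           # fractional CoV of ESV
    cov_eoa: float = 0.0           # fractional CoV of EOA
    cov_net_flow: dict = field(default_factory=dict)  # site -> fractional CoV
    shape_noise_amp: float = 0.0   # additive waveform noise, fraction of peak
    shape_corr_time: float = 0.06  # correlation time of shape noise, s
    cov_hr: float = 0.0            # fractional CoV of cycle length
    dt: float = 0.04               # resampling interval, s

    def __post_init__(self) -> None:
        for name in ("cov_a_lvot", "cov_esv", "cov_eoa", "cov_hr",
                     "shape_noise_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.cov_net_flow.values()):
            raise ValueError("net-flow CoVs must be >= 0")
        if self.shape_corr_time <= 0 or self.dt <= 0:
            raise ValueError("correlation time and resampling interval must be > 0")


#: published repeatability of the input measures, used as calibration
INTRA_NOISE = NoiseModel(
    cov_a_lvot=0.028, cov_esv=0.030, cov_eoa=0.015,
    cov_net_flow={"mitral_valve": 0.041, "aortic_valve": 0.012,
                  "ascending_aorta": 0.018},
    shape_noise_amp=0.02, dt=0.04,
)
INTER_NOISE = NoiseModel(
    cov_a_lvot=0.12, cov_esv=0.038, cov_eoa=0.086,
    cov_net_flow={"mitral_valve": 0.091, "aortic_valve": 0.027,
                  "ascending_aorta": 0.034},
    shape_noise_amp=0.035, dt=0.04,
)
SEQUENCE_NOISE_SGRE = NoiseModel(
    cov_a_lvot=0.12, cov_esv=0.0, cov_eoa=0.086,
    cov_net_flow={"mitral_valve": 0.13, "aortic_valve": 0.091,
                  "ascending_aorta": 0.042},
    shape_noise_amp=0.05, cov_hr=0.037, dt=0.04,
)
SEQUENCE_NOISE_EPI = replace(SEQUENCE_NOISE_SGRE, dt=0.03)

ZERO_NOISE = NoiseModel()

#: occasion tag -> noise model of the default study design
DEFAULT_DESIGN: dict[str, NoiseModel] = {
    "observer1_a": INTRA_NOISE,
    "observer1_b": INTRA_NOISE,
    "observer2": INTER_NOISE,
    "sgre": SEQUENCE_NOISE_SGRE,
    "epi": SEQUENCE_NOISE_EPI,
}

#: paired comparison -> (occasion A, occasion B)
COMPARISONS: dict[str, tuple[str, str]] = {
    "intra": ("observer1_a", "observer1_b"),
    "inter": ("observer1_a", "observer2"),
    "sequence": ("sgre", "epi"),
}

#: uniform healthy ranges for the subject-specific parameters
HEALTHY_RANGES: dict[str, tuple[float, float]] = {
    "E_max_lv": (1.7, 2.4), "E_min_lv": (0.05, 0.08),
    "R_C_lv": (1.6, 2.3), "R_R_lv": (18.0, 26.0),
    "alpha_S_lv": (0.19, 0.26), "alpha_D_lv": (0.36, 0.45),
    "t_max_lv": (0.30, 0.38),
    "E_max_la": (0.25, 0.36), "E_min_la": (0.12, 0.19),
    "R_C_la": (1.6, 2.3), "R_R_la": (10.0, 16.0),
    "alpha_S_la": (0.07, 0.11), "alpha_D_la": (0.13, 0.20),
    "t_max_la": (0.10, 0.16),
    "EOA": (2.5, 3.6), "A_LVOT": (3.8, 5.2),
    "C_aa": (0.22, 0.40), "R_ao": (0.02, 0.045), "L_ao": (3e-4, 8e-4),
    "C_art": (0.9, 1.5), "R_p": (0.75, 1.1), "R_mv": (0.003, 0.006),
    "L_mv": (1.5e-4, 3e-4),
}


def truncated_normal(rng: np.random.Generator, size=None, clip: float = 3.0):
    """Standard normal draw truncated at +/-``clip`` SD (redraw, not clamp,
    would bias the variance; clamping at 3 SD changes it by < 1 %)."""
    z = rng.standard_normal(size)
    return np.clip(z, -clip, clip)


def rescale_cycle(params: ModelParameters, T_new: float) -> ModelParameters:
    """Change the cycle length, stretching the second-valued phase
    parameters proportionally (time constants are already fractions)."""
    s = T_new / params["T"]
    return params.with_values(
        T=T_new,
        t_max_lv=params["t_max_lv"] * s,
        t_max_la=params["t_max_la"] * s,
        t_onset_la=params["t_onset_la"] * s,
    )


def draw_subject(
    seed: int | np.random.SeedSequence,
    ranges: dict[str, tuple[float, float]] | None = None,
    max_attempts: int = 10,
    sim_kwargs: dict | None = None,
) -> ModelParameters:
    """Draw ground-truth subject parameters uniformly within healthy ranges.

    The end-systole times are snapped to the intrinsic activation peak of
    the drawn elastance shape so the normalized activation attains its
    maximum of one at ``t_max``.  Draws whose forward simulation fails to
    converge are rejected and redrawn (at most ``max_attempts`` times).
    """
    if ranges is None:
        ranges = HEALTHY_RANGES
    unknown = set(ranges) - set(FREE_NAMES)
    if unknown:
        raise KeyError(f"ranges given for non-subject-specific parameters: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for _ in range(max_attempts):
        values = {name: rng.uniform(lo, hi) for name, (lo, hi) in ranges.items()}
        try:
            params = ModelParameters(values=values)
            params = params.with_values(
                t_max_lv=intrinsic_peak_time(params.lv_elastance, params["T"]),
                t_max_la=intrinsic_peak_time(params.la_elastance, params["T"]),
            )
            sim = simulate(params, **(sim_kwargs or {}))
            if sim.converged:
                return params
            last_err = SimulationError("periodicity not reached")
        except (SimulationError, ValueError, FloatingPointError) as exc:
            last_err = exc
    raise SimulationError(
        f"no convergent subject in {max_attempts} draws from ranges {ranges}: {last_err}"
    )


def _smooth_noise(rng, n: int, corr_samples: float) -> np.ndarray:
    """Unit-variance, zero-cycle-mean smooth noise (circular moving average)."""
    white = rng.standard_normal(n)
    k = max(int(round(corr_samples)), 1)
    kernel = np.ones(k) / k
    # circular convolution keeps the trace periodic
    smooth = np.real(np.fft.ifft(np.fft.fft(white) * np.fft.fft(kernel, n)))
    smooth -= smooth.mean()
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def perturb_scalars(
    truth: dict[str, float], noise: NoiseModel, rng: np.random.Generator,
    max_attempts: int = 10,
) -> dict[str, float]:
    """Multiplicative truncated-Gaussian perturbation of the scalar inputs.

    ``truth`` must contain A_LVOT, ESV, EOA (mL/cm^2).  Redraws EOA/A_LVOT
    jointly if a draw violates EOA < A_LVOT.
    """
    esv = truth["ESV"] * (1.0 + noise.cov_esv * truncated_normal(rng))
    for _ in range(max_attempts):
        a_lvot = truth["A_LVOT"] * (1.0 + noise.cov_a_lvot * truncated_normal(rng))
        eoa = truth["EOA"] * (1.0 + noise.cov_eoa * truncated_normal(rng))
        if 0 < eoa < a_lvot and esv > 0:
            return {"ESV": float(esv), "A_LVOT": float(a_lvot), "EOA": float(eoa)}
    raise ValueError(
        f"could not draw valid scalars after {max_attempts} attempts "
        f"(EOA ~ {truth['EOA']}, A_LVOT ~ {truth['A_LVOT']})"
    )


def observe(
    truth: ModelParameters,
    noise: NoiseModel,
    seed: int | np.random.SeedSequence,
    subject_id: str = "s00",
    occasion: str = "observer1_a",
    truth_sim: SimulationResult | None = None,
    sim_kwargs: dict | None = None,
) -> MeasurementBundle:
    """Produce one observed MeasurementBundle from a ground-truth subject.

    If the noise model carries heart-rate variability, the cycle length is
    rescaled and the model re-simulated first (a physiological change, not
    a measurement error); otherwise a cached ``truth_sim`` is reused.
    """
    rng = np.random.default_rng(seed)
    params = truth
    if noise.cov_hr > 0:
        T_new = truth["T"] * (1.0 + noise.cov_hr * float(truncated_normal(rng)))
        params = rescale_cycle(truth, T_new)
        sim = simulate(params, **(sim_kwargs or {}))
    else:
        sim = (truth_sim if truth_sim is not None
               else simulate(truth, **(sim_kwargs or {})))
    T = params["T"]

    scalars = perturb_scalars(
        {"ESV": sim.esv, "A_LVOT": params["A_LVOT"], "EOA": params["EOA"]},
        noise, rng)

    times = np.arange(0.0, T - 1e-9, noise.dt)
    sim_q = {"mitral_valve": sim.q_mv, "aortic_valve": sim.q_av,
             "ascending_aorta": sim.q_aa}
    waveforms = {}
    for site in SITES:
        q = np.interp(times, sim.time, sim_q[site], period=T)
        factor = 1.0 + noise.cov_net_flow.get(site, 0.0) * float(truncated_normal(rng))
        q = q * factor
        if noise.shape_noise_amp > 0:
            corr_samples = noise.shape_corr_time / noise.dt
            q = q + (noise.shape_noise_amp * np.max(np.abs(q))
                     * _smooth_noise(rng, len(times), corr_samples))
        waveforms[site] = FlowWaveform(site=site, time=times, flow=q, T=T)

    # peak-velocity trace consistent with the observed flow and EOA
    velocity = VelocityTrace(
        time=times, velocity=waveforms["aortic_valve"].flow / scalars["EOA"])

    return MeasurementBundle(
        subject_id=subject_id, occasion=occasion, T=T,
        ESV=scalars["ESV"], EOA=scalars["EOA"], A_LVOT=scalars["A_LVOT"],
        SBP=sim.sbp, DBP=sim.dbp,
        waveforms=waveforms, velocity=velocity,
    )


@dataclass
class SyntheticSubject:
    subject_id: str
    truth: ModelParameters
    bundles: dict  # occasion -> MeasurementBundle
    truth_sim: SimulationResult | None = None


@dataclass
class SyntheticCohort:
    """A reproducible cohort of subjects with per-occasion bundles."""

    subjects: list
    seed: int
    design: dict  # occasion -> NoiseModel

    def occasion_pairs(self, comparison: str):
        a, b = COMPARISONS[comparison]
        return [(s.bundles[a], s.bundles[b]) for s in self.subjects]


def build_cohort(
    n_subjects: int = 10,
    design: dict[str, NoiseModel] | None = None,
    seed: int = 0,
    ranges: dict | None = None,
    sim_kwargs: dict | None = None,
) -> SyntheticCohort:
    """Generate the full study cohort (default: ten subjects, five
    occasions covering the intra/inter/sequence comparisons)."""
    if design is None:
        design = DEFAULT_DESIGN
    root = np.random.SeedSequence(seed)
    subjects = []
    for i, subj_seq in enumerate(root.spawn(n_subjects)):
        draw_seq, *occ_seqs = subj_seq.spawn(1 + len(design))
        truth = draw_subject(draw_seq, ranges=ranges, sim_kwargs=sim_kwargs)
        truth_sim = simulate(truth, **(sim_kwargs or {}))
        sid = f"s{i:02d}"
        bundles = {
            occ: observe(truth, nm, occ_seq, subject_id=sid, occasion=occ,
                         truth_sim=truth_sim, sim_kwargs=sim_kwargs)
            for (occ, nm), occ_seq in zip(design.items(), occ_seqs)
        }
        subjects.append(SyntheticSubject(sid, truth, bundles, truth_sim))
    return SyntheticCohort(subjects=subjects, seed=seed, design=dict(design))


__all__ = [
    "NoiseModel", "SyntheticSubject", "SyntheticCohort",
    "INTRA_NOISE", "INTER_NOISE", "SEQUENCE_NOISE_SGRE", "SEQUENCE_NOISE_EPI",
    "ZERO_NOISE", "DEFAULT_DESIGN", "COMPARISONS", "HEALTHY_RANGES",
    "draw_subject", "observe", "perturb_scalars", "build_cohort",
    "rescale_cycle", "truncated_normal",
]
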