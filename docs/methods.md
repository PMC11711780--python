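# Methods

## The circulation model

The model is a closed-loop, zero-dimensional description of the left heart
and systemic circulation with nine states: six compartment volumes (left
atrium, left ventricle, ascending aorta, arch/descending aorta, peripheral
arterial bed, venous/pulmonary reservoir) and three flows carried by
inertances (mitral, aortic-valve and ascending-aortic flow). Volume
derivatives are inflow minus outflow, so total blood volume is conserved
identically; the reservoir plays the role of a pulmonary-venous pressure
source but, being a (large, 30 mL/mmHg) compliance rather than a true
source, keeps the loop closed.

Chamber pressure is `P = E(t)(V − V0)` with a normalized double-Hill
activation: a rising Hill factor with exponent `R_C` and characteristic
time `α_S·T`, times a falling factor with exponent `R_R` and time `α_D·T`,
normalized to equal one at the end-systolic time `t_max`. This is the
standard form carrying exactly this parameter set (maximal and minimal
elastance, contraction and relaxation rates, systolic and diastolic time
constants, time of end-systole). Note that the normalization point is a
free parameter: if `t_max` is moved off the intrinsic argmax of the
underlying curve, the activation exceeds 1 elsewhere. Default parameter
sets and synthetic subjects therefore snap `t_max` to the intrinsic peak
(computed on a 20 001-point grid); the optimizer is free to move it.

The left atrium uses the same functional form on a shifted periodic clock
`t' = (t − t_onset) mod T` with onset at 0.80·T, so the atrial kick peaks
at ≈ 0.93·T, just before ventricular activation. The shifted clock is
periodic, so there is no discontinuity at the cycle wrap; the residual
activation at wrap is below 1e-9 for the default shapes.

### Aortic valve

The transvalvular gradient is the energy-loss form
`ΔP = ρ/(2·ELCo²)·Q|Q|·(0.06/133.322) + B·dQ/dt`, with
`ELCo = EOA·A_LVOT/(A_LVOT − EOA)` and ρ = 1.06 g/mL. The composite factor
0.06/133.322 converts the CGS dynamic-pressure value of the convective
term (flows in mL/s, areas in cm²) to mmHg and is applied verbatim; it is
centralized in `flowtwin.units`. The inertial coefficient defaults to
`B = 2π·ρ/√EOA` in the same unit system (≈ 1.7e-3 mmHg·s²/mL); the
convective part is unaffected by B and is what the direct E_max estimate
uses.

### Valves as smooth diodes

Both valves are flow states (inertance `L_mv` resp. `B_av`) whose driving
pressure difference is opposed by a reverse-blocking resistance
`R_leak·σ(−(Q + q0)/q_s)` with `R_leak = 1000 mmHg·s/mL`, `q0 = 1 mL/s`,
`q_s = 0.2 mL/s`. For forward flow the extra resistance is negligible
(< 7 mmHg·s/mL at Q = 0, decaying within ~1 mL/s); reverse flow is capped
near `|ΔP|/R_leak` plus the sigmoid ramp width, a documented leakage bound
of ε ≈ 1.5 mL/s against peak forward flows of several hundred. A
conductance gated on a narrow *pressure* window was considered and
rejected: gating out the reverse pressure removes the very force that
closes the valve (leaving only the tiny convective term to decelerate the
jet, with seconds-long closure), and a flow-sigmoid centred at zero
introduces a spurious ~R_leak·q_s/4 opening barrier. The chosen form keeps
the right-hand side smooth for the stiff integrator.

### Integration and periodic steady state

LSODA with rtol 1e-6 and atol 1e-8, integrated cycle by cycle from a fixed
cold-start state until the maximum relative change of the state between
cycle starts (scale `max(|y|, 1)`) falls below the periodicity tolerance
(default 1e-3, at most 30 cycles; both configurable). Every cycle is
sampled on 241 uniform points as it is integrated, and the cycle that
satisfies the periodicity check is the reported one.
Warm-starting from a previous periodic state cuts the transient to 1–3
cycles and is used heavily inside the optimizer and the sensitivity
sweeps. The cold-start volumes are built from *fixed* parameters only, so
the conserved total blood volume is a study constant that cannot drift
when subject-specific parameters are optimized. The right-hand side is
compiled with numba.

### Parameter set

All 40 parameters live in a single registry with per-parameter defaults,
bounds, units and a free/fixed flag: 23 subject-specific (EOA, A_LVOT,
E_max_lv anchored to measurements within ±10 %; 20 optimizer-tuned
including both elastance blocks, C_aa, aortic and peripheral Windkessel
elements and the mitral valve) and 17 fixed population constants (cycle
length T — copied from the measurement, never optimized — blood density,
unstressed volumes, the reservoir, the arch segment, diode and source
constants). Defaults describe a healthy adult at T = 1 s and were chosen
to give textbook resting hemodynamics (about 128/75 mmHg, stroke volume
87 mL, cardiac output 5.2 L/min, EDV/ESV 149/62 mL); all are overridable.
The LV unstressed volume V0_LV is fixed at 10 mL and the same value enters
the direct E_max estimate, keeping derivation and model consistent.

## Input derivation

`EOA = SV/VTI`: SV is the trapezoidal integral of the aortic-valve flow
over the cycle; VTI integrates the peak-velocity trace over the systolic
support, defined as flow above 1 % of its peak (the quadrature and the
support rule are our choices; the 1 % threshold keeps diastolic noise out
of the integral). `E_max = 0.9·(SBP + PG_max)/(ESV − V0_LV)` with
`PG_max = ρ/(2·ELCo²)·max(AV flow)²·(0.06/133.322)`. In this model the
estimate runs ~10 % high (the 0.9 factor and the ESV ≈ end-systolic-volume
approximation do not hold exactly here); the ±10 % optimization window
absorbs most of that bias, which is the role it plays in the
personalization design.

## Personalization

Bound-constrained least squares (scipy `least_squares`, TRF) over the 23
free parameters. Residuals: the three simulated flow waveforms resampled
onto the measurement grids by periodic linear interpolation, each
normalized by the site's peak measured flow and by √n (grid-refinement
invariant); plus three scalar residuals — (max simulated aortic pressure −
SBP)/SBP, (min − DBP)/SBP, and (simulated minus measured ESV)/ESV. Default
weights: flow sites equal; the pressure weight is (SBP/100)² so a 1-mmHg
error counts like a 1 % peak-flow error; the ESV weight 1 (1 % ≈ 1 %).
The pressure terms fix the pressure gauge without which C_aa and the
resistances are unidentifiable; the ESV term fixes the volume gauge:
flows determine chamber volumes only up to an offset, and without it the
fit can reproduce all waveforms and both cuff pressures with E_max, E_min
and α_S displaced ~10 % along a compensation valley while mispredicting
the measured ESV by several mL. All three anchors are measured inputs of
the bundle.

Multi-start: the first start is the assembled measurement-anchored set;
further starts (default `n_starts = 20`) come from a seeded Latin
hypercube within bounds. The cost surface is sloppy — long curved valleys
in the elastance shape parameters — and a single trust-region run stalls
partway along them, so each start is re-launched from its own solution
until the cost improves by less than 30 % (at most `max_restarts = 4`
launches), with finite-difference steps of 1e-4 relative and adaptive
(`x_scale='jac'`) scaling. Forward simulations warm-start from the
previous periodic state. Simulation failures return a large finite
residual so the optimizer backs off rather than crashing; parameters
ending at a bound are reported, not silently clipped.

Noise-free recovery experiments tighten the forward-model periodicity
tolerance to 1e-5 (and 1e-6 for the generating simulation): the default
1e-3 transient error acts as pseudo-noise comparable to the cost
curvature at the few-percent recovery scale being measured.

## Synthetic measurements

A subject is a uniform draw of the 23 subject-specific parameters within
healthy ranges (roughly ±15 % around defaults; simulation convergence is
required, with redraw on failure). An occasion applies a noise model with:

* multiplicative truncated-Gaussian (±3 SD) perturbations of A_LVOT, ESV
  and EOA at the repeatability CoVs reported for this measurement type —
  intra-observer 2.8 / 3.0 / 1.5 %, inter-observer 12 / 3.8 / 8.6 %,
  inter-sequence 12 / — / 8.6 % (ESV noise omitted there, as the
  end-systolic segmentation comes from the same morphological images);
* a per-site multiplicative net-flow factor (CoVs: mitral 4.1 / 9.1 / 13 %,
  aortic valve 1.2 / 2.7 / 9.1 %, ascending aorta 1.8 / 3.4 / 4.2 %) plus
  additive smooth shape noise — circular moving-average-filtered white
  noise with 60 ms correlation time, amplitude 2 / 3.5 / 5 % of peak — with
  the cycle mean removed, so net volumes carry exactly the calibrated
  multiplicative variability (the shape amplitude is the free knob that
  controls waveform RMSE without touching net-flow CoVs);
* resampling to the occasion's interval: 40 ms (SGRE-like) or 30 ms
  (EPI-like);
* for inter-sequence occasions, a heart-rate perturbation (CoV 3.7 %): the
  cycle length and the second-valued phase parameters are rescaled and the
  true model re-simulated before observation — a physiological change
  between scans, not a measurement error.

Because each of a pair's two occasions receives independent noise at CoV c,
the pairwise repeatability CoV (RMS within-subject SD over grand mean) is
also c, which is what the calibration-closure check verifies. One known
consequence: the inter-observer *pair* mixes an intra-level occasion
(observer 1) with an inter-level one (observer 2), so its pairwise CoV
lands between the two settings; only the ordering inter ≥ intra is treated
as a testable claim. Cuff pressures are shared between occasions (same
cuff measurement) and carry no observer noise. A peak-velocity trace
consistent with the observed flow and EOA is attached so the EOA
derivation closes on the bundle.

What the generator does **not** emulate: spatial image content and
segmentation mechanics, velocity-encoding artefacts, background phase
offsets, navigator-gating efficiency, beat-to-beat variability within one
acquisition, or non-Gaussian observer error. Passing tests therefore show
the pipeline's behaviour under calibrated, well-specified input noise —
not under every failure mode of real flow-MRI analysis.

## Variability statistics

Bland–Altman bias `mean(a−b)` with 1.96·SD limits of agreement (sample SD,
n−1). Repeatability CoV: within-pair variance `d²/2`, RMS over subjects,
divided by the grand mean, in percent; a pairwise alternative (SD of
differences over grand mean) is provided for sensitivity to the
definition. Wilcoxon rank-sum (unpaired, two-sided; exact for combined
n ≤ 20 without ties, normal approximation with tie correction otherwise;
fully degenerate data returns p = 1 with no significance claim), at the
conventional 0.05 threshold and with no multiple-testing correction, one
test per quantity. Waveform RMSE aligns cycles by normalizing time to
cycle fraction (needed when T differs between sequences) and resamples
both waveforms by periodic linear interpolation onto a uniform grid of
max(len(a), len(b)) points. Net flow closes the period with the first
sample before trapezoidal integration, so a constant 100 mL/s over a 1-s
cycle integrates to exactly 100 mL.

The study report covers the four input scalars, the three net flows, and
— when per-occasion personalization results are supplied — the seven
headline model parameters (E_min, E_max, R_C, R_R, α_S, α_D of the LV and
C_aa), one row each with bias, limits of agreement, p-value and CoV, plus
a per-site, per-subject waveform RMSE table.

## Sensitivity analysis

One-at-a-time sweeps of EOA, A_LVOT and E_max over ±10 % in 2.5 % steps
(the window the optimization itself grants those inputs), re-simulating
from the baseline periodic state; ELCo is recomputed implicitly when an
area changes. Effects are reported both as waveform RMSE of the mitral and
aortic-valve flows and aortic pressure against baseline (trace units) and
as relative changes of scalar summaries (peak flows, SBP, DBP). The zero
point reuses the baseline simulation, so the identity perturbation has
exactly zero effect; non-convergent grid points are flagged and skipped.
Sweeps used in ordering comparisons run at periodicity tolerance 1e-4,
because valve-area effects on a non-stenotic valve (gradients of a few
tenths of a mmHg) are otherwise comparable to the periodicity error.

## Numerical choices and degenerate inputs

* Diode constants (R_leak, q0, q_s) and the leak bound ε are documented
  above; ε is asserted in the tests.
* The activation rejects non-finite values (overflow of extreme Hill
  exponents) naming the offending exponent.
* `derive_eoa` rejects non-overlapping grids and non-positive VTI;
  `derive_elco` rejects EOA ≥ A_LVOT; `derive_emax_lv` rejects
  ESV ≤ V0_LV.
* Estimation with all starts failing raises, never returning a silent
  partial answer; the optimizer's failure sentinel is a finite 1e3 per
  residual.
* Problem sizes in the shipped tests and the acceptance script — 10
  ground-truth draws with single-start personalization, 20 cohort noise
  replicates, 1000 calibration pairs, a 9-point sensitivity grid — were
  chosen so the full suite completes in minutes on one core while keeping
  every sampling error well inside the asserted tolerances.

## Known limitations

* The right heart and pulmonary circulation are a single reservoir; no
  baroreflex, no exercise states, no 1-D/3-D wave propagation.
* Absolute parameter values of the fixed set are literature-typical
  round numbers, not fitted population values; conclusions should rest on
  within-pipeline comparisons, which is how the package uses them.
* Eq.-style direct E_max estimation is ~10 % biased high against this
  model's true E_max (see above); the ±10 % window makes this benign for
  the personalization but the *derived* scalar itself should not be read
  as an unbiased elastance measurement.
* The elastance shape parameters are sloppily identified from flow
  waveforms sampled at 30–40 ms plus two cuff pressures and ESV. E_min and
  α_S carry the widest noise-free recovery spread: typical draws recover
  them within a few percent, but occasional draws settle in a robust local
  minimum of the cost (gradient numerically zero, unreachable by restarts
  or Latin-hypercube multi-start at moderate budgets) with these two off
  by 10–30 % while every waveform still matches to a fraction of a
  percent. The pooled recovery median stays at the 1–2 % level; the
  per-parameter tails are an identifiability property of the data, not an
  optimizer bug.
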