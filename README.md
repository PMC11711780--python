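# flowtwin

Personalization of a lumped-parameter model of the left heart and systemic
circulation from non-invasive measurements — volumetric flow waveforms at
the mitral valve, the aortic valve and the ascending aorta, brachial cuff
pressures, and a handful of image-derived scalars — together with the
statistical machinery to ask how reproducible the personalized parameters
are when the *inputs* vary: repeated analysis by one observer, analysis by
a second observer, or a change of acquisition sequence.

It is aimed at cardiovascular modellers who want a compact, fully
reproducible sandbox for that question: because real flow-MRI datasets are
rarely redistributable, the package ships a synthetic-measurement generator
whose noise levels are calibrated to published repeatability figures for
this kind of data, and the whole study loop (generate → derive → fit →
compare) runs from a single seed.

## The model and the personalization

The circulation is a closed loop of 0-D compartments: a venous/pulmonary
reservoir feeds a left atrium and left ventricle described by time-varying
elastances, the LV ejects through an energy-loss aortic valve into an
ascending-aorta compliance `C_aa` (where the flow measurement plane sits),
then an arch/descending RLC segment, a peripheral Windkessel, and back to
the reservoir. Chamber pressure follows `P(t) = E(t) (V(t) − V0)` with the
double-Hill activation

```
E(t) = E_min + (E_max − E_min) · h(t)/h(t_max),
h(t) = [(t/(α_S T))^R_C / (1 + (t/(α_S T))^R_C)] · [1 + (t/(α_D T))^R_R]^(−1)
```

so six shape parameters (`E_max`, `E_min`, rates of contraction and
relaxation `R_C`, `R_R`, systolic and diastolic time constants `α_S`,
`α_D`) control the pressure–volume loop. The transvalvular gradient uses
the energy-loss formulation `ΔP = ρ/(2 ELCo²) · Q|Q| · (0.06/133.322) +
B dQ/dt` with `ELCo = EOA·A_LVOT/(A_LVOT − EOA)`.

Of the model's 40 parameters, 23 are subject-specific. Three are anchored
to measurements and allowed ±10 % during optimization — `EOA = SV/VTI`,
`A_LVOT`, and the directly estimated maximal elastance
`E_max = 0.9·(SBP + PG_max)/(ESV − V0_LV)` — the cycle length `T` is copied
exactly, and the remaining 20 are fitted by multi-start bound-constrained
least squares against the three measured flow waveforms plus the cuff
pressures and ESV.

The statistics module mirrors a paired repeatability study: Bland–Altman
bias and 1.96-SD limits of agreement, the repeatability coefficient of
variation (RMS within-subject SD over the grand mean), two-sided Wilcoxon
rank-sum tests, and per-site waveform RMSE.

## Worked example

```python
from flowtwin import simulate, estimate, default_parameters
from flowtwin.synthetic import draw_subject, observe, INTRA_NOISE

truth = draw_subject(seed=42)            # a random healthy subject
sim = simulate(truth)                    # periodic steady state
print(f"SBP/DBP {sim.sbp:.1f}/{sim.dbp:.1f} mmHg, "
      f"SV {sim.edv - sim.esv:.1f} mL")

bundle = observe(truth, INTRA_NOISE, seed=7, truth_sim=sim)  # one "analysis"
fit = estimate(bundle, seed=0, n_starts=1)
for name in ("E_max_lv", "alpha_D_lv", "C_aa"):
    print(f"{name}: fitted {fit.params[name]:.3f} vs true {truth[name]:.3f}")
```

prints (seeds as above; the personalization takes a few minutes):

```
SBP/DBP 131.9/83.0 mmHg, SV 85.4 mL
E_max_lv: fitted 2.209 vs true 2.242
alpha_D_lv: fitted 0.426 vs true 0.448
C_aa: fitted 0.267 vs true 0.320
```

i.e. the drawn subject has normal resting hemodynamics. Under realistic
single-analysis noise the maximal elastance (mmHg/mL) and diastolic time
constant come back within a few percent, while the ascending-aorta
compliance (here 0.267 fitted vs 0.320 mL/mmHg true) is visibly the least
identifiable of the headline parameters — the same ranking the
repeatability study machinery quantifies across a full cohort. The same loop runs from the shell:

```sh
flowtwin simulate --out out/
flowtwin cohort --n 10 --seed 1 --out cohort/
flowtwin variability --cohort cohort/ --comparison intra --out intra.csv
flowtwin run --config config.yaml        # full pipeline with manifest
```

## Layout

- `src/flowtwin/model.py` — closed-loop ODE model, periodic steady state
- `src/flowtwin/derivation.py` — EOA, ELCo, E_max from measurements
- `src/flowtwin/estimation.py` — cost and multi-start least squares
- `src/flowtwin/synthetic.py` — calibrated measurement-bundle generator
- `src/flowtwin/stats.py` — Bland–Altman, CoV, rank tests, RMSE
- `src/flowtwin/sensitivity.py` — one-at-a-time input sweeps
- `src/flowtwin/{io,config,pipeline,cli}.py` — formats, YAML config,
  end-to-end pipeline with manifest, command-line interface

See `docs/methods.md` for the modelling assumptions, parameter table
rationale, numerical choices and known limitations.
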