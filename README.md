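# protonarc

Automated treatment planning for **discrete proton arc therapy (PAT)** and
IMPT, at desk scale, on synthetic head-and-neck phantoms — for medical
physicists and algorithm developers who want to study *planning-system*
questions (energy-layer reduction, beam-angle selection, robust
multi-criteria optimization, bias-free plan comparison) without a clinical
TPS, patient data or a Monte-Carlo dose engine.

## What it does

Pencil-beam-scanning proton plans are vectors of nonnegative spot weights
(monitor units) `w` over candidate spots indexed by (field, energy layer,
lateral position), with dose linear in the weights: `d = D_s w` per error
scenario `s`. The package implements the full planning pipeline shared by
four delivery approaches:

1. **Beam configuration** — 36 equiangular arc fields (`pat36`,
   `utopia36`), the printed 4/6-field clinical class solutions with their
   range-shifter rules (`cs4`, `cs6`), or patient-tailored angles selected
   from 72 equiangular candidates by beam-level group sparsification
   (`bao6`/`bao8`/`bao10`).
2. **Energy-layer reduction (ELR)** for discrete PAT: group-lasso
   regularization over (field, energy-layer) spot groups,
   `min  f(w) + λ Σ_g √|g| ‖w_g‖₂   s.t.  hard constraints,  w ≥ 0`,
   trading the number of delivered energy layers (delivery time) against
   plan quality via λ. Utopia is the same pipeline with ELR skipped.
3. **Sparsity-induced spot selection (SISS)** — an L1-penalized solve of
   the scalarized wish-list surrogate pre-selects the high-weight spots.
4. **Lexicographic multi-criteria optimization (MCO)** — wish-list driven:
   hard constraints (robust target min/max over 21 setup×range scenarios,
   47 Gy per-field cap, OAR maxima) plus prioritized objectives minimized
   one at a time under ε-constraints on the higher priorities. One
   Pareto-optimal plan per phantom, same wish-list for every mode, so mode
   comparisons are free of planning bias.
5. **Finalization & evaluation** — minimum/maximum MU enforcement,
   normalization to CTV70 D98%(VWmin) = 95% of the 70 Gy prescription,
   then DVH metrics, logistic NTCP models, integral dose and exact paired
   Wilcoxon signed-rank comparisons between modes.

Robustness follows scenario-based evaluation: 21 scenarios = nominal, ±3%
range, ±3 mm setup shifts along three axes, and their combinations;
coverage metrics use the voxel-wise minimum (VWmin) and near-max metrics
the voxel-wise maximum (VWmax) over scenarios.

The dose engine is a documented analytic Bragg-peak + Gaussian-penumbra
model on parallel rays (see `docs/methods.md`) — enough physics for the
optimization algorithms to be exercised honestly, not a dose calculator.

## Worked example

```python
import protonarc as pa
from protonarc.pipeline import desk_config, run_mode

phantom = pa.generate_phantom(pa.default_quasi2d_spec(), seed=1)
plan, report = run_mode(phantom, "cs4", desk_config())

print(f"active spots    : {report.spot_count}  (energy layers: {report.el_count})")
print(f"CTV70 D98% VWmin: {report.structure_metrics['ctv70']['D98%_vwmin']:.2f} Gy")
print(f"parotid L/R mean: {report.structure_metrics['parotid_l']['Dmean_nominal']:.2f} / "
      f"{report.structure_metrics['parotid_r']['Dmean_nominal']:.2f} Gy")
print(f"cord D2% VWmax  : {report.structure_metrics['cord']['D2%_vwmax']:.2f} Gy")
print(f"per-field max   : {report.per_field_max_gy:.2f} Gy")
print(f"integral dose   : {report.integral_dose_gyl:.2f} Gy*L")
```

prints (about a minute on one CPU):

```
active spots    : 50  (energy layers: 36)
CTV70 D98% VWmin: 66.50 Gy
parotid L/R mean: 11.51 / 12.59 Gy
cord D2% VWmax  : 44.90 Gy
per-field max   : 47.00 Gy
integral dose   : 2.50 Gy*L
```

Reading the numbers: robust target coverage sits exactly at the
normalization point (66.5 Gy = 95% of 70 Gy in the worst-case-per-voxel
dose over all 21 scenarios); the cord's near-maximum dose presses against
its 45 Gy robust constraint; no field contributes more than the 47 Gy cap
anywhere; the parotid means are what the prioritized objectives could
achieve under those constraints with 4 fixed fields. Running
`run_mode(phantom, "pat36", ...)` on the same phantom yields lower OAR
means — the arc-vs-class-solution comparison the pipeline exists for — and
`run_study(10, ["utopia36", "pat36", "cs4", "cs6"], ...)` produces the
paired Wilcoxon tables across a seeded phantom cohort.

A CLI wraps the same stages: `protonarc phantom|dij|plan|finalize|evaluate|run|study`.

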