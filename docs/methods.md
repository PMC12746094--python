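# Methods

`protonarc` re-implements, at desk scale, an automated treatment-planning
stack for comparing proton delivery approaches — 36-field discrete proton
arc therapy (PAT), clinical 4- and 6-field beam-angle class solutions
(cs4/cs6), patient-tailored beam-angle-optimized IMPT (bao6/8/10), and a
36-field "Utopia" benchmark with no energy-layer reduction — on synthetic
oropharynx-like phantoms, with one shared optimizer so that differences
between approaches reflect geometry, not planning bias.

## Phantoms

A phantom is a relative-stopping-power raster plus boolean structure masks
on a regular grid (0-based indices; world = origin + (index + 0.5)·spacing;
all lengths mm). Structures are analytic shapes (ellipsoids, cylinders,
ellipsoidal shells, boxes) rasterized by a voxel-center-inside test and
clipped to the body. The default 3D spec approximates the clinical
population's target volumes (high-dose target ≈ 83 mL, elective target
≈ 270 mL) with two nested ellipsoids, bilateral parotid-like ellipsoids, a
pharyngeal-constrictor shell, a posterior cord cylinder and two
shoulder-like blocking slabs; no anatomical fidelity beyond volumes and
rough topology is claimed. Density is piecewise constant per structure
(body 1.0, air 0, bone-like 1.3 for the shoulder slabs) — only
radiological-depth behavior matters to the algorithms being exercised.

Quasi-2D phantoms (`nz = 1`) are first-class: a single axial slice of a
z-extruded anatomy. They make full robust optimization runs take seconds
and are used for all study-level testing. Two consequences of the extrusion
are deliberate: rays never leave the slab along z (density lookups clamp
the z index), and setup errors along z act trivially (spot rows exist at
every z of an extruded anatomy, so a z-shift maps the dose distribution
onto itself). The 21-scenario bookkeeping is unchanged; the four z-shift
scenario groups simply coincide with their in-plane counterparts. What
quasi-2D tests therefore cannot show: out-of-plane robustness effects,
non-coplanar geometry, and 3D dose-falloff behavior.

Study cohorts are generated from one spec with seeded jitter (centers
±3 mm, sizes ±5%) emulating inter-patient variation. Identical (spec, seed)
gives bitwise-identical phantoms.

## Dose model

The engine is an analytic parallel-ray pencil-beam model — a stand-in for a
clinical dose engine, keeping only the features the planning algorithms
rely on:

* depth dose `D(z; R)`: Gaussian-smeared Bragg peak at the nominal range
  `R` (width w80 = 6 mm WET) over an entrance plateau (35% of peak, mild
  buildup, erfc distal rolloff). The peak sits within ~1 mm of `R`.
* lateral profile: Gaussian with `sigma(z) = sqrt(sigma0^2 + (k z)^2)`,
  `sigma0 = 3 mm`, `k = 0.04` — monotone depth broadening is the only
  property downstream logic uses.
* range shifter: adds 34 mm water-equivalent thickness upstream (pulling
  the in-patient peak back by exactly 34 mm for a fixed machine range) and
  a fixed `sigma` increment of 4 mm — the penumbra cost that makes
  shifter-free arc delivery attractive.
* radiological depth: midpoint-rule line integral of density along the ray
  (default step 2–3 mm), scaled by the scenario's range multiplier
  (undershoot = denser = ×1.03).
* per-MU calibration: 3 Gy/MU on the spot axis at the Bragg peak, chosen so
  optimized spot weights land inside a clinical-style MU window
  (MUmin 0.02, MUmax 50). The lateral Gaussian multiplies `D(z)` directly
  (no fluence-spreading renormalization), so the on-axis depth of maximum
  dose equals the nominal range by construction.
* sparsity: dose-influence entries below `1e-4` × column max are dropped
  (desk-scale configs use `1e-3`–`2e-3`; the entrance plateau keeps proton
  columns intrinsically long, and this floor dominates problem size).

Setup-error scenarios evaluate the nominal dose field at `x + shift`
(equivalent to a rigid beam-vs-patient translation for parallel beams);
range scenarios scale density during WET integration. Candidate spots per
field cover the union-target beam's-eye-view projection (default 5 mm
lateral lattice, 7–9 mm in desk configs) with energy layers on a global WET
lattice (default 5 mm) spanning each ray's target depth interval, both
expanded by a margin (7–8 mm) that absorbs the 3 mm setup and 3% range
errors. Spots whose entrance ray crosses a blocking structure (shoulders in
the default anatomy) are removed up front. The isocenter is the center of
mass of the elective target.

## Wish-list optimization

A wish-list holds hard constraints and prioritized objectives. The shipped
default (robust min/max on the targets, a robust cord max, a nominal body
max, the 47 Gy per-field cap; objectives parotids → constrictor → cord →
low-dose bath) is an illustrative recipe for the synthetic anatomy, not a
clinical protocol; goal values are configuration.

Robust items are enforced per scenario (21 copies — scenario-based rather
than worst-case reformulation). `per_field_max_dose` bounds each field's own
dose in the nominal scenario. Mean-dose terms are linear; max-dose terms use
an epigraph auxiliary; every stage is a sparse LP solved with HiGHS.

Lexicographic solving minimizes priority k subject to hard constraints and
to previously optimized objectives bounded at `achieved·(1 + delta)`
(`delta = 0.03`, plus a 0.01 Gy absolute slack against numerical
infeasibility). Objectives marked *sufficient* stop improving at their goal:
the recorded value is clipped at the goal when the optimum lies below it, so
later priorities may spend the slack. With `delta = 0` the scheme is
strictly lexicographic. Equal-cost optima are left to the solver's choice;
tests assert objective values, never weight uniqueness.

The scalarized surrogate used by all sparsification stages is the
inverse-priority weighted sum (priority k weighted `10^(1-k)`) of the same
objective terms under the same hard constraints. Its optimal value is the
"plan quality" scalar used in mode comparisons; restricting the spot support
can only increase it, which is what makes the Utopia ≤ PAT and
bao6 ≥ bao8 ≥ bao10 ordering laws exact rather than empirical.

## Sparsification stages

**SISS (spot selection).** The surrogate plus `coefficient · sum(w)` (exact
L1 on nonnegative weights) is one LP; spots above `1e-3` × max weight
survive. An optional bisection hits a requested spot count within ±5%.

**ELR (energy-layer reduction).** Groups are (field, energy layer) spot
sets; the surrogate gains the classical group-lasso penalty
`lambda · sum_g sqrt(|g|) · ||w_g||_2` (an L∞-style grouping is available
behind a config switch). Layers above `1e-3` × max group norm survive; all
spots of unselected layers are removed before SISS/MCO. `tune_lambda`
bisects log-lambda to a requested EL count. At `lambda = 0` the pipeline
skips the stage entirely, which makes pat36 at zero coefficient literally
identical to utopia36.

**BAO (beam-angle optimization).** The same group machinery at beam level:
72 equiangular coplanar candidates, one group per beam, rank by group norm,
keep the top N (ties toward the smaller gantry angle). Because all three
configurations come from one ranking, the 6/8/10-beam sets are nested. Desk
configurations run candidates with range shifters in all fields — without
them, few-field configurations at the coarse spot lattice often cannot
cover the target robustly at all, which is the penumbra-vs-coverage
trade-off that motivates shifter use clinically. Each selected
configuration is then planned twice (shifters in all fields / in none) and
the better plan is kept: lower summed NTCP, then lower integral dose. At
desk scale candidates run at the base lattice (`bao_coarsen = 1`); the 2×
coarsening knob exists for machine-resolution runs.

**Penalized solver.** No installed convex-programming package handles
linearly constrained group-lasso programs, so the package carries its own:
the group norm is smoothed (`sqrt(||w_g||^2 + eps^2) - eps`, `eps = 1e-3`),
constraints enter through an escalating quadratic exterior penalty
(escalation ×10 until max violation ≤ 0.01 Gy), and L-BFGS-B minimizes the
smooth bound-constrained problem, warm-started from the unpenalized LP.
The output is used only for *selection*; every downstream stage re-solves
an exact LP on the selected support, which restores exact feasibility.
Selections match exhaustive subset enumeration on the toy registry.

## Finalization and evaluation

**MU limits.** Spots below MUmin are dropped and the surrogate is re-solved
with the MUmax ceiling, iterating (≤ 8 rounds) until no surviving spot falls
below MUmin, then one box-constrained solve (`MUmin ≤ w ≤ MUmax`) fixes the
final weights — a deliberate extension of single-pass constraint
restoration, because forcing every initially surviving spot to MUmin in one
shot is structurally infeasible at coarse spot lattices. Final weights obey
`{0} ∪ [MUmin, MUmax]`.

**Normalization.** All weights are scaled so the high-dose target's D98% of
the voxel-wise minimum (VWmin) over the 21 scenarios equals 95% of the
70 Gy prescription. Dose is linear in weights, so the result is exact; MU
compliance is re-checked once and violations warn rather than loop
(guaranteed termination). Normalization follows MU enforcement.

**Evaluation.** Dq% is the volume-weighted inverse DVH with linear
interpolation between sorted voxel doses (no sub-voxel boundary handling);
mean doses are nominal-scenario; near-maximum doses are D2% of VWmax (D2%
being the conventional choice; configurable). Integral dose is summed over
the whole body, targets included (a `--exclude-targets` style switch exists
in the API, off by default, and every report logs the volume definition
used). NTCP models are logistic in transformed dose predictors
(identity/sqrt), the structure of the Dutch national protocol models for
xerostomia and dysphagia; shipped coefficients are illustrative
configuration data for synthetic phantoms, not the published clinical
models. Paired mode comparisons use two-sided Wilcoxon signed-rank tests
with zeros dropped and mid-ranks for ties; the null distribution is exact
(dynamic programming over rank sums) for n ≤ 25, normal approximation
beyond. For 10 phantoms and all-same-sign differences the exact two-sided
floor is p = 2/1024 ≈ 0.002.

## Problem sizes and numerical choices

Desk-scale runs use quasi-2D phantoms: 48×48 voxels at 4 mm with 7 mm
spot/EL lattices for single-plan runs (≈ 1200 candidate spots for cs4), and
28×28 at 4 mm with 9 mm lattices for multi-phantom studies (≈ 800–6000
candidate spots depending on mode). These sizes were chosen so a full
robust 21-scenario plan solves in seconds to tens of seconds on one CPU;
they are the package's study conditions and are not varied per test.
Solver tolerances: hard constraints hold to 1e-3 Gy; surrogate objective
comparisons use 1e-6 absolute slack; epsilon-constraint slack is
`delta = 0.03` plus 0.01 Gy.

## Known limitations

* Parallel-ray beams (infinite SAD): no divergence; penumbra trends only.
* No Monte-Carlo transport, nuclear halo, heterogeneity scatter, or
  LET/RBE modelling; density is piecewise constant.
* Delivery time is not modelled; EL counts are its only proxy.
* The lexicographic restoration after MU enforcement re-optimizes the
  scalarized surrogate, not the full priority stack.
* NTCP coefficients and the wish-list are illustrative configuration;
  absolute NTCP values on synthetic phantoms carry no clinical meaning —
  only paired differences between modes are interpretable.
* Quasi-2D studies cannot exercise out-of-plane robustness or the printed
  non-coplanar couch angles' 3D geometry (they are applied as a rotation
  about the vertical axis and work on 3D grids).
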