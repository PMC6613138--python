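# Methods

## Model

The package simulates a radially symmetric colony biofilm as a
moving-boundary (Stefan-type) problem.  Biomass is an indicator field of
constant density `B0` (normalized to 1) on the disc `r < s(t)`.  Growth adds
mass at specific rate `g(F)`, a Hill response to local free iron with
exponent `m` and half-saturation `Fh`, cut off sharply below the minimum
supporting level `Fc`.  Because the biomass density is constant, mass
conservation turns the growth term into a source for an elliptic pressure
problem, `λΔp = −g` inside the footprint with `p(s) = 0` and symmetry at the
axis, and the edge advances with the Darcy velocity `v = −λ∂r p` at `r = s`.
By the divergence theorem this velocity equals `(1/s)∫₀ˢ g(F(r)) r dr`, which
is how the solver evaluates it: the identity is exact for the continuous
problem, makes `v ≥ 0` structural (no front retraction), and shows that the
mobility λ cancels from the observable dynamics — only the pressure field
itself scales with it.  λ is therefore carried as a parameter but is not
identifiable from area data, and the calibration never fits it.

Pulcherriminic acid `A` is produced under the footprint at rate `kb·B`,
chelates free iron by mass action (`kp·F·A`) into the immobile deposit
pulcherrimin `C`, and all three species diffuse in the agar (the deposit with
a token small `DC`; no measured value exists, and the code accepts `DC = 0`).
Iron is additionally consumed by biomass maintenance at `kf·B·F`.  A closed
dish is assumed: zero flux at the axis and at `R_dish`.

Arrest emerges, rather than being imposed: the chelation wave travels at a
speed set by `kb/F0` while the front moves at a speed set by the growth
response; when production is strong enough the wave overtakes the front,
`F < Fc` in a band beyond the edge, `g` vanishes on the whole footprint
neighbourhood, and `v → 0`.  With `kb = 0` the wave never exists, `C ≡ 0`,
and expansion continues to the dish wall.

## Nondimensionalization

Concentrations scale with the initial iron `F0`, time with `1/κ0`, length
with `R_dish`.  The resulting groups (chelation number `kp F0/κ0`, production
number `kb B0/(κ0 F0)`, utilization number `kf B0/κ0`, diffusivity ratios
`D/(κ0 R²)`, scaled thresholds `Fc/F0`, `Cc/F0`) determine the dynamics
completely.  The invariance this encodes — multiplying `F0, Fh, Fc, Cc, kb`
by a constant and dividing `kp` by the same constant leaves every observable
unchanged — is verified by test and is the reason the calibration reports the
chelation product `kb·kp` rather than either factor alone.

## Default parameters

No published table of fitted constants accompanies the qualitative
description this model formalizes, so the defaults were calibrated once
against the reported experimental conditions and retained:

| parameter | value | unit | rationale |
|---|---|---|---|
| κ0 | 0.08 | 1/h | non-producer front reaches the 4.5 cm dish wall near 73 h |
| Fh | 5 | uM | growth mildly iron-limited at 50 uM supplementation |
| m | 2 | – | generic cooperative response; no measured value |
| Fc | 1 | uM | iron in the depleted halo zone reads below a 1 uM detection limit |
| kb | 12 | uM/h | chelation wave overtakes the front within the arresting range of F0 |
| kp | 0.0067 | 1/(uM·h) | with kb, sets arrest onset at ~2.5 d for 50 uM iron |
| kf | 0.015 | 1/h | leaves ~15–20 uM under a non-producer colony after 72 h |
| DA, DF | 0.02 | cm²/h | small-molecule diffusivity in agar (~10⁻⁵·0.5 cm²/s) |
| DC | 10⁻⁴ | cm²/h | pulcherrimin is a deposit; token mobility |
| F0 | 50 | uM | standard FeCl₃ supplementation of the growth medium |
| s0 | 0.25 | cm | 5 uL inoculation spot |
| R_dish | 4.5 | cm | 9-cm Petri dish |
| Cc | 0.5 | uM | halo visibility threshold, 1% of initial iron |

With these values the producer arrests at 60.3 h with a 4.77 cm² footprint
and a pulcherrimin halo beyond the front, and the non-producer covers the
dish — both regimes under one parameter set, which is the model's central
qualitative claim.

## Numerical scheme

* **Grid.** Uniform cell-centered finite volumes on `[0, R_dish]`; default
  900 cells (50 um).  Annulus areas `2πr_i·dr` are exact, so the discrete
  mass functional is an exact quadrature of piecewise-constant fields.
* **Diffusion.** Backward Euler with the symmetric finite-volume Laplacian;
  tridiagonal solves via `scipy.linalg.solveh_banded`.  The inner edge of the
  first cell carries zero area, which regularizes the axis without special
  casing.  Unconditionally stable, positivity-preserving (M-matrix), mass
  conserved to roundoff.
* **Reaction.** Strang cascade of closed-form updates per substep: half
  production (linear), half utilization (exact exponential decay), full
  chelation via the analytic solution of the bimolecular pair `A + F → C`
  (`X = AF·expm1(z)/(A·expm1(z) + A − F)`, `z = (A−F)kp·dt`), then the
  mirrored half steps.  Every update is exact for its sub-dynamics, hence
  unconditionally positive; chelated iron moves to `C` and utilized iron to
  the consumed pool with no leakage, so budget closure holds to machine
  precision by construction.
* **Pressure/front.** The Poisson problem is discretized on a front-fixed
  subgrid `ξ = r/s` (Dirichlet through the boundary half-cell, second-order
  accurate; verified against the closed form and a shooting oracle).  The
  stepper itself uses the flux-integral identity for the edge velocity with
  exact partial-annulus weighting of the edge cell, and advances `s` with a
  Heun predictor–corrector (the velocity depends on `s` through the domain of
  integration), which meets a 1% tolerance against the exponential-growth
  ODE oracle over five front doublings.
* **Step control.** dt halves whenever any field's per-step change exceeds
  5% of its running maximum (floored at 1% of `F0`) or the front crosses more
  than one cell, and doubles back toward `dt_max = 0.5 h` after four easy
  accepts.  The accepted-step history is interpolated linearly onto the
  requested sampling cadence; snapshots are the first accepted state at or
  after each requested time.  Everything is deterministic — identical inputs
  give bit-identical trajectories.

## Calibration

Plain least squares on areas, with the producer and non-producer regimes
simulated separately and interpolated at the observation times.  Stage 1 fits
`{κ0, kf, Fh}` to the non-producer data with `kb = 0` (chelation parameters
provably cannot affect this stage); stage 2 freezes them and fits `{kb, Fc}`
to the producer data, holding `kp` so that `kb` carries the identifiable
`kb·kp` group.  The search runs over log-parameters in multiplicative box
bounds (default ×30 either way) with bounded Nelder–Mead.  Termination is
set by a 1% log-parameter resolution: below that, discrete changes in the
adaptive step sequence give the simulated objective a jitter floor that a
tighter tolerance would chase forever.  A failing simulation returns a large
finite penalty so the simplex can retreat.

At 2% multiplicative measurement noise the ten-seed recovery study
(`scripts/acceptance.py`) recovers κ0 to well under 1% and the chelation
group to a median of roughly 10–15%; individual seeds can reach ~16% because
`kb` and `Fc` trade off along a shallow valley that equally fits a noisy
arrest shoulder.  This is an identifiability limit of the data, not of the
optimizer — restarting the simplex does not move it — and mirrors the
observation that different grouped-parameter combinations fit the area data
comparably well.

## Synthetic data

The generator emulates the study's observables: footprint areas sampled
every 20 min over 160 h (481 points), three replicates, multiplicative
Gaussian noise (CV 2%) with a 0.01 cm² additive floor, clipped to the dish;
a 9-point ferrozine standard curve over 0–400 uM; Poisson–binomial CFU pairs
for sporulation.  It does **not** emulate biological replicate-to-replicate
variability (an optional parameter jitter hook exists but defaults off),
image segmentation artifacts, agar drying, or non-radial colony shapes — so
passing recovery tests demonstrate correctness of the pipeline under the
stated noise model, not robustness to real-world systematics.

## Analysis conventions

* **Arrest** is declared at the earliest sample after which the forward
  5-h-windowed mean front velocity stays below 10⁻³ cm/h through the end of
  the run; runs whose front reaches the dish wall are "expanding".
* **Linear phase** statistics are read, as in routine growth-curve analysis,
  on the stretch where the area lies between 20% and 80% of its final value
  (straddling the inflection, excluding lag and deceleration); the mutant's
  **exponential phase** is read where the front lies between 30% and 95% of
  the dish radius.
* **Halo radii** are outermost threshold crossings on the discrete fields
  (`C > Cc` for visibility, `F < Fc` for depletion).  Near arrest the
  depletion radius overtakes the front; at late times the visibility halo
  keeps spreading with continued production, so the two radii are reported
  separately.
* The ferrozine report censors values above 350 uM to 350 uM ("at upper
  limit"), flags values below 1 uM ("below detection"), and clamps negative
  inversions to zero; spore percentages above 100% are reported but flagged.

## Problem sizes

Default runs use the 900-cell grid (50 um) over 160 h.  The recovery study
uses a 300-cell grid, chosen so that the ten-seed fit completes in a few
minutes while leaving discretization error far below the parameter-recovery
tolerance; coarser 150-cell grids serve the fast unit tests.

## Known limitations

* Strictly radial, one-dimensional: no two-colony competition, wrinkle
  morphology, vertical structure, or matrix-component resolution.
* The front cannot retract; the elliptic problem with `g ≥ 0` guarantees
  `v ≥ 0`, and the model offers no mechanism for biomass loss.
* The high-iron growth inhibition observed for non-producing strains at 10×
  supplementation is outside the model: growth is monotone in iron here, so
  the non-producer never arrests at any `F0`.
* `λ` and the absolute scale of `(kb, kp)` are structurally non-identifiable
  from area data (see the scaling symmetry above).
* The sharp `Fc` cutoff makes `g` discontinuous in `F`; an optional C¹ ramp
  (`fc_ramp`) is available if a smoother response is preferred, and is off by
  default.
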