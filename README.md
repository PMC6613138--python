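# ironfront

A moving-boundary model of why *Bacillus subtilis* colony biofilms stop
expanding.

On iron-supplemented agar, a wild-type *B. subtilis* biofilm spreads for two
to three days and then arrests at a fixed footprint, while strains unable to
synthesize the extracellular iron chelator **pulcherriminic acid** keep
expanding until they hit the dish wall.  `ironfront` implements the continuum
model that explains this dichotomy: the secreted chelator diffuses ahead of
the colony, precipitates free ferric iron into the insoluble deposit
**pulcherrimin**, and starves the advancing edge of the iron it needs to
grow.  The package is for quantitative microbiologists and modellers who want
to simulate, calibrate, and probe that mechanism against footprint-area
time-lapse data.

## The model

Biomass of constant density `B0` occupies a disc of radius `s(t)` on the agar
plate.  Growth-generated pressure `p` drives radial expansion through a Darcy
closure, and the edge moves with the local Darcy velocity:

    ∂t B = ∇·(B λ∇p) + B g(F)                 (biomass)
    v = −λ ∂r p   at  r = s(t)                (edge velocity)

with a Hill-type growth response to free iron `F` that shuts off completely
below a threshold:

    g(F) = κ0 F^m / (Fh^m + F^m)   for F ≥ Fc,     g(F) = 0  for F < Fc.

Pulcherriminic acid `A`, pulcherrimin `C` and free iron `F` react and diffuse
in the agar:

    ∂t A = kb B − kp F A + DA ΔA
    ∂t C =        kp F A + DC ΔC
    ∂t F =      − kp F A − kf B F + DF ΔF

Setting `kb = 0` models non-producing mutants.  With production on, the
chelation wave overtakes the front, drives `F < Fc` in a band beyond the
edge, and the colony arrests inside a visible pulcherrimin halo (`C > Cc`
out to a radius `r_h > s`).  With production off the model predicts unbounded
(near-exponential) expansion — the mutant phenotype.

The solver discretizes the agar disc on a uniform radial finite-volume grid,
integrates reaction–diffusion with Strang splitting (exact positive reaction
updates, implicit diffusion), solves the pressure Poisson problem on a
front-fixed subgrid, and advances the front with a Heun step.  Iron is
conserved to machine precision: free + chelated + consumed = initial, always.

## Worked example

```python
import ironfront as irf

params = irf.default_parameters()           # 50 uM FeCl3, 9-cm dish
grid = irf.RadialGrid.from_radius(params.R_dish, 900)

producer = irf.simulate(params, grid, t_end=160.0)
mutant = irf.simulate(params.as_mutant(), grid, t_end=160.0)

print(f"producer: arrest at {producer.arrest_time:.1f} h, "
      f"terminal area {producer.area[-1]:.2f} cm^2")
print(f"mutant:   final area {mutant.area[-1]:.2f} cm^2, "
      f"reached dish wall: {mutant.reached_boundary}")
```

prints

```
producer: arrest at 60.3 h, terminal area 4.77 cm^2
mutant:   final area 63.62 cm^2, reached dish wall: True
```

The producer stops after ~2.5 days at a 4.8 cm² footprint — iron beyond its
edge has been chelated below the growth threshold `Fc`, and the pulcherrimin
halo extends past the front.  The mutant covers the full 63.6 cm² dish by
~73 h.  The same pipeline runs from the shell:

```sh
ironfront simulate --out run/                 # trajectory.csv + config + log
ironfront simulate --out run-mutant/ --mutant
ironfront synth areas --seed 7 --out data/    # noisy synthetic time-lapse
ironfront fit --producer data/areas_producer.csv \
              --non-producer data/areas_non_producer.csv --out fit/
ironfront sweep --f0 25,50,100,250,500 --out sweep/
```

`fit` mirrors the study's two-stage calibration: growth parameters against
the non-producer curve first (chelation cannot affect it), then chelation
parameters against the producer curve.  Because rescaling all concentrations
is a symmetry of the model, only the product `kb·kp` is identifiable; the fit
report states it explicitly.

## Layout

- `ironfront.model` — kinetic laws, parameters, nondimensionalization
- `ironfront.grid`, `ironfront.solver` — radial finite volumes, moving front
- `ironfront.calibration` — area objective, two-stage fit, initial-iron sweep
- `ironfront.synthetic` — seeded generators for areas, standards, CFU counts
- `ironfront.assays` — ferrozine inverse calibration, spore percentages
- `ironfront.config`, `ironfront.cli` — strict configs and the `ironfront` CLI

See `docs/methods.md` for the numerical scheme, parameter choices, and known
limitations.
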