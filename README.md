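# gastrosim

Particle-resolved 2D simulation of solid-food **trituration** in a
peristaltically contracting stomach.

Large solid food particles (> 1–2 mm) cannot pass the pyloric sphincter:
they must first be ground down in the antrum by the combined squeeze of
antral contraction waves, hydrodynamic stresses and particle–particle
collisions. Those forces are essentially unmeasurable *in vivo*.
`gastrosim` is for researchers in digestive biomechanics, food science and
oral drug delivery who want a desk-scale, fully inspectable model of that
process: it resolves each particle, quantifies the pressure, shear and
contact forces acting on it, and contrasts a healthy stomach with an
antral-hypomotility (gastroparesis-like) stomach at different liquid
viscosities.

## Model

* **Fluid.** Incompressible Navier–Stokes, ∇·**u** = 0 and
  ρ(∂**u**/∂t + **u**·∇**u**) = −∇p + μ∇²**u**, on a fixed Cartesian MAC
  grid (fractional-step projection, AB2/QUICK explicit predictor, direct
  sparse Poisson solve). ρ = 1000 kg m⁻³; μ = 1 or 10 mPa s.
* **Stomach.** A parametric 2D lumen (fundus → body → antrum → pylorus →
  short duodenal segment) around a J-shaped centreline, half-width
  R(s,t) = R₀(s)·(1 − occ(s,t)) with Gaussian occlusion waves travelling
  toward the pylorus (period T_p = 20 s, peak relative occlusion A = 0.8,
  deepening to full amplitude through the terminal antrum). Hypomotility
  scales the occlusion by χ (healthy χ = 1, hypomotile χ = 0.5 by default).
  Walls and particles act on the fluid through volume-fraction
  immersed-boundary forcing. A 2 mm pyloric sieve keeps the particles in.
* **Particles.** Eight rigid 4 mm discs of density 1.1 g cm⁻³ with
  three degrees of freedom each: m dv_p/dt = F_f + F_c + W and
  I dω_p/dt = M_f + M_c, where F_f (pressure + viscous traction surface
  integrals) is evaluated from extrapolated surface probes, F_c is a
  Hertzian spring–dashpot contact force (repulsion only, activation gap
  0.1 mm), and W is the buoyancy-corrected weight.
* **Diagnostics.** Per-particle surface means τ̄ₙ = ∮τ dA / ∮dA and p̄ₙ
  (gauge: duodenal outlet), ensemble means ⟨τ⟩ = (1/N)Σ τ̄ₙ with min/max
  envelopes, distance-to-pylorus trajectories, transpyloric flux and
  emptying rates, contact-force event logs, and summary statistics tables.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Healthy vs. hypomotile stomach at low viscosity (μ = 1 mPa s), 45 s each
with a 0.5 mm grid:

```yaml
# study.yaml
duration_s: 45.0
numerics:
  grid_h_mm: 0.5
```

```bash
gastrosim run --config study.yaml --out runs/healthy
gastrosim run --config study.yaml --out runs/hypo --motility hypomotile
gastrosim compare runs/healthy runs/hypo
gastrosim plot runs/healthy
```

Each run directory contains tidy CSV series (`particles.csv`, `flux.csv`,
`contacts.csv`), a `summary.txt`, optional VTK snapshots and checkpoints.
The healthy run prints:

```
gastrosim run: scenario=gastric motility=healthy mu=1.0 mPa s, particles=True
emptying rate over (20.0, 40.0): 0.198 ml/min
min distance to pylorus (mm, sorted): 5.7 9.5 13.3 15.2 18.1 20.8 21.9 31.7; average 17.0
      quantity      mean        sd        max
p - p_duo (Pa) -1.954505 38.690615  73.574865
     tau (mPa)  5.180155 17.060502 357.872195
```

and the hypomotile run:

```
emptying rate over (20.0, 40.0): 3.376 ml/min
min distance to pylorus (mm, sorted): 14.6 17.7 19.3 20.7 24.1 27.7 31.4 35.3; average 23.9
      quantity     mean       sd       max
p - p_duo (Pa) 0.127473 0.100160  1.275258
     tau (mPa) 1.041441 1.427915 21.134162
```

Reading these: the particles settle into the antral sinus within a couple of
seconds and then shuttle with the 20 s wave period. In the healthy stomach
the deep terminal waves carry the lowest particles to within ~6 mm of the
pylorus, squeeze them during the terminal antral contraction (peak contact
forces there exceed the hypomotile case by more than an order of magnitude)
and eject them backwards; surface shear is correspondingly higher and far
more intermittent (mean 5.2 mPa, max 358 mPa vs. 1.0/21 mPa hypomotile).
The hypomotile stomach never grips the particles — its average closest
approach to the pylorus is ~41% farther — which is the mechanical signature
of impaired trituration. A liquid-only companion run
(`gastrosim run ... --no-particles`) empties faster than the same stomach
with solids present, because trapped solids obstruct the terminal antrum.

Validation (`gastrosim bench`) runs Poiseuille, Taylor–Green, hydrostatic,
peristaltic-pumping and closed-lumen mass-conservation oracles plus the two
canonical particle cases — a disc settling in a channel against a
drag-correlation ODE, and the draft–kiss–tumble pair — and writes a
machine-readable pass/fail report.

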