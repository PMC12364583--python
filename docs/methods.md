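# Methods

`gastrosim` simulates the mechanical processing (trituration) of large solid
food particles in a contracting stomach: an incompressible liquid phase, a
moving lumen wall, and rigid circular particles that are too large to pass
the pyloric sieve. This note documents the model, its numerical treatment,
the parameters that matter, and what the synthetic scenario does and does not
represent.

## Physical model

**Geometry.** The stomach is a two-dimensional planar slice: a tube of
half-width `R0(s)` around a J-shaped centreline, where the arc coordinate
`s` is measured from the pyloric plane (s = 0) and increases proximally.
The lumen comprises a fundus chamber at the top, a body descending along the
greater curvature, an antrum that forms the lowest region of the stomach, a
pylorus with a 1 mm rest half-gap (a 2 mm sieve: 4 mm particles can never
empty), and a short straight duodenal segment that leaves the domain. The
sinus — the most dependent point, where heavy solids settle — lies just
proximal of the pylorus (s ≈ 20 mm), with the gastric outlet above the level
of the settled contents, matching the classical clinical picture of solid
gastric digestion. Gravity points along −y.

A 3D imaging-based anatomy was deliberately replaced by this parametric
model: every geometric feature is a named, documented parameter, and the
trituration mechanics of interest (settling, wave-driven shuttling, terminal
antral trapping, retropulsion) survive the reduction to 2D. The price is
quantitative: all reported magnitudes are per unit depth, converted with a
nominal depth of one particle diameter (4 mm) for ml/min and N-equivalent
outputs, and should be read as scaled-down analogues of 3D values.

**Antral contraction waves.** The instantaneous half-width is

    R(s, t) = max( R0(s) · (1 − occ(s, t)),  R_floor ),

where `occ` is a train of Gaussian occlusions of half-width w = 10 mm
travelling toward the pylorus at c = s_start / T_p (one antral traverse per
period; T_p = 20 s; a new wave launches every period, at most two active at
once). The depth is `χ · A · ramp(s) · gate(s)`: A = 0.8 peak occlusion,
`ramp` grows linearly from 0 at the wave origin (s_start = 55 mm, the antrum
entry) and saturates at 1 for s ≤ s_full = 20 mm, so waves run at full depth
through the terminal antrum — the terminal antral contraction (TAC).
`gate` fades the occlusion to zero across the pyloric plane over 3 mm, which
co-modulates the pyloric gap with each arriving wave (closing toward
`R_floor` = 0.5 mm at the TAC, reopening as the wave dies); the duodenum
never contracts. Antral hypomotility is the single factor χ (1 healthy,
0.5 hypomotile default).

The ramp saturation at the terminal-antrum entry matters mechanically:
physiological antral waves approach lumen-occluding depth throughout the
distal antrum, and it is this that lets a wave grip (lumen gap < particle
diameter) and carry settled particles from the sinus into the TAC. With a
ramp that only reaches full depth at s = 0, the minimum particle–pylorus
distance is set by gravity alone and healthy and hypomotile runs become
nearly indistinguishable — contrary to the motility contrast the model is
meant to expose.

**Fluid.** Incompressible Navier–Stokes, ρ = 1000 kg/m³, μ = 1 or 10 mPa s.
The solver works in dynamic pressure: with a uniform liquid density the
hydrostatic component is analytic, so gravity is dropped from the fluid
momentum equation and applied to the particles as a net weight
(m − ρA)g. Reported surface pressures are therefore free of hydrostatic
head and gauged to the duodenal outlet (p_duo = 0). A gravity body-force
term remains available and is exercised by the hydrostatic benchmarks.

**Fundic tone inlet.** With fully prescribed periodic wall motion and a
single opening, incompressibility forces the net transpyloric flux over a
period to vanish identically — no prescribed-wall model can empty. Real
stomachs empty because the proximal stomach loses volume (fundic tone).
This is modelled as a small Dirichlet-pressure patch (default 0.2 Pa) at the
fundus apex: a compliant proximal boundary that feeds liquid as the antral
pump ejects it. Net emptying then arises from wave pumping rectified by the
pyloric co-modulation, and particles crowding the terminal antrum can
obstruct it — the mechanism behind the with/without-solids comparison.

**Particles.** Eight rigid discs of diameter 4 mm and density 1.1 g/cm³
(meat- or nut-like, heavier than the liquid), released as a 2×4 cluster in
the upper stomach with 0.2 mm surface-to-surface gaps (read as surface gaps;
4 mm spheres with centres 0.2 mm apart would interpenetrate). Each disc has
three degrees of freedom; disc inertia I = m r²/2. Hydrodynamic loads are
surface integrals of pressure and viscous traction; the gravitational and
contact forces complete the momentum balance. Particle size reduction
(erosion, fracture) is out of scope, as are non-circular shapes, secretion,
pH and enzymatic softening.

**Contacts.** Hertzian-style repulsion-only spring (force ∝ overlap^{3/2})
with a linear dashpot, activated when the surface gap drops below
g_act = 0.1 mm (inactive at the 0.2 mm release spacing). Default stiffness
is sized so a 50 mm/s head-on impact peaks at 5% of the radius; default
damping targets restitution ≈ 0.3 (food is dissipative). Contacts are
frictionless by default, so the contact moment is identically zero for
discs; an optional Coulomb tangential term is provided. The particle–wall
normal is the gradient of the tube signed distance, ∇φ = sign(d)·n̂ −
(∂R/∂s)·t̂: the flank of an advancing occlusion therefore pushes particles
along the tube as well as transversely. This term is what makes the wave
"shovel" settled solids toward the pylorus and is geometrically exact for
the tube description, not an adjustable closure.

## Numerics

* **Grid.** Uniform MAC staggered grid (pressure at centres, velocities at
  faces); default h = 0.4 mm (10 cells per particle diameter). The study
  runs in this repository use h = 0.5 mm, the 8-cells-per-diameter
  resolution floor.
* **Time stepping.** Explicit fractional step: variable-step Adams–Bashforth-2
  with QUICK (quadratic upwind-biased) advective fluxes and second-order
  central diffusion; adaptive dt at convective CFL 0.4, capped at 2 ms and
  bounded by the explicit diffusion limit h²ρ/(4μ). The first step of a run
  is forward Euler.
* **Immersed boundaries.** Volume-fraction direct forcing: face velocities
  are blended toward the local solid velocity (wall or particle rigid-body
  velocity) with weight equal to the solid fraction, smeared over one cell.
  First-order accurate at interfaces; the trade-off against sharp-interface
  schemes is accepted for robustness with many moving bodies at desk scale.
* **Pressure.** Five-point Poisson solve by direct sparse LU, factorized
  once per run (the matrix is constant: Dirichlet rows at the duodenal
  outlet strip, the fundic tone inlet, and deep-exterior cells; Neumann at
  box walls; a pinned cell in closed boxes). Post-projection divergence in
  fluid cells is at machine precision (tolerance 1e-8 s⁻¹ asserted).
* **Surface loads.** Pressure and cell-centred velocity gradients are
  sampled by bilinear interpolation at M = max(32, ⌈2πr/h⌉) equispaced
  probes on two rings at r+h and r+2h and linearly extrapolated to the
  surface; inside those offsets the fields are contaminated by the interior
  forcing. The extrapolation is exact for uniform and linear fields (the
  Archimedes check) and brings the settling benchmark within a few percent
  of the drag-correlation oracle. The surface-mean shear τ̄ is the mean of
  the |tangential traction| over probes (the magnitude convention is a
  declared choice; the reduction is not otherwise defined).
* **Coupling.** Loose one-pass coupling per step: wall kinematics at t+dt →
  fluid step with solid velocities at t → hydrodynamic loads → contact
  detection/forces → rigid-body integration. A virtual-mass term
  C_vm ρ A (C_vm = 0.5) augments the translational inertia — the standard
  stabilization for loose coupling at density ratio ≈ 1; it damps transients
  without altering steady states (terminal velocities are unaffected).
* **Contact sub-stepping.** Within a fluid step, contacts plus the frozen
  hydrodynamic and weight accelerations are integrated with sub-steps
  dt_c = min(dt, 0.1·√(m/k_lin)); the wall gap is linearized over the step
  (particles move ≪ 0.1 mm per fluid step). Sub-step counts above 10⁴ abort.
* **Determinism.** There is no random number generator anywhere in the
  core; identical configurations yield byte-identical outputs, and
  checkpoint/restart reproduces an uninterrupted run to ≤ 1e-8 relative.

## Diagnostics

Per particle and output step (default cadence 0.1 s): position, arc
coordinate s (distance to pylorus), surface means p̄ₙ and τ̄ₙ, and the peak
contact-force magnitude in the interval. Ensemble statistics follow the
standard convention: ⟨τ⟩ and ⟨p⟩ are means over particles of the
per-particle surface means, with min/max envelopes. Summary tables pool all
particle–time samples in the analysis window and report mean, population
standard deviation and max (pooling is a declared convention). Histograms
default to Freedman–Diaconis bins. The transpyloric flux is the face-velocity
integral across the pyloric plane (positive toward the duodenum); emptying
rates are its time average over an integer number of wave periods times the
nominal depth. The analysis window starts at t = 20 s, after the
gravity-driven descent completes. Dominant shuttling periods are estimated
with a detrended Lomb–Scargle periodogram summed over particles, robust for
the few cycles a 1–2 minute run contains.

Region bands by arc coordinate: terminal antrum [0, 20) mm (the distal
~2 cm the TAC collapses), antrum [0, 55), body [55, 80), fundus ≥ 80.

Because surface pressures are gauged to the duodenal outlet their mean sits
near zero, so the across-particle uniformity of pressure (an elliptic
variable) versus the particle-to-particle variability of shear (set by local
flow) is quantified by the instantaneous across-particle envelope width
normalized by each quantity's pooled standard deviation, not by its mean
level.

## Validation battery

Anchored to independent oracles, not to published validation numbers (the
original appendix values are not available in the main text):

* Poiseuille channel (64 cells across): max error < 2% against the exact
  parabola.
* Taylor–Green vortex: kinetic-energy decay within 2% of exp(−4νk²t) at
  128², observed spatial order ≥ 1.8 between 64² and 128².
* Hydrostatic rest and closed-box projection exactness (machine-zero
  velocity).
* Peristaltic channel: travelling occlusions in an open straight tube pump
  net flow in the wave direction.
* Closed deforming lumen (area-preserving pulsating ellipse): prescribed
  wall motion with zero net volume displacement; fluid divergence stays at
  solver tolerance while the wall drives an O(5 mm/s) interior flow.
* Falling disc in a channel: quasi-steady settling speed within 10% of an
  ODE oracle using the Sucker–Brauer circular-cylinder drag correlation with
  a return-flow blockage correction 1/(1 − d/W)² (small blockage, d/W = 0.08
  by default; Re ≈ 12).
* Draft–kiss–tumble: two discs released in tandem (0.4 mm lateral offset to
  break the unstable symmetric equilibrium deterministically) show the
  three-phase signature in order: gap shrinks while the trailing disc is
  faster (draft), contact activates (kiss), then lateral separation grows
  and the pair axis rotates past 45° (tumble).

## Problem sizes used by the test suite

The shipped suite runs the gastric scenario at h = 0.5 mm with shortened
horizons — healthy μ=1 mPa s for 70 s; the liquid-only (no-particles)
comparison for 60 s; hypomotile μ=1 for 45 s; the two μ=10 mPa s runs for
35 s — with all statistics taken from t = 20 s onward. These sizes are the
package's choice of desk-scale study conditions: they span 0.75–2.5 wave periods of
post-descent shuttling, enough to resolve the period, the min-distance
statistics and the paired contrasts, while keeping a full suite run on one
CPU in tens of minutes. Longer horizons (the 120 s default) sharpen the
statistics but change no direction of any comparison we have examined.

## What the synthetic scenario does and does not show

The scenario reproduces, by construction and by measurement: settling of
heavy solids into the antrum in seconds; repeated wave-locked shuttling at
the wave period; trapping in the terminal antrum followed by retropulsive
ejection (healthy); weakened trapping, smaller stresses and weaker contact
forces under hypomotility; higher surface shear at higher viscosity; and
reduced liquid emptying when solids are present.

It does not represent: 3D antral vortical structure and azimuthal particle
motion; patient-specific anatomy; quantitative emptying rates in ml/min at
physiological stomach volumes (the 2D per-depth conversion is nominal);
particle breakdown itself (forces are quantified, erosion is not modelled);
secretion, pH, enzymes, or duodenal feedback. Absolute stress magnitudes
are smaller than in the 3D system because the 2D lumen is thinner, flows
are slower, and depth effects are absent; comparisons between matched runs
(motility, viscosity, with/without solids) are the meaningful outputs.

## Known limitations

* The volume-fraction forcing is first-order at interfaces; particle
  surface stresses carry O(h) error, mitigated but not removed by the
  extrapolated probes.
* The pyloric channel (2 mm rest gap) spans only 4 cells at h = 0.5 mm;
  transpyloric flux is resolved but gap-scale profiles are coarse.
* Loose coupling with virtual-mass stabilization redistributes transient
  impulse between particle and fluid; instantaneous momentum bookkeeping
  closes on the fluid side (forcing + wall impulse) but particle-side
  transients are smoothed.
* The tube signed distance |d| − R(s) is approximate where the centreline
  curvature radius approaches the local half-width (inner bend of the J);
  the error stays below one grid cell in the configurations shipped.
* Very stiff contacts under the collapsing TAC can exceed the 25%-of-radius
  penetration guideline transiently; this is the physical squeeze of
  trapped particles and is flagged by a warning, not an error.
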