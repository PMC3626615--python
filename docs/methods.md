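# Methods

`chimera` simulates a population of single-celled organisms as soft
spheres in a closed cubic tank of fluid, together with the particulate
nutrients they live on. Starting from identical specialist founders
resting on the floor, heritable variation in diet and adhesion lets the
population restructure its own environment: cells broaden their diet,
climb the walls, colonize the top face where nutrients enter, intercept
the inflow, and finally support a floor-dwelling guild of detritivores
feeding on the rain of dead-cell residue. This note documents the model,
the numerical choices, and what the bundled experiments do and do not
show.

## Physical model

Bodies (cells and particles) are point-mass spheres with position `r`,
velocity `v`, mass `m`, radius `R`, integrated by semi-implicit Euler:
the velocity is updated from the total force at the current state and
the position from the *new* velocity,

    v(t+dt) = v(t) + F(t)/m * dt,        r(t+dt) = r(t) + v(t+dt) * dt.

All forces, drag included, are evaluated at the current velocity, so a
free body under drag decays geometrically with per-step ratio
`1 - gamma*dt/m`; the configuration loader rejects any `dt` for which
the drag-limited terminal speed under gravity plus peak noise would move
a body farther than its own radius in one step (at the defaults
`gamma*dt/m = 0.25` for cells, well inside the stable region).

The total force on a cell is

    F = F_env + m g - gamma v + F_contact + F_wall-spring + F_cell-springs ,

and on a particle the same without any adhesion term (particles never
adhere to anything).

**Environmental forcing.** One random vector `sigma * xi` per step,
`xi` i.i.d. uniform on [-1, 1] per component, shared by every body: the
turbulent forcing is spatially homogeneous, deliberately excluding
small-scale eddies. Uniform support keeps the force bounded.

**Contacts.** Interpenetrating pairs (center distance `d` below
`R_i + R_j`) feel a discrete-element force: a linear repulsive spring on
the overlap (`k_spring`), normal damping (`k_damp`), tangential shear
damping (`k_shear`), plus the gradient of a truncated soft-core
potential `U(d) = eps*((R_i+R_j)/d)^n` (defaults `eps = 0.1`, `n = 2`).
The gradient diverges as `d -> 0`, and freshly injected particles can
land almost on top of each other; the gradient is therefore capped at
the full-overlap force of the linear spring, `k_spring*(R_i+R_j)`,
which keeps the deepest overlaps integrable at the chosen step without
affecting ordinary grazing contacts. The force is antisymmetric by
construction, and the integrator records the residual of the summed
internal forces every step as a conservation diagnostic.

**Broad phase.** A uniform voxel grid (voxel edge = the largest
interaction cutoff, 0.175 box units by default) covers the tank;
candidate pairs are drawn from identical or adjacent voxels only, which
is exact for any cutoff up to the voxel size. Two implementations of
the same algorithm exist: a vectorized numpy reference and a compiled
(numba) cell-list used in the inner loop; the test suite holds both to
set-equality against an all-pairs oracle. The grid is rebuilt from
scratch every step.

**Walls.** The tank is closed. A body that interpenetrates a boundary
plane is relocated back to contact and its velocity reversed and scaled
by the restitution factor (default 0.5). The default reverses the full
velocity vector; `physics.bounce_mode: normal` switches to reflecting
only the normal component. Reversal applies only to bodies moving into
the wall, so resting contact does not re-accelerate.

**Adhesion springs.** Cells carry two heritable traits in [0, 1]: wall
adhesion `A_w` and cell-cell adhesion `A_c`. A cell within the
adhesion range of its closest wall attaches a spring (anchor = its
perpendicular projection on that wall, fixed thereafter; one wall
spring per cell) with per-step probability `A_w`. Two unlinked cells
within the attachment range link with probability `A_c(i)*A_c(j)` (the
symmetric product reduces to the single-trait rule when traits are
equal). Both spring kinds are Hookean, detach spontaneously with small
per-step probability, and break deterministically when stretched past
their maximal length (enforced again at the end of every step, so no
overlong spring ever survives a step).

## Ecology and evolution

Each step, `eta` nutrient particles enter at the top face, split evenly
over `n_sources = 4` classes, and fall under gravity. Nutrients degrade
memorylessly at rate `delta` per step, detritus at the strictly slower
`delta_detritus`. Without grazers the per-class count relaxes to the
fixed point of `dN/dt = eta/n_sources - delta*N`, which the
`equilibrium` experiment verifies.

A cell touching a particle of class `k` consumes it only if its
efficiency `e_k > 0`, gaining `e_k * m_p` of mass (linear intake);
otherwise the particle is deflected by contact physics alone. One
particle feeds at most one cell per step — the nearest center wins,
ties broken by lowest cell id. Cells pay a constant maintenance cost
per step; a cell whose mass falls below `m_min` dies, its springs are
destroyed, and `n_detritus = 3` detritus particles are released inside
its former volume. A cell with at least twice the birth mass `m0` and
fewer than `rho_max` cells within the division neighborhood divides:
the daughter starts at `m0` (transferred from the mother, so the
trigger cannot immediately re-fire; `half_split` switches to even
splitting), placed at a uniformly random offset of one to two radii,
clamped inside the tank.

The genome is the efficiency vector over `n_sources + 1` classes (the
last entry is detritus, zero in founders) plus the two adhesion traits.
Each entry of an offspring genome is independently perturbed with
probability `p_mut` by `N(0, sigma_mut^2)`, clipped to [0, 1];
efficiencies are then L1-renormalized. Because floating-point
renormalization cannot make the sum exactly one, the normalized vector
is snapped to a 2^-30 grid (grid multiples and their partial sums are
exact in double precision), so the unit-sum invariant holds
identically; the quantization (< 1e-9) is four orders of magnitude
below `sigma_mut`.

The fixed per-step stage order is: inject -> physics step -> feeding ->
degradation -> maintenance -> death -> division -> metrics. Every
stochastic stage draws from its own named counter-based substream
(physics, ecology, mutation, placement) spawned from the run seed, so a
run is bit-reproducible from `(config, seed)` and adding draws to one
consumer never perturbs another.

## Observables

*Diet entropy* of a cell is the normalized Shannon entropy of its
relative efficiencies, `H = -sum p_k ln p_k / ln C` with `C` the number
of resource classes (detritus included by default; configurable): 0 for
a specialist, 1 for a uniform generalist. *Mean efficiency* is
`sum(e)/n_used = 1/n_used` under the unit-sum constraint. Heights are
normalized so the top face is 0 and the floor -1.

The *top-layer detector* declares the top face occupied when more than
10% of all cells — and at least 10 cells — lie within 0.15 box units
(about two cell radii) of the top face. This is a declared operational
definition: a "presence of a top population" rule, chosen because the
colonizing population also coats the side walls, so a
majority-of-population rule would miss fully colonized tops. A
finished run is classified: **extinction** (no cells at the end),
**EEN** (detector true in at least half of the final-window records),
**multilayer** (occupied vertical span above `layer_k = 2` cell
diameters), else **monolayer**.

## Default parameters (box units; box side = 1)

| parameter | value | why |
|---|---|---|
| dt | 0.05 | largest step passing the displacement-per-step assertion with margin |
| gamma | 5.0 | overdamped regime; velocity relaxation in a few steps |
| g | (0, 0, -2.5) | particles cross the tank in ~80 steps; newly born cells fall slowly enough to attach to walls |
| sigma | 0.5 | moderate stirring (the sweep scans 0.1–0.7; stability bound ~1.0) |
| k_spring / k_damp / k_shear | 50 / 2 / 1 | stiff enough to keep overlaps under ~20% of a radius, `dt*sqrt(k/m) < 1` |
| restitution | 0.5 | inelastic walls |
| cell radius / particle radius | 0.07 / 0.03 | floor monolayer saturates at ~50 cells while the inflow feeds ~200, forcing vertical growth |
| m0 / m_min / m_p | 1 / 0.5 / 0.5 | two full-efficiency particles per division; starvation in 125 steps |
| maintenance | 0.004 per step | sets the starvation clock above |
| eta / n_sources | 6 / 4 | standing crop of a few hundred particles; sweeps scan eta 1–8 |
| delta / delta_detritus | 0.01 / 0.0025 | ~45% of particles reach the floor; detritus persists 4x longer |
| wall spring L0/k/Lmax | 0.07 / 200 / 0.21 | holds a cell's weight against gravity at modest sag |
| cell spring L0/k/Lmax | 0.14 / 100 / 0.28 | rest length = contact distance; supports short hanging chains |
| p_detach (wall / cell) | 0.003 / 0.005 | mean spring lifetimes of ~330 / 200 steps |
| p_mut / sigma_mut | 0.3 / 0.1 | desk-scale evolution: trait sweeps complete within a few thousand steps |
| rho_max / r_neighborhood | 9 / 0.175 | blocks division inside crowded layers, allows it at pile surfaces and on walls |
| founder A_w / A_c | 0.45 / 0.35 | see below |

Founder adhesion deserves a note: with near-zero ancestral adhesion a
newly born cell next to a wall falls faster than it can attach, so wall
climbing cannot bootstrap within desk-scale run lengths regardless of
selection. The founders are therefore given a moderately sticky
ancestral phenotype — attachment within a few steps while in range —
which leaves selection plenty of headroom (in colonizing runs mean wall
adhesion subsequently sweeps toward 0.6–0.9, and in non-colonizing
noisy runs it erodes).

## The bundled experiments and their scales

All study conditions are frozen in `chimera.presets` and sized for a
single desktop CPU; each derives independent per-run seeds from a base
seed through a splittable seed sequence, so any replica is reproducible
in isolation.

- **Grazer-free equilibrium**: cell-free worlds at three (eta, delta)
  settings spanning a decade; time-averaged per-class counts match
  `(eta/n_sources)/delta` within a few percent (the discrete scheme's
  expected count is `(1-delta)` of the continuum value, well inside the
  tolerance at these rates).
- **Phase diagram**: 4 x 4 grid, eta in {1, 3, 6, 8} x sigma in
  {0.1, 0.3, 0.5, 0.7}, 2 replicas, 5000 steps. Starvation at eta = 1
  (founders are class-1 specialists fed by a quarter of a trickle);
  monolayers at eta = 3; multilayers at intermediate inflow; EEN in the
  rich corner. Modal labels over replicas, ties to the less severe
  label.
- **Colonization replicates**: eta = 8, sigma = 0.5, 10000 steps,
  10 seeds.  Colonization typically completes in the first half of the
  run; the remainder covers the slower consolidation of wall adhesion
  and detritivory.  The sequence measured: top-face colonization, rising
  mean height, mean wall adhesion above the founder value, collapse of
  the free-nutrient standing crop below its pre-colonization peak, and
  rising mean detritivore efficiency after colonization.  End-of-run
  levels are final-window means (ten records): subset means over a live
  population fluctuate from record to record, and a windowed mean is the
  natural estimate of the settled level.
- **Transition curve**: eta = 6, sigma in {0.2, 0.5, 0.8}, 10 replicas,
  3500 steps; the fraction of replicas with a colonized top face falls
  with noise, and the replica standard deviation of the 0/1 indicator
  peaks where the fraction is nearest 1/2 — the finite-size fluctuation
  signature of a second-order-like transition.
- **Generalism drift**: a well-fed world (eta = 8, no effective
  division-density limit), 10 seeds, 5000 steps; mean diet entropy
  rises from the founders' zero in essentially every replicate.

## What the synthetic worlds do and do not show

Every experiment runs on worlds generated by the model itself; there is
no external data. Passing tests therefore demonstrate internal
consistency (conservation, containment, exact broad phase, genome
legality, reproducibility) and the *emergent phenomenology* of this
model — they do not calibrate it against any real microbial system.
Real aggregates differ in at least: hydrodynamic interactions and
small-scale eddies (explicitly excluded), cell geometry and rotation
(point-mass spheres, no torques), continuous nutrient fields versus
discrete particles, and regulated development (no gene networks; traits
are three heritable scalars plus a diet vector).

## Numerical choices and degenerate inputs

- Coincident body centers (exactly overlapping spheres) are resolved
  before force evaluation by a deterministic seeded jitter of
  `1e-6 * R` applied to the younger body, and logged as an event.
- The closest-wall query breaks ties by the fixed order floor, ceiling,
  x-, x+, y-, y+ (first minimum wins).
- Division neighbor counts are computed once per step from the post-move
  pair list and mapped by body id across removals; all divisions in a
  step use these frozen counts.
- An empty population is not an error: runs continue with particles
  only, and summary means are recorded as absent (NaN), never zero.
- Non-finite positions or velocities abort the run with an error naming
  the body and step.

## Known limitations

- The snapshot table records bodies only; adhesion springs, cumulative
  counters and RNG state are not serialized, so an exact resume is only
  possible for spring-free worlds (this is tested); resumed evolved
  worlds re-form their springs stochastically.
- Trajectories are bit-reproducible for a fixed package version and
  environment, but not across changes to pair-enumeration order (e.g.
  running without numba), since the consumers of the random streams are
  then visited in a different order.
- At strong noise near the stability bound (sigma ~ 1) bodies remain
  contained but contacts become stiff; the sweep grid stays at or below
  sigma = 0.7–0.9.
- Run lengths are desk-scale (10^3–10^4 steps). The emergent sequence
  completes at the documented conditions; at gentler mutation rates or
  lower founder adhesion the same sequence requires proportionally
  longer runs.
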