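# Model and methods

## The physical picture

A differentiating neuron sprouts neurites only after its cortical
actomyosin shell loosens: cortical tension is a mechanical barrier to
membrane protrusion.  `neuritesim` studies this gate in a minimal
two-dimensional coarse-grained cell with two competing surface
parameters:

* **U3** — the depth of the membrane–actin adhesion well, standing in
  for cortical tension: how strongly the membrane is coupled to the
  actin cytoskeleton underneath it;
* **kappa00** — the elastic (spring) constant of the membrane ring's
  bonds, standing in for membrane tension: how strongly the membrane
  resists changes of its perimeter.

The cell is a closed plasma-membrane ring, a concentric nuclear ring,
and radial actin filaments anchored on the nuclear envelope, each tipped
by a distinct head bead that starts engaged in the adhesion well of the
membrane — the nuclear envelope is mechanically connected to the cell
membrane through the filaments.  The canonical bead budget is 240
membrane + 120 nuclear + 20 filaments x (16 shaft + 1 head) = 700 beads.
The two-dimensional outline matches how this class of cell model is
visualized (contour plots) and keeps one closed ring meaningful at this
bead count.

## Energetics

Reduced units throughout: bead diameter sigma = 1 (length), kT = 1
(energy), friction gamma = 1 (time).  U3 and kappa00 are then
dimensionless and literature values are used verbatim.

| term | form | default |
|---|---|---|
| membrane bonds | FENE tether: stiffness kappa00, max extension 1 sigma | kappa00 = 10 |
| all other bonds | harmonic, E = k/2 (r - r0)^2 | kappa = 500 |
| membrane bending | E = k (1 - cos(theta - theta0)) | kappa_bend_membrane = 50 |
| nuclear bending | same form | kappa_nuclear = 200 |
| filament bending | same form, straight preferred | kappa_filament = 100 |
| filament base joint | same form (soft pivot) | kappa_anchor = 2 |
| excluded volume | WCA, eps = 1, range sigma | all non-bonded pairs |
| membrane–actin adhesion | truncated-shifted LJ, depth U3, range sigma_attr = 0.55, cutoff 2.5 sigma | membrane x head pairs |

Preferred angles and rest lengths are the as-built ones, so a fresh cell
is stress free in every bonded term.  Design choices that matter:

**Membrane tension is stretching, not bending.**  kappa00 is the spring
constant of the membrane bonds: tension is the quantity conjugate to
perimeter, so "resisting deformation" here means resisting perimeter
change.  A stiff ring (kappa00 = 500) is areally inextensible, like a
real bilayer; a soft ring (kappa00 = 10) can feed protrusions by
stretching — and can locally be parted by a filament tip (below).
Bending stiffness exists but is a fixed moderate constant
(kappa_bend_membrane): it sets outline smoothness, not tension.
Membrane bonds are finitely extensible (FENE) tethers — harmonic at
small strain, diverging at one bead diameter of extension — because an
unboundedly stretchable harmonic bond at kappa00 = 10 can be pulled past
any length for a few tens of kT, which is unphysical for a tether and
trips the rupture guard during legitimate adhesive dragging.

**Adhesion is a molecular clutch.**  The adhesion well acts between
membrane beads and filament *head* beads only (the cortex rim; coupling
the membrane to interior shaft beads lets a 2-D ring invaginate and
crumple — a configuration a 3-D membrane sheet cannot reach).  Both the
attractive tail and the repulsive core of the well scale with U3, so the
entire mechanical coupling — stickiness *and* grip — is cortical
tension, and it vanishes as U3 goes to 0.  The well's range
(sigma_attr = 0.55) is substantially narrower than the membrane bead
spacing (~0.98): an engaged tip sits in the notch between two membrane
beads.  Under polymerization load, the tip can escape by parting those
two beads and slipping through the ring; the energetic toll is the
well-exit cost (~2 U3) plus the bond-parting cost, which is trivial for
a soft ring and prohibitive for a stiff one.  This single geometry
yields the clutch phenomenology:

* soft membrane + weak coupling — tips slip through; no force reaches
  the membrane; the cell stays round while bare filaments poke past it;
* soft membrane + intermediate coupling — tips stay engaged and push;
  the stretchy ring supplies perimeter; long stable protrusions;
* soft membrane + strong coupling — the membrane is glued onto the
  cortical cage at every tip; deformation is distributed and small;
* stiff membrane + weak coupling — tips cannot slip (the ring cannot be
  parted) but slide tangentially, cluster, and push localized
  protrusions;
* stiff membrane + strong coupling — every tip is locked in its notch
  and no stretchable slack exists; the outline barely deforms.

The first three bullets are the non-monotonic cortical-tension
dependence at soft membranes; the last two the low-beats-high ordering
at stiff membranes.  `sigma_attr` is one pre-registered geometric
constant, not a per-condition fit: at 0.5 even stiff rings lose their
tips, at 0.6 no tip ever slips, 0.55 sits in the partial-slippage
regime (the calibration scans live outside the package).

## Dynamics

Overdamped (position-)Langevin, first-order Euler–Maruyama:

    x <- x + (F/gamma) dt + sqrt(2 kT dt / gamma) N(0,1)

Cells at this scale are inertia-free; the scheme is isolated behind
`step_overdamped` (NumPy reference) and a compiled kernel
(`run_simulation`), verified equal to 1e-10 against a brute-force
O(n^2) oracle.

**Timestep.**  The stability bound is the stiffest mode — adhesion-well
curvature ~57 U3 / sigma_attr^2, bond springs, or bending ~4 k / l^2.
`suggest_timestep` returns 0.1 gamma / k_max.  The sweep driver
integrates each condition at its own stable timestep while holding the
physical schedule fixed: total simulated time, recorded frame count, and
elongation speed per unit time are identical across conditions, so
conditions differ only in discretization error (halving dt changes
fixture results by < 5%).

**Displacement limiter.**  Per-step displacements are capped at
max(0.1 sigma, six standard deviations of the thermal step).  The cap
never binds in regular dynamics (and provably cannot bias free
diffusion); it only arrests the runaway launch of a bead transiently
driven deep into a repulsive core during a slip event, where the local
curvature exceeds the stable-timestep bound.

**Growth.**  Each step, each filament's terminal (head-adjacent) bond
rest length grows by 0.05 sigma with probability `growth_rate`
(an unloaded elongation speed of ~0.67 sigma per time unit at the
default timestep), capped at a total filament rest length of
`max_filament_length`, and **stalled** while the terminal bond is
compressed by more than `growth_stall_deficit` = 0.2 sigma — i.e. the
polymerization motor has a finite stall force of about
kappa x 0.2 = 100 energy units per length, as real actin does.  Growth
acts on rest lengths, never bead counts: every frame holds exactly
`n_total` beads.

**Guards.**  A run aborts with `NumericalInstabilityError` (step and
bead attached) on non-finite positions, a collapsed bead pair, or any
membrane bond beyond 3x its rest length.  Torn membranes are reported,
never returned; failed sweep replicates are recorded and excluded from
summaries with a logged warning, never silently dropped.

**Determinism.**  All randomness flows from one seeded PCG64 generator
in a fixed draw order; identical parameters give bitwise-identical
trajectories; snapshots carry the serialized generator state and runs
can be resumed exactly from any snapshot.  Replicates use
`seed0 + 10000 * condition + replicate`, so sweeps are pure functions of
their inputs and process-level parallelism reproduces serial results
exactly.

## Morphometrics

The membrane outline (ring order recovered from bond topology, so all
measures are invariant to bead relabeling and rigid motion):

* **projection length** — max over membrane beads of (distance from the
  outline centroid − R_base), floored at 0, with R_base the **median**
  radial distance, so a single long neurite does not inflate its own
  baseline.  This radial-excess definition is this package's
  operationalization of "neurite projection length"; the experiments it
  mirrors do not define one.
* **protrusion count** — maximal contiguous arcs with radial excess
  above a threshold, circular wrap-around handled.
* **circularity** — 4 pi A / P^2 of the outline polygon (shoelace area;
  self-intersecting outlines warn and use |area|).
* **stability** — fraction of the final window of frames (default: last
  25%) still carrying a protrusion above threshold.

Default protrusion threshold is 0.5 R_base; the preset experiments use
an absolute threshold of 2 sigma — clearly beyond thermal outline
roughness at both preset cell sizes.

## The canonical experiments and problem sizes

Two presets (`neuritesim.experiments.protrusion_preset`):

* `"default"` — the 700-bead cell, 40 time units;
* `"reduced"` — a geometrically similar 192-bead cell (96 membrane + 48
  nuclear + 8 filaments x 6), 30 time units, same stiffnesses and
  elongation speed, growth cap scaled to the shorter filaments.  It
  reproduces the same phenomenology at about a tenth of the cost and is
  the size at which the acceptance checks run (10 replicates per
  condition).

The two experiments: `low_vs_high_adhesion_experiment` (U3 = 3 vs 30 at
kappa00 = 500) and `adhesion_sweep_experiment` (five-point geometric U3
grid from 3 to 30 at kappa00 = 10).  `scripts/acceptance.py` recomputes
both from scratch, plus the integrator oracles, and writes the numbers
as JSON; the test suite asserts the orderings at the same reduced size.

## What the model does and does not claim

The synthetic cells reproduce the mechanical logic of neurite
initiation — cortical tension gating protrusion through a
clutch-like membrane-cytoskeleton coupling — not any particular neuron.
Omitted by construction: three-dimensional membrane mechanics, actin
turnover and severing, explicit myosin contractility (folded into U3),
cell-substrate adhesion, microtubule dynamics (a stiff-filament flag
exists, default off), and all biochemistry.  Passing tests show that the
stated parameter dependencies emerge from the stated Hamiltonian; they
do not validate rate constants against living cells.

## Numerical choices at a glance

* Euler–Maruyama, per-condition stable dt (safety 0.1), noise-aware
  displacement cap.
* Verlet neighbour list, skin 1.0 sigma, half-skin rebuild trigger;
  equal to the O(n^2) oracle to 1e-10.
* Compiled (numba) inner loop with fastmath; harmonic bonds ride the
  FENE formula with a huge extension limit, which degenerates to exact
  Hooke's law without a branch.
* Trajectory format: HDF5 without embedded timestamps — byte-identical
  re-writes; lossless round trip asserted in tests.
* Degenerate inputs raise typed errors (`ConfigurationError`,
  `GeometryError`, `NumericalInstabilityError`, ...) rather than
  returning partial results.
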