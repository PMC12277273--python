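# Methods

`fibrilsim` simulates the tensile mechanics of single collagen fibrils as
they mineralize across a ligament-to-bone insertion, using a mesoscopic
(bead–spring) molecular-dynamics model.  This note records the model, its
assumptions, the tunable parameters, and the numerical and design choices
behind the implementation.

## The model

**Collagen.**  A collagen molecule (≈300 nm × 1.6 nm triple helix) is
coarse-grained to a straight chain of 218 beads of 1,316 Da at 13.876 Å
spacing (molecule length 3,011 Å).  Molecules pack on a quasi-hexagonal
lattice (constant 16.52 Å); molecules within a 215 Å diameter — 151 of them
— form the fibril.  Each lattice site carries one of five axial stagger
classes offset by one D-period (682 Å = 400 Å gap + 282 Å overlap), the
Hodge–Petruska arrangement that produces the characteristic gap/overlap
banding.  The cell is periodic along the fibril axis with length
5 D = 3,410 Å; the transverse directions are open (vacuum).  Quoted gap lengths
vary across the literature (360–400 Å); we use the self-consistent set
400 + 282 = 682, 5·682 = 3,410.

**Interactions.**  Total energy is pair + bond + angle:

* Pair: 12-6 Lennard-Jones between all non-bonded bead pairs,
  ε = 6.87 kcal/mol, σ = 14.72 Å for Col–Col; ε = 137.1, σ = 9.88 for
  HAp–HAp; ε = 106.7, σ = 10.28 for Col–HAp.  The published parameter set
  states no cutoff; we use 2.5σ per pair type with the energy shifted to
  zero at the cutoff (standard practice; keeps forces short-ranged).  A
  minimum-distance clamp at 0.5σ guards against pathological overlaps that
  the mineral-placement rejection should already prevent.
* Bond: bilinear (hyperelastic) force law with permanent rupture —
  KT0·(r − r0) below the hyperelastic onset r1, KT1·(r − r̄1) up to the
  breaking distance rb, zero beyond.  r̄1 = r1 − KT0(r1 − r0)/KT1 makes the
  force continuous at r1.  Collagen: r0 14.00, r1 18.20, rb 21.00 Å,
  KT0 17.13, KT1 97.66 kcal/mol/Å².  HAp: 10.00/12.00/14.89 Å,
  200.00/418.40.  Bond energy integrates the force law with E(r0) = 0 and
  plateaus after rupture (energy stays continuous; the stored elastic
  energy is dissipated).  The maximum energy storable on the hyperelastic
  branch, 0.5·KT1·(rb − r̄1)² = 610.8 kcal/mol for collagen, exceeds every
  mineral LJ well (137.1, 106.7 kcal/mol): mineral adhesion detaches before
  the collagen backbone breaks.
* Angle: harmonic KΘ(θ − θ0)² on collagen triplets, KΘ = 14.98
  kcal/mol/rad².  θ0 is taken from the as-built straight geometry (180°);
  molecules carry no built-in kink between gap and overlap regions.

**Hydroxyapatite.**  Mineral enters as bead clusters on a simple-cubic
lattice at 10 Å spacing (the HAp equilibrium bond distance), c-axis along
the fibril.  The HAp bead mass is not part of the published parameter set;
we assign 1,903 Da = 3.16 g/cm³ (HAp crystal density) × (10 Å)³, the mass
of the material volume one bead represents.  Three morphologies:

* gap-zone ellipsoids (long diameter 20–340 Å matched to the gap, short
  20–40 Å), placed with centers in the gap bands;
* intrafibrillar platelets (20–40 × 50–100 × 50–400 Å) lying in lattice
  planes of the hexagonal packing that contain the fibril axis, one of the
  three symmetry-equivalent families chosen uniformly;
* extrafibrillar shell sectors (radial thickness 20–40 Å, arc width
  0–400 Å, axial length 150–1,000 Å) in an annulus starting just outside
  the fibril radius; the annulus is 100 Å deep so shells can stack
  radially at high mineral content.

Candidate beads closer than 8.22 Å (0.8 σ_Col−HAp) to any existing bead are
rejected — minerals therefore conform to the available void space (gap
channels, interstitial planes, the surface).  HAp–HAp bonds connect bead
pairs within 1.2 × the lattice spacing *within one inclusion* (each
inclusion is one crystal; contacting crystals interact through LJ only).
Col–HAp contacts are always nonbonded.

**Mineral volume fraction.**  The measured gradient across the insertion is
linear from 9.4% (ligament, x = 0) to 65.2% (bone, x = 1); `mvf_at_position`
implements exactly this line.  (A commonly quoted mid-gradient value of
22.3% at x = 0.25 sits slightly off the line, which gives 23.35%; we
follow the linear rule.)  On beads,
MVF is computed from per-bead spherical volumes with diameter equal to the
species' equilibrium spacing (14 Å Col, 10 Å HAp):
MVF = V_hap/(V_hap + V_col).  This convention is monotone in bead count and
cheap; alternatives (voxel occupancy) can be swapped behind `compute_mvf`.
Inclusions are placed one at a time until MVF ≥ target, so the overshoot is
at most one inclusion volume.  Kind scheduling keeps the extrafibrillar
bead-volume share near 75% (the measured partition): shells are drawn with
probability 0.75, and a corrective draw is forced when the realized share
drifts more than half the ±5-point tolerance.  Placement failure (200
consecutive fully-rejected inclusions) raises an error naming the achieved
MVF.

## Simulation protocol

Units: kcal/mol, Å, fs, Da; 1 kcal/mol/Å³ = 6.9477 GPa.  Velocity-Verlet
with a 10 fs timestep; Langevin (Ornstein–Uhlenbeck splitting) thermostat
at 300 K with 1,000 fs damping; net momentum re-zeroed periodically.
Neighbor search uses a cell list over the open x/y box and the periodic z
length, with a 3 Å Verlet skin and rebuilds on half-skin displacement.
Directly bonded pairs are excluded from the pair sum; a ruptured bond's
pair re-enters the LJ interaction at the next rebuild.

**Relaxation.**  Two NVT stages: the first couples an axial box-length
proportional controller that drives the mean axial virial stress to zero
(the NPT surrogate — only the axial direction is periodic, so only axial
residual stress matters), the second is plain NVT.  The as-built lattice
stores potential energy (bead spacing 13.876 Å vs r0 = 14.00 Å, and chains
not in LJ registry); it settles within ~10⁴ steps at microfibril scale.
Full runs default to a 1 ns (10⁵ step) relaxation;
desk-scale runs use ~10⁴ steps, after which mineral-free microfibrils sit
below the 20 MPa residual-stress tolerance; heavily mineralized reduced
models can retain a few tens of MPa of residual stress, which the relaxer
reports as a warning rather than an error.

**Tensile deformation.**  Default BOX_STRAIN: the axial cell length grows
at a constant engineering rate with affine remap of z-coordinates each
step — end-velocity loading and longitudinal periodicity cannot both hold
literally, and the affine box strain is the standard reconciliation; an
END_CLAMP mode (end slabs moving at ±v/2, z open) is provided for
single-chain checks.  The default strain rate is 10⁻⁷ per fs (10⁸ s⁻¹),
typical for coarse-grained fibril pulling.  Axial stress is the virial estimator
−(Σ m v_z² + Σ r_z f_z)/V in MPa; the kinetic term (≈1 MPa at 300 K) is
included by default and is configurable (conventions differ on whether
it belongs in the estimator).  Volume is a cylinder: current cell length × πR², with R the
95th-percentile radial bead-center distance from the axial centroid plus a
half-bead margin (σ_Col−Col/2 = 7.36 Å).  The margin matters: bead centers
sit half a bead inside the material boundary, so the bare center percentile
reproduces the quoted 21.5 nm fibril diameter 4% low at full scale but
under-counts the 19-molecule cross-section by ~30%, inflating every stress
by the same factor; with the margin both scales are consistent (110.6 Å vs
the quoted 107.5 at full scale, and the per-molecule area matches the
hexagonal cell area at microfibril scale).  For tensile runs the protocol
freezes the cross-section after relaxation *from the collagen beads alone*
and uses area × current cell length thereafter: a mineral-laden fibril's
enclosing cylinder grows severalfold with extrafibrillar shells, and
normalizing by that moving target would make moduli incomparable across
insertion positions (the collagen reference is also what makes the
modulus's near-invariance to mineral content observable at all).  Both the
percentile, the margin and the reference are configurable
(`fibril_volume`, `collagen_cross_section`, `ProtocolConfig`).

**Property extraction.**  Curves are smoothed by a centered 51-record
moving average (suppresses the few-MPa virial fluctuation without
flattening the yield knee).  Young's modulus: OLS slope over 0–10% strain.
Yield: 1% offset; DROP mode when the curve falls onto the offset line
σ = E(ε − 0.01) (onset of intermolecular sliding), LIFT when it instead
departs *above* the elastic line by the same E·0.01 before the ultimate
point (strain hardening — the hyperelastic bond branch activates before
any sliding), NONE otherwise.  The symmetric LIFT threshold is our
quantification of the qualitative "lift from the elastic curve"
description; the LIFT search starts beyond the 0–10% fit window, because
the OLS modulus averages over early-curve curvature and a departure inside
its own fit window is a fitting artifact, not hardening.  Ultimate point: argmax of the smoothed stress, ties toward
smaller strain.  Each study point runs five replicates (three at reduced
scale) with independent named seed streams for mineral placement, velocity
initialization and the thermostat, and reports min/max/mean plus a
DROP/LIFT/NONE tally.

## Problem sizes and what the desk-scale runs show

The full 151-molecule model (32,918 collagen beads, plus up to ~10⁵ mineral
beads at bone-side MVF, 10⁵ relaxation steps, 4–6·10⁵ pulling steps per
replicate, 25 replicates) is a cluster-scale computation; the package ships
its configuration (`GeometryConfig()` defaults + `ProtocolConfig()`
defaults) but tests and the acceptance script run reduced problems chosen
once:

* **19-molecule microfibril** (4,142 beads, full-length molecules, default
  D-periodic geometry, 10⁴-step relaxation, default strain rate, pulled to
  46%) for the mineral-free modulus and UTS;
* **7-molecule microfibril** with quarter-length molecules (55 beads per
  molecule, all axial lengths scaled by 54/217 so the gap/D ratio, bead
  spacing and stagger are preserved; 385 collagen beads) with a 40× strain
  rate for the five-position gradient-trend study at 3 seeds.  Inclusion
  size ranges for this study are scaled to the reduced geometry (shells
  20–25 × 20–60 × 60–150 Å, and so on): at the published ranges a single
  extrafibrillar shell exceeds the entire ligament-side mineral budget of
  so small a model, which collapses different positions onto the same
  realization and tests nothing.

At these scales the *trends* (UTS rising with mineral content, modulus
insensitive to it, LIFT-mode yields appearing at high MVF) are the
meaningful outputs; absolute stresses carry boundary-molecule softening
and strain-rate elevation, which is why the mineral-free UTS is only
expected within a factor of ~2 of the full-scale value.  Two reduced-scale
artifacts are worth naming.  Periodic-image self-interaction of minerals
(a shell can span a large fraction of the reduced cell) adds variance to
the mineralized trend runs.  And at 40× the production strain rate,
mineral–collagen LJ contacts rearrange dissipatively during the 0–10%
modulus window, so mineralized trend runs fit systematically softer
apparent moduli than the mineral-free position — the full-scale, slow-rate
near-invariance of the modulus to mineral content is *not* recovered at
this scale, and the trend suite documents that as an expected reduced-scale
failure rather than hiding it.

## Numerical details and edge cases

* Collinear angle triplets (θ = 180° = θ0): the transverse force direction
  is undefined and the force magnitude limit is zero; the kernel returns
  zero force there (sin θ clamped at 10⁻⁸ elsewhere).
* Bond rupture is evaluated on the minimum-image distance and is
  irreversible; broken bonds contribute their plateau energy so the total
  energy is continuous at the rupture step.
* The stress plateau tie-break for DROP yield uses the *last* index of a
  stress maximum so that an ideal elastic–perfectly-plastic curve still
  reports its plateau crossing.
* The mineralizer caps sampled inclusion lengths at the gap length
  (ellipsoid long axis) and the cell length (platelet/shell length) so that
  reduced geometries remain meaningful; with default geometry the caps are
  inactive except for the 400 Å gap cap on 340 Å ellipsoids (never
  binding).
* Determinism: every random stage consumes an `numpy` Generator seeded via
  `SeedSequence`; replicate seeds derive from (base seed, position index,
  replicate index).  Fixed seeds reproduce builds, mineral placements,
  trajectories and study summaries bit-for-bit on the same platform.

## Known limitations

* No enzymatic or non-enzymatic cross-links (deliberately excluded to
  isolate the mineral effect); no electrostatics or solvent; no molecular
  kinking between gap and overlap regions.
* The bead chain is taken as given (218 beads × 1,316 Da); deriving it
  from an atomistic structure is upstream of this package.
* The quasi-hexagonal 5-coloring (i + 2j mod 5) balances stagger classes
  to within 3 counts over the 151-site patch; no linear coloring of this
  patch does better than 3.
* Mineral crystallization kinetics are not modeled; only final placements
  matter.
* Desk-scale absolute stresses remain rate- and size-elevated even with
  the bead-margin volume convention (documented above, and reflected in the
  finite-size tolerances of the verification checks).
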