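# fibrilsim

Coarse-grained molecular dynamics of mineralized collagen fibrils across
the ligament-to-bone insertion (enthesis).

The enthesis anchors ligament to bone through a millimeter-scale zone whose
mineral volume fraction (MVF) rises linearly from ≈9.4% on the ligament
side to ≈65.2% on the bone side. `fibrilsim` asks what that gradient does
to the tensile mechanics of the underlying collagen fibrils: it builds a
bead–spring fibril (218-bead molecules on a quasi-hexagonal lattice with
Hodge–Petruska D-staggering), deposits hydroxyapatite bead clusters —
gap-zone ellipsoids, intrafibrillar platelets and extrafibrillar shell
sectors, ≈75% extrafibrillar — until the position-dependent MVF is reached,
runs thermostatted tensile MD, and extracts the mechanical-property
gradient. It is aimed at biomechanics and multiscale-modelling researchers
who want a self-contained, reproducible mesoscale testbed rather than a
hand-assembled LAMMPS workflow.

## Model

Total energy `E = E_pair + E_bond + E_angle`:

* pair (non-bonded): 12-6 Lennard-Jones,
  `E = 4ε[(σ/r)¹² − (σ/r)⁶]`, cutoff 2.5σ, energy-shifted;
* bond: bilinear hyperelastic force law with rupture,
  `F = KT0(r − r0)` for `r < r1`, `KT1(r − r̄1)` for `r1 ≤ r < rb`, 0
  beyond `rb` (permanent), with `r̄1 = r1 − KT0(r1 − r0)/KT1` enforcing
  force continuity;
* angle: harmonic `KΘ(θ − θ0)²` keeping molecules straight.

Stress is the axial virial `σ_zz = −(Σ m v_z² + Σ r_z f_z)/V` over a
cylinder volume of the fibril; properties follow materials-testing
conventions (0–10% modulus fit, 1% offset yield with drop/lift mode
classification, smoothed-peak ultimate point). `docs/methods.md` documents
every parameter, convention and known limitation.

## Worked example

```python
import numpy as np
import fibrilsim as fs

ff = fs.default_forcefield()
bond = ff.bond[("COL", "COL")]
print(f"continuity constant r1bar = {bond.r1bar:.3f} A")
print(f"Col-Col bond rupture energy = {fs.rupture_energy(bond):.1f} kcal/mol")

model = fs.build_fibril(fs.GeometryConfig(n_molecules=151))
print(f"fibril: {model.n_beads} beads, {model.bonds.shape[0]} bonds, "
      f"cell {model.cell_length:.0f} A")

for x in (0.0, 0.5, 1.0):
    print(f"MVF at x={x:.1f}: {fs.mvf_at_position(x):.1%}")

mineral = fs.MineralizationConfig(target_mvf=fs.mvf_at_position(0.0))
small = fs.mineralize(fs.build_fibril(fs.microfibril_preset(7)),
                      mineral, np.random.default_rng(1))
print(f"mineralized microfibril: {small.n_beads} beads, "
      f"achieved MVF {fs.compute_mvf(small):.1%} "
      f"({len(small.inclusion_log)} inclusions)")
```

prints

```
continuity constant r1bar = 17.463 A
Col-Col bond rupture energy = 610.8 kcal/mol
fibril: 32918 beads, 32767 bonds, cell 3410 A
MVF at x=0.0: 9.4%
MVF at x=0.5: 37.3%
MVF at x=1.0: 65.2%
mineralized microfibril: 3757 beads, achieved MVF 34.8% (1 inclusions)
```

The continuity constant and the 610.8 kcal/mol rupture energy come straight
from the published bond parameters; the fibril counts are the closed-form
lattice arithmetic. The last line shows a real property of the placement
model: inclusion sizes are calibrated to the full 151-molecule fibril, so
on a 7-molecule microfibril a single extrafibrillar shell can overshoot the
ligament-side target — mineralization stops at the first state at or above
target, and the inclusion log records exactly what was placed
(`small.inclusion_log`).

A full tensile run is one call:

```python
curve, mvf = fs.run_one_replicate(
    fs.microfibril_preset(19), fs.MineralizationConfig(target_mvf=0.0),
    fs.ProtocolConfig(relax_steps=10_000, max_strain=0.42,
                      record_interval=500), seed=1)
props = fs.extract_properties(curve)
```

which on the mineral-free 19-molecule microfibril yields a Young's modulus
of ≈4.7 GPa and an ultimate strength of ≈0.9 GPa (≈15 min on one core; see
below). The same pipeline is scriptable from the shell:

```sh
fibrilsim build --preset micro7 --mvf 0.094 --seed 1 --out-dir out/
fibrilsim simulate out/fibril_micro7_mvf0.094.data --seed 1 --out-dir out/
fibrilsim analyze out/fibril_micro7_mvf0.094_curve.csv
fibrilsim study --preset micro19 --replicates 5 --seed 1 --out-dir out/
```

The full-scale study configuration (151 molecules, 1 ns relaxation, five
positions × five replicates) is `GeometryConfig()` + `ProtocolConfig()`
defaults driven through `run_insertion_study`; it is a cluster-scale
computation and is not exercised by the test suite.

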