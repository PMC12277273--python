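"""Mineral-free collagen fibril geometry.

A collagen molecule is coarse-grained to a straight chain of 218 beads
(13.876 Å spacing, 3,011 Å long, 1,316 Da per bead).  Molecules sit on a
quasi-hexagonal lattice (constant 16.52 Å) inside a 21.5 nm circle — 151
molecules for the default diameter — and are axially staggered in five
classes separated by one D-period (682 Å = 400 Å gap + 282 Å overlap), the
Hodge–Petruska packing that produces the banded gap/overlap pattern.  The
simulation cell is longitudinally periodic with length 5 D-periods
(3,410 Å); x/y are open (vacuum-padded) directions.

Axis convention: the fibril axis is z; cell z ∈ [0, L) half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .forcefield import COL, HAP, ForceField, default_forcefield

__all__ = [
    "GeometryConfig",
    "FibrilModel",
    "hex_lattice_sites",
    "assign_stagger",
    "build_molecule",
    "build_fibril",
    "microfibril_preset",
    "write_lammps_data",
    "read_lammps_data",
    "write_xyz",
    "SPECIES_COL",
    "SPECIES_HAP",
    "HAP_BEAD_MASS",
]

SPECIES_COL = 0
SPECIES_HAP = 1
SPECIES_NAMES = {SPECIES_COL: COL, SPECIES_HAP: HAP}

#: HAp bead mass (Da): hydroxyapatite density 3.16 g/cm³ times the (10 Å)³
#: volume carried by one bead of the simple-cubic mineral lattice.
HAP_BEAD_MASS = 1903.0

#: x/y vacuum padding for the open directions, as a multiple of σ_Col−Col.
XY_PAD = 3.0 * 14.72


class BuildError(RuntimeError):
    """Raised when the fibril cannot be assembled consistently."""


@dataclass
class GeometryConfig:
    """Structural parameters of the fibril (defaults: full-scale model)."""

    beads_per_molecule: int = 218
    bead_mass: float = 1316.0       # Da
    molecule_length: float = 3011.0  # Å
    gap: float = 400.0               # Å
    overlap: float = 282.0           # Å
    n_periods: int = 5
    lattice_constant: float = 16.52  # Å
    fibril_diameter: float = 215.0   # Å
    n_molecules: int = 0             # expected count; 0 = whatever fits

    @property
    def d_period(self) -> float:
        return self.gap + self.overlap

    @property
    def cell_length(self) -> float:
        return self.n_periods * self.d_period

    @property
    def bead_spacing(self) -> float:
        return self.molecule_length / (self.beads_per_molecule - 1)


@dataclass
class FibrilModel:
    """Bead/bond/angle representation of a (possibly mineralized) fibril.

    ``species`` is 0 for collagen, 1 for hydroxyapatite; ``bond_species``
    likewise labels Col–Col vs HAp–HAp bond laws.  The cell is periodic in
    z only.
    """

    positions: np.ndarray        # (N, 3) Å
    species: np.ndarray          # (N,) int8
    molecule_id: np.ndarray      # (N,) int32; minerals get fresh ids
    masses: np.ndarray           # (N,) Da
    bonds: np.ndarray            # (M, 2) int64
    bond_species: np.ndarray     # (M,) int8
    angles: np.ndarray           # (K, 3) int64
    cell_length: float           # Å, periodic z extent
    fibril_radius: float         # Å, lateral extent of the collagen lattice
    config: Optional[GeometryConfig] = None
    inclusion_log: List[dict] = field(default_factory=list)

    @property
    def n_beads(self) -> int:
        return int(self.positions.shape[0])

    def total_mass(self) -> float:
        return float(self.masses.sum())

    def wrap(self) -> None:
        """Wrap z-coordinates into [0, cell_length). Idempotent."""
        self.positions[:, 2] %= self.cell_length

    def axial_density_profile(self, n_bins: int = 100
                              ) -> Tuple[np.ndarray, np.ndarray]:
        """Histogram of bead z-coordinates over the periodic cell."""
        hist, edges = np.histogram(
            self.positions[:, 2] % self.cell_length,
            bins=n_bins, range=(0.0, self.cell_length))
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers, hist

    def copy(self) -> "FibrilModel":
        return FibrilModel(
            positions=self.positions.copy(),
            species=self.species.copy(),
            molecule_id=self.molecule_id.copy(),
            masses=self.masses.copy(),
            bonds=self.bonds.copy(),
            bond_species=self.bond_species.copy(),
            angles=self.angles.copy(),
            cell_length=self.cell_length,
            fibril_radius=self.fibril_radius,
            config=self.config,
            inclusion_log=list(self.inclusion_log),
        )


def hex_lattice_sites(lattice_constant: float, fibril_diameter: float
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Triangular-lattice sites within fibril_diameter/2 of the axis.

    Returns (xy, ij): site coordinates (n, 2) and their integer lattice
    coordinates (n, 2), sorted by (j, i) for determinism.  The default
    parameters (16.52 Å, 215 Å) admit 151 sites.
    """
    if lattice_constant <= 0 or fibril_diameter <= 0:
        raise ValueError("lattice_constant and fibril_diameter must be > 0")
    a = lattice_constant
    radius = fibril_diameter / 2.0
    m = int(math.ceil(radius / a)) + 2
    ii, jj = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1),
                         indexing="ij")
    x = a * (ii + 0.5 * jj)
    y = a * (math.sqrt(3) / 2.0) * jj
    keep = x * x + y * y <= radius * radius
    ij = np.stack([ii[keep], jj[keep]], axis=1)
    xy = np.stack([x[keep], y[keep]], axis=1)
    order = np.lexsort((ij[:, 0], ij[:, 1]))
    return xy[order], ij[order]


def assign_stagger(ij: np.ndarray) -> np.ndarray:
    """Stagger class in {0..4} for integer lattice coordinates (i, j).

    Uses the 5-coloring class = (i + 2j) mod 5, under which any five
    consecutive sites along a lattice row carry all five classes — the
    Hodge–Petruska-compatible quasi-hexagonal stagger.  The axial offset of
    a molecule is class · D-period (modulo the cell length).
    """
    ij = np.atleast_2d(np.asarray(ij, dtype=int))
    return (ij[:, 0] + 2 * ij[:, 1]) % 5


def build_molecule(config: GeometryConfig, axial_offset: float,
                   lattice_site: np.ndarray) -> np.ndarray:
    """Straight bead chain along z at a lattice site.

    Beads are uniformly spaced by molecule_length/(N−1), start at
    axial_offset, and are wrapped into the periodic cell.
    """
    n = config.beads_per_molecule
    z = (axial_offset + config.bead_spacing * np.arange(n)) % config.cell_length
    pos = np.empty((n, 3))
    pos[:, 0] = lattice_site[0]
    pos[:, 1] = lattice_site[1]
    pos[:, 2] = z
    return pos


def build_fibril(config: Optional[GeometryConfig] = None) -> FibrilModel:
    """Assemble the mineral-free fibril from the configuration.

    The default configuration yields 151 molecules × 218 beads = 32,918
    beads, 151·217 bonds, 151·216 angles in a 3,410 Å periodic cell.
    """
    config = config or GeometryConfig()
    xy, ij = hex_lattice_sites(config.lattice_constant, config.fibril_diameter)
    n_mol = xy.shape[0]
    if config.n_molecules and n_mol != config.n_molecules:
        raise BuildError(
            f"lattice admits {n_mol} molecules, expected {config.n_molecules}")
    # overlap rejection: no two molecules may share a lattice site
    if n_mol > 1:
        d2 = ((xy[None, :, :] - xy[:, None, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        if d2.min() < (0.5 * config.lattice_constant) ** 2:
            raise BuildError("two molecules closer than half a lattice constant")

    classes = assign_stagger(ij)
    offsets = (classes * config.d_period) % config.cell_length

    nb = config.beads_per_molecule
    pos = np.empty((n_mol * nb, 3))
    mol_id = np.empty(n_mol * nb, dtype=np.int32)
    for m in range(n_mol):
        pos[m * nb:(m + 1) * nb] = build_molecule(config, offsets[m], xy[m])
        mol_id[m * nb:(m + 1) * nb] = m
    base = np.arange(n_mol)[:, None] * nb
    intra = np.arange(nb - 1)[None, :]
    bonds = np.stack([(base + intra).ravel(),
                      (base + intra + 1).ravel()], axis=1).astype(np.int64)
    intra3 = np.arange(nb - 2)[None, :]
    angles = np.stack([(base + intra3).ravel(),
                       (base + intra3 + 1).ravel(),
                       (base + intra3 + 2).ravel()], axis=1).astype(np.int64)

    model = FibrilModel(
        positions=pos,
        species=np.zeros(n_mol * nb, dtype=np.int8),
        molecule_id=mol_id,
        masses=np.full(n_mol * nb, config.bead_mass),
        bonds=bonds,
        bond_species=np.zeros(bonds.shape[0], dtype=np.int8),
        angles=angles,
        cell_length=config.cell_length,
        fibril_radius=float(np.hypot(xy[:, 0], xy[:, 1]).max()
                            + 0.5 * config.lattice_constant),
        config=config,
    )
    model.wrap()
    return model


#: molecule counts of complete hexagonal neighbor shells and the lattice
#: radius (in units of the lattice constant) that encloses them.
_SHELL_RADIUS = {7: 1.0, 19: 2.0, 37: 3.0}


def microfibril_preset(n_molecules: int, n_periods: int = 5,
                       beads_per_molecule: int = 218) -> GeometryConfig:
    """Reduced configuration for desk-scale runs.

    ``n_molecules`` must be a complete hexagonal shell count (7, 19, 37).
    Shorter molecules (``beads_per_molecule`` < 218) scale all axial lengths
    (molecule length, gap, overlap, hence D-period) by (N−1)/217 so the bead
    spacing, gap/D ratio and stagger scheme of the full model are preserved.
    """
    if n_molecules not in _SHELL_RADIUS:
        raise ValueError(f"n_molecules must be one of {sorted(_SHELL_RADIUS)}")
    full = GeometryConfig()
    scale = (beads_per_molecule - 1) / (full.beads_per_molecule - 1)
    diameter = 2.0 * _SHELL_RADIUS[n_molecules] * full.lattice_constant * 1.001
    return replace(
        full,
        beads_per_molecule=beads_per_molecule,
        molecule_length=full.molecule_length * scale,
        gap=full.gap * scale,
        overlap=full.overlap * scale,
        n_periods=n_periods,
        fibril_diameter=diameter,
        n_molecules=n_molecules,
    )


# ---------------------------------------------------------------------------
# LAMMPS data / XYZ export
# ---------------------------------------------------------------------------

def _xy_bounds(model: FibrilModel) -> Tuple[float, float, float, float]:
    xlo = model.positions[:, 0].min() - XY_PAD
    xhi = model.positions[:, 0].max() + XY_PAD
    ylo = model.positions[:, 1].min() - XY_PAD
    yhi = model.positions[:, 1].max() + XY_PAD
    return xlo, xhi, ylo, yhi


def write_lammps_data(model: FibrilModel, path,
                      forcefield: Optional[ForceField] = None) -> None:
    """LAMMPS data file, atom style *molecular*.

    Column layout: ``Atoms`` lines are ``id mol type x y z`` (types: 1 = COL,
    2 = HAP); ``Bonds`` are ``id type i j`` (types: 1 = Col–Col, 2 =
    HAp–HAp); ``Angles`` are ``id type i j k``; indices are 1-based.
    ``PairIJ Coeffs`` carries ε, σ and the cutoff of each species pair.
    """
    ff = forcefield or default_forcefield()
    xlo, xhi, ylo, yhi = _xy_bounds(model)
    col_mass = model.config.bead_mass if model.config else 1316.0
    has_col = np.any(model.species == SPECIES_COL)
    if has_col:
        col_mass = float(model.masses[model.species == SPECIES_COL][0])
    hap_mass = HAP_BEAD_MASS
    if np.any(model.species == SPECIES_HAP):
        hap_mass = float(model.masses[model.species == SPECIES_HAP][0])
    lines = ["fibrilsim LAMMPS data (atom style: molecular)", ""]
    lines.append(f"{model.n_beads} atoms")
    lines.append(f"{model.bonds.shape[0]} bonds")
    lines.append(f"{model.angles.shape[0]} angles")
    lines.append("2 atom types")
    lines.append("2 bond types")
    lines.append("1 angle types")
    lines.append("")
    lines.append(f"{xlo:.6f} {xhi:.6f} xlo xhi")
    lines.append(f"{ylo:.6f} {yhi:.6f} ylo yhi")
    lines.append(f"0.000000 {model.cell_length:.6f} zlo zhi")
    lines.append("")
    lines.append("Masses")
    lines.append("")
    lines.append(f"1 {col_mass:.4f}")
    lines.append(f"2 {hap_mass:.4f}")
    lines.append("")
    lines.append("PairIJ Coeffs # epsilon sigma cutoff")
    lines.append("")
    order = [((COL, COL), 1, 1), ((COL, HAP), 1, 2), ((HAP, HAP), 2, 2)]
    for key, t1, t2 in order:
        p = ff.pair[key]
        lines.append(f"{t1} {t2} {p.epsilon:.4f} {p.sigma:.4f} {p.cutoff:.4f}")
    lines.append("")
    lines.append("Atoms # molecular")
    lines.append("")
    for i in range(model.n_beads):
        x, y, z = model.positions[i]
        lines.append(f"{i + 1} {model.molecule_id[i] + 1} "
                     f"{int(model.species[i]) + 1} "
                     f"{x:.6f} {y:.6f} {z:.6f}")
    if model.bonds.shape[0]:
        lines.append("")
        lines.append("Bonds")
        lines.append("")
        for n, (i, j) in enumerate(model.bonds):
            lines.append(f"{n + 1} {int(model.bond_species[n]) + 1} "
                         f"{i + 1} {j + 1}")
    if model.angles.shape[0]:
        lines.append("")
        lines.append("Angles")
        lines.append("")
        for n, (i, j, k) in enumerate(model.angles):
            lines.append(f"{n + 1} 1 {i + 1} {j + 1} {k + 1}")
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_lammps_data(path) -> FibrilModel:
    """Round-trip reader for :func:`write_lammps_data` output."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    counts = {}
    zhi = None
    masses = {}
    section = None
    atoms, bonds, angles = [], [], []
    for line in raw[1:]:
        stripped = line.split("#")[0].strip()
        if not stripped:
            continue
        parts = stripped.split()
        if parts[-1] in ("atoms", "bonds", "angles") and len(parts) == 2:
            counts[parts[-1]] = int(parts[0])
            continue
        if stripped.endswith("types"):
            continue
        if stripped.endswith("zlo zhi"):
            zhi = float(parts[1])
            continue
        if stripped.endswith(("xlo xhi", "ylo yhi")):
            continue
        if parts[0] in ("Masses", "Atoms", "Bonds", "Angles", "PairIJ"):
            section = parts[0]
            continue
        if section == "Masses":
            masses[int(parts[0])] = float(parts[1])
        elif section == "Atoms":
            atoms.append((int(parts[0]), int(parts[1]), int(parts[2]),
                          float(parts[3]), float(parts[4]), float(parts[5])))
        elif section == "Bonds":
            bonds.append((int(parts[1]), int(parts[2]), int(parts[3])))
        elif section == "Angles":
            angles.append((int(parts[2]), int(parts[3]), int(parts[4])))
    atoms.sort(key=lambda t: t[0])
    pos = np.array([[a[3], a[4], a[5]] for a in atoms])
    species = np.array([a[2] - 1 for a in atoms], dtype=np.int8)
    mol_id = np.array([a[1] - 1 for a in atoms], dtype=np.int32)
    mass_arr = np.array([masses[a[2]] for a in atoms])
    bond_arr = (np.array([[b[1], b[2]] for b in bonds], dtype=np.int64) - 1
                if bonds else np.empty((0, 2), dtype=np.int64))
    bond_sp = (np.array([b[0] - 1 for b in bonds], dtype=np.int8)
               if bonds else np.empty(0, dtype=np.int8))
    ang_arr = (np.array(angles, dtype=np.int64) - 1
               if angles else np.empty((0, 3), dtype=np.int64))
    col = species == SPECIES_COL
    radius = float(np.hypot(pos[col, 0], pos[col, 1]).max()) if col.any() else 0.0
    return FibrilModel(
        positions=pos, species=species, molecule_id=mol_id, masses=mass_arr,
        bonds=bond_arr, bond_species=bond_sp, angles=ang_arr,
        cell_length=float(zhi), fibril_radius=radius)


def write_xyz(model: FibrilModel, path, comment: str = "fibrilsim") -> None:
    """Minimal XYZ export (element column: C for collagen, P for mineral)."""
    with open(path, "w") as fh:
        fh.write(f"{model.n_beads}\n{comment}\n")
        for i in range(model.n_beads):
            el = "C" if model.species[i] == SPECIES_COL else "P"
            x, y, z = model.positions[i]
            fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")
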