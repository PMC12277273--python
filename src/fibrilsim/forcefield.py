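"""Mesoscopic force field for mineralized collagen fibrils.

Three interaction classes act between beads:

* **Pair (Lennard-Jones)** — radial cohesion between non-bonded beads,
  ``E = 4ε[(σ/r)¹² − (σ/r)⁶]``, evaluated with a 2.5σ cutoff and shifted so
  the energy vanishes at the cutoff.
* **Bond (piecewise hyperelastic)** — axial stretching between consecutive
  beads of a molecule/crystal.  The *force* law is bilinear with a breaking
  distance::

      F(r) = KT0·(r − r0)        r <  r1
           = KT1·(r − r̄1)       r1 ≤ r < rb
           = 0                   r ≥ rb   (bond permanently broken)

  where r̄1 = r1 − KT0·(r1 − r0)/KT1 enforces force continuity at r1.
* **Angle (harmonic)** — ``E = KΘ·(θ − θ0)²`` on bead triplets of collagen
  molecules, keeping chains straight (θ0 = 180° for the as-built geometry).

Default parameters are the published mesoscopic collagen and hydroxyapatite
values (collagen: r0 14.00 Å, r1 18.20 Å, rb 21.00 Å, KT0 17.13,
KT1 97.66 kcal/mol/Å², ε 6.87 kcal/mol, σ 14.72 Å; HAp: r0 10.00 Å,
r1 12.00 Å, rb 14.89 Å, KT0 200.00, KT1 418.40, ε_HAp−HAp 137.1,
σ_HAp−HAp 9.88 Å, ε_Col−HAp 106.7, σ_Col−HAp 10.28 Å).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

import numpy as np
import yaml

__all__ = [
    "PairParams",
    "BondParams",
    "AngleParams",
    "ForceField",
    "derive_r1bar",
    "bond_force",
    "bond_energy",
    "rupture_energy",
    "lj_energy",
    "lj_force",
    "angle_energy",
    "angle_forces",
    "default_forcefield",
    "COL",
    "HAP",
]

COL = "COL"
HAP = "HAP"

#: LJ cutoff as a multiple of sigma (energy shifted to zero there).
CUTOFF_FACTOR = 2.5
#: minimum-distance clamp as a multiple of sigma (safety net for bad overlaps)
MIN_DIST_FACTOR = 0.5


class InvalidParameters(ValueError):
    """Raised for physically inconsistent force-field parameters."""


@dataclass
class PairParams:
    """12-6 Lennard-Jones parameters for one species pair."""

    epsilon: float  # kcal/mol, well depth
    sigma: float    # Å, zero-crossing distance
    cutoff: float = 0.0  # Å; 0 -> CUTOFF_FACTOR * sigma

    def __post_init__(self) -> None:
        if self.cutoff == 0.0:
            self.cutoff = CUTOFF_FACTOR * self.sigma
        if self.epsilon <= 0 or self.sigma <= 0 or self.cutoff <= self.sigma:
            raise InvalidParameters(f"bad LJ parameters: {self}")

    @property
    def shift(self) -> float:
        """Energy at the cutoff, subtracted so E(cutoff) = 0."""
        s6 = (self.sigma / self.cutoff) ** 6
        return 4.0 * self.epsilon * (s6 * s6 - s6)


@dataclass
class BondParams:
    """Piecewise hyperelastic bond law with breaking distance."""

    r0: float    # Å, equilibrium distance
    r1: float    # Å, hyperelastic onset
    rb: float    # Å, breaking distance
    kt0: float   # kcal/mol/Å², harmonic branch stiffness
    kt1: float   # kcal/mol/Å², hyperelastic branch stiffness
    r1bar: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.r0 < self.r1 < self.rb):
            raise InvalidParameters("require r0 < r1 < rb")
        self.r1bar = derive_r1bar(self)


@dataclass
class AngleParams:
    """Harmonic bending law; theta0 in degrees."""

    ktheta: float  # kcal/mol/rad²
    theta0: float = 180.0  # degrees

    @property
    def theta0_rad(self) -> float:
        return math.radians(self.theta0)


def derive_r1bar(bond: BondParams) -> float:
    """Constant of the hyperelastic branch enforcing force continuity at r1.

    Solves KT0·(r1 − r0) = KT1·(r1 − r̄1) for r̄1.
    """
    if bond.kt1 == 0:
        raise InvalidParameters("KT1 must be nonzero")
    return bond.r1 - bond.kt0 * (bond.r1 - bond.r0) / bond.kt1


def bond_force(r, bond: BondParams):
    """Signed bond force magnitude (positive = restoring toward r0) at r.

    Returns KT0·(r−r0) below r1, KT1·(r−r̄1) between r1 and rb, and zero at
    or beyond rb (broken).  Permanent rupture bookkeeping lives in the engine.
    """
    r = np.asarray(r, dtype=float)
    f = np.where(
        r < bond.r1,
        bond.kt0 * (r - bond.r0),
        bond.kt1 * (r - bond.r1bar),
    )
    return np.where(r >= bond.rb, 0.0, f)


def bond_energy(r, bond: BondParams):
    """Bond energy: piecewise integral of the force law with E(r0) = 0.

    Continuous at r1 and constant for r ≥ rb (the stored elastic energy is
    dissipated at rupture; the plateau keeps the total energy continuous).
    """
    r = np.asarray(r, dtype=float)
    e_harm = 0.5 * bond.kt0 * (r - bond.r0) ** 2
    e_r1 = 0.5 * bond.kt0 * (bond.r1 - bond.r0) ** 2
    e_hyper = e_r1 + 0.5 * bond.kt1 * (
        (r - bond.r1bar) ** 2 - (bond.r1 - bond.r1bar) ** 2
    )
    e_rb = e_r1 + 0.5 * bond.kt1 * (
        (bond.rb - bond.r1bar) ** 2 - (bond.r1 - bond.r1bar) ** 2
    )
    e = np.where(r < bond.r1, e_harm, e_hyper)
    return np.where(r >= bond.rb, e_rb, e)


def rupture_energy(bond: BondParams) -> float:
    """Maximum elastic energy storable on the hyperelastic branch.

    Evaluated as 0.5·KT1·(rb − r̄1)² — the stored energy of the hyperelastic
    spring at the breaking distance.
    """
    return 0.5 * bond.kt1 * (bond.rb - bond.r1bar) ** 2


def lj_energy(r, pair: PairParams, shifted: bool = False):
    """12-6 LJ energy; zero beyond the cutoff; clamped below 0.5σ."""
    r = np.asarray(r, dtype=float)
    rc = np.clip(r, MIN_DIST_FACTOR * pair.sigma, None)
    s6 = (pair.sigma / rc) ** 6
    e = 4.0 * pair.epsilon * (s6 * s6 - s6)
    if shifted:
        e = e - pair.shift
    return np.where(r >= pair.cutoff, 0.0, e)


def lj_force(r, pair: PairParams):
    """Radial LJ force magnitude −dE/dr (positive = repulsive); 0 past cutoff."""
    r = np.asarray(r, dtype=float)
    rc = np.clip(r, MIN_DIST_FACTOR * pair.sigma, None)
    s6 = (pair.sigma / rc) ** 6
    f = 4.0 * pair.epsilon * (12.0 * s6 * s6 - 6.0 * s6) / rc
    return np.where(r >= pair.cutoff, 0.0, f)


def angle_energy(theta, params: AngleParams):
    """Harmonic bending energy KΘ(θ − θ0)²; theta in radians."""
    theta = np.asarray(theta, dtype=float)
    return params.ktheta * (theta - params.theta0_rad) ** 2


def angle_forces(r1: np.ndarray, r2: np.ndarray, r3: np.ndarray,
                 params: AngleParams) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic forces of the harmonic angle on the triplet (end, apex, end).

    Forces sum to zero; the collinear limit (θ → 180°, sinθ → 0) is handled
    by the finite limit of (θ − θ0)/sinθ for θ0 = 180° and by a sinθ clamp
    otherwise.
    """
    u = np.asarray(r1, float) - np.asarray(r2, float)
    v = np.asarray(r3, float) - np.asarray(r2, float)
    lu = np.linalg.norm(u)
    lv = np.linalg.norm(v)
    uh, vh = u / lu, v / lv
    c = float(np.clip(np.dot(uh, vh), -1.0, 1.0))
    theta = math.acos(c)
    s = math.sqrt(max(1.0 - c * c, 0.0))
    dtheta = theta - params.theta0_rad
    if s < 1e-8:
        # collinear: for theta0 = pi the prefactor tends to 2K; transverse
        # direction is undefined, so the limit force is zero.
        return (np.zeros(3), np.zeros(3), np.zeros(3))
    pref = 2.0 * params.ktheta * dtheta / s  # dE/dθ / sinθ
    f1 = pref * (vh - c * uh) / lu
    f3 = pref * (uh - c * vh) / lv
    f2 = -(f1 + f3)
    return f1, f2, f3


@dataclass
class ForceField:
    """Full interaction table: pair (LJ), bond and angle laws by species."""

    pair: Dict[Tuple[str, str], PairParams]
    bond: Dict[Tuple[str, str], BondParams]
    angle: Dict[str, AngleParams]

    def pair_for(self, a: str, b: str) -> PairParams:
        return self.pair[tuple(sorted((a, b)))]

    def bond_for(self, a: str, b: str) -> BondParams:
        return self.bond[tuple(sorted((a, b)))]

    # -- serialization (keys mirror the published parameter tables) ---------
    def to_yaml(self, path) -> None:
        doc = {
            "pair": {
                "-".join(k): {"epsilon": p.epsilon, "sigma": p.sigma,
                              "cutoff": p.cutoff}
                for k, p in self.pair.items()
            },
            "bond": {
                "-".join(k): {"r0": b.r0, "r1": b.r1, "rb": b.rb,
                              "KT0": b.kt0, "KT1": b.kt1}
                for k, b in self.bond.items()
            },
            "angle": {
                k: {"ktheta": a.ktheta, "theta0": a.theta0}
                for k, a in self.angle.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ForceField":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        pair = {
            tuple(k.split("-")): PairParams(v["epsilon"], v["sigma"],
                                            v.get("cutoff", 0.0))
            for k, v in doc["pair"].items()
        }
        bond = {
            tuple(k.split("-")): BondParams(v["r0"], v["r1"], v["rb"],
                                            v["KT0"], v["KT1"])
            for k, v in doc["bond"].items()
        }
        angle = {k: AngleParams(v["ktheta"], v["theta0"])
                 for k, v in doc["angle"].items()}
        return cls(pair=pair, bond=bond, angle=angle)


def default_forcefield() -> ForceField:
    """Published mesoscopic collagen + hydroxyapatite parameter set."""
    return ForceField(
        pair={
            (COL, COL): PairParams(epsilon=6.87, sigma=14.72),
            (HAP, HAP): PairParams(epsilon=137.1, sigma=9.88),
            (COL, HAP): PairParams(epsilon=106.7, sigma=10.28),
        },
        bond={
            (COL, COL): BondParams(r0=14.00, r1=18.20, rb=21.00,
                                   kt0=17.13, kt1=97.66),
            (HAP, HAP): BondParams(r0=10.00, r1=12.00, rb=14.89,
                                   kt0=200.00, kt1=418.40),
        },
        angle={COL: AngleParams(ktheta=14.98, theta0=180.0)},
    )
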