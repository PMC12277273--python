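"""Shared fixtures: force field, reduced fibril models, force oracle.

The brute-force oracle evaluates all O(N²) pair interactions plus bonds and
angles directly through the reference (non-kernel) force-field functions;
it is the independent check for the engine's neighbor-listed kernels.
"""

import math

import numpy as np
import pytest

import fibrilsim as fs
from fibrilsim import forcefield as ffm
from fibrilsim.engine import ForceTables, NeighborList, SimulationState


@pytest.fixture(scope="session")
def ff():
    return fs.default_forcefield()


@pytest.fixture(scope="session")
def tables(ff):
    return ForceTables(ff)


@pytest.fixture(scope="session")
def micro7():
    """7-molecule microfibril, full-length molecules."""
    return fs.build_fibril(fs.microfibril_preset(7))


@pytest.fixture(scope="session")
def micro7_short_config():
    """7 molecules with quarter-length molecules: desk-scale dynamics."""
    return fs.microfibril_preset(7, beads_per_molecule=55)


@pytest.fixture(scope="session")
def micro7_short(micro7_short_config):
    return fs.build_fibril(micro7_short_config)


def random_mixed_state(n=80, box=90.0, seed=0):
    """Random collagen/HAp bead soup with a few bonds and one angle."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(5, box - 5, (n, 3))
    pos[:, 2] = rng.uniform(0, box, n)
    species = (rng.uniform(size=n) < 0.3).astype(np.int8)
    bonds = np.array([[0, 1], [2, 3], [4, 5]], dtype=np.int64)
    species[[0, 1, 2, 3]] = 0
    species[[4, 5]] = 1
    bond_sp = np.array([0, 0, 1], dtype=np.int8)
    angles = np.array([[0, 1, 2]], dtype=np.int64)
    masses = np.where(species == 0, 1316.0, 1903.0)
    return SimulationState(
        positions=pos, velocities=np.zeros((n, 3)), masses=masses,
        species=species, bonds=bonds, bond_species=bond_sp,
        broken=np.zeros(3, dtype=np.bool_), angles=angles, cell_length=box)


def brute_force_oracle(state, ff):
    """All-pairs reference forces/energy, independent of the engine kernels."""
    n = state.n_beads
    lz = state.cell_length
    names = {0: "COL", 1: "HAP"}
    F = np.zeros((n, 3))
    E = 0.0
    bondset = {(min(i, j), max(i, j)) for i, j in state.bonds}
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in bondset:
                continue
            d = state.positions[i] - state.positions[j]
            d[2] -= lz * np.round(d[2] / lz)
            r = float(np.linalg.norm(d))
            p = ff.pair_for(names[state.species[i]], names[state.species[j]])
            if r >= p.cutoff:
                continue
            E += float(ffm.lj_energy(r, p, shifted=True))
            fmag = float(ffm.lj_force(r, p))
            F[i] += fmag * d / r
            F[j] -= fmag * d / r
    for (i, j), t in zip(state.bonds, state.bond_species):
        d = state.positions[i] - state.positions[j]
        d[2] -= lz * np.round(d[2] / lz)
        r = float(np.linalg.norm(d))
        b = ff.bond[("COL", "COL") if t == 0 else ("HAP", "HAP")]
        E += float(ffm.bond_energy(r, b))
        fm = float(ffm.bond_force(r, b))
        F[i] -= fm * d / r
        F[j] += fm * d / r
    for (i, j, k) in state.angles:
        r1, r2, r3 = state.positions[[i, j, k]]
        u = r1 - r2
        u[2] -= lz * np.round(u[2] / lz)
        v = r3 - r2
        v[2] -= lz * np.round(v[2] / lz)
        f1, f2, f3 = ffm.angle_forces(r2 + u, r2, r2 + v, ff.angle["COL"])
        F[i] += f1
        F[j] += f2
        F[k] += f3
        c = float(np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v))
        E += float(ffm.angle_energy(math.acos(np.clip(c, -1, 1)),
                                    ff.angle["COL"]))
    return F, E
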