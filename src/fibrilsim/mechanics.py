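"""Mechanical-property extraction and the insertion study driver.

From each tensile stress–strain record five scalar properties are
extracted, following standard materials-testing conventions adapted to the
fluctuating MD signal:

* **Young's modulus** — least-squares slope of stress vs strain restricted
  to the 0–10% strain window.
* **Yield point (1% offset)** — intersection of the smoothed curve with the
  elastic line shifted by 1% strain.  Two modes: *DROP* (the curve falls to
  the offset line — onset of intermolecular sliding) and *LIFT* (no drop
  occurs; the curve instead departs *above* the elastic line by the same
  offset — strain hardening activating the hyperelastic bond branch before
  any sliding).  *NONE* if neither occurs.
* **Ultimate point** — peak of the smoothed curve (collective sliding).

Curves are moving-average smoothed (default 51 records) before extraction
to suppress the few-MPa virial fluctuation.  Each study point is replicated
over independent seeds (default 5) and summarized by min/max/mean plus a
yield-mode tally.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import (ProtocolConfig, SimulationState, ForceTables,
                     NeighborList, collagen_cross_section, relax,
                     tensile_run)
from .forcefield import ForceField, default_forcefield
from .geometry import GeometryConfig, build_fibril
from .mineralization import (MineralizationConfig, compute_mvf,
                             mineralize, mvf_at_position)

__all__ = [
    "MechanicalProperties",
    "StudyResult",
    "smooth_curve",
    "youngs_modulus",
    "yield_point",
    "ultimate_point",
    "extract_properties",
    "aggregate_replicates",
    "run_insertion_study",
    "plot_study",
    "plot_curves",
    "DROP",
    "LIFT",
    "NONE",
]

DROP = "DROP"
LIFT = "LIFT"
NONE = "NONE"

PROPERTY_FIELDS = ("youngs_modulus", "yield_strain", "yield_stress",
                   "ultimate_strain", "ultimate_stress")


@dataclass
class MechanicalProperties:
    """The five tensile properties of one run (MPa / strain fractions)."""

    youngs_modulus: float
    yield_strain: float
    yield_stress: float
    ultimate_strain: float
    ultimate_stress: float
    yield_mode: str = NONE


def smooth_curve(curve: pd.DataFrame, window: int = 51) -> pd.DataFrame:
    """Centered moving average of the stress column on the same strain grid."""
    if len(curve) < window:
        raise ValueError(
            f"curve has {len(curve)} points, smoothing window is {window}")
    out = curve.copy()
    out["stress_MPa"] = (curve["stress_MPa"]
                         .rolling(window, center=True, min_periods=1)
                         .mean())
    return out


def youngs_modulus(curve: pd.DataFrame, strain_window: float = 0.10
                   ) -> float:
    """OLS slope (MPa) of stress vs strain over [0, strain_window]."""
    mask = curve["strain"] <= strain_window
    if mask.sum() < 2 or curve["strain"][mask].max() < 0.5 * strain_window:
        raise ValueError("curve does not span the modulus strain window")
    slope, _ = np.polyfit(curve["strain"][mask], curve["stress_MPa"][mask], 1)
    return float(slope)


def _first_crossing(x: np.ndarray, y: np.ndarray) -> Optional[int]:
    """Index of the first sign change of y from > 0 to <= 0."""
    above = y > 0
    for k in range(1, len(y)):
        if above[k - 1] and not above[k]:
            return k
    return None


def yield_point(curve: pd.DataFrame, modulus: Optional[float] = None,
                offset: float = 0.01, lift_from: float = 0.10):
    """1%-offset yield point: (strain, stress, mode).

    DROP: first intersection where the curve falls onto the offset line
    σ = E·(ε − offset) from above.  LIFT: if no drop occurs before the
    ultimate point, the first strain where the curve exceeds the elastic
    line σ = E·ε by E·offset — searched only beyond the elastic fit window
    (``lift_from``), since inside the window the fitted slope averages over
    any curvature and a departure there is a fitting artifact, not strain
    hardening.  NONE otherwise.
    """
    strain = curve["strain"].to_numpy()
    stress = curve["stress_MPa"].to_numpy()
    if np.any(np.diff(strain) < 0):
        raise ValueError("strain must be non-decreasing")
    e = modulus if modulus is not None else youngs_modulus(curve)
    # guard: a DROP crossing must occur no later than the ultimate point;
    # ties on a stress plateau resolve to the plateau's end so that a
    # perfectly plastic plateau still yields
    ult_idx = len(stress) - 1 - int(np.argmax(stress[::-1]))
    # DROP: consider the region beyond the offset construction
    region = strain > offset
    diff = stress - e * (strain - offset)
    ridx = np.where(region)[0]
    k = _first_crossing(strain[ridx], diff[ridx])
    if k is not None and ridx[k] <= ult_idx:
        i1, i0 = ridx[k], ridx[k - 1]
        # linear interpolation of the crossing
        f = diff[i0] / (diff[i0] - diff[i1])
        ey = strain[i0] + f * (strain[i1] - strain[i0])
        sy = stress[i0] + f * (stress[i1] - stress[i0])
        return float(ey), float(sy), DROP
    # LIFT: departure above the elastic line by E*offset
    lift = stress - e * strain - e * offset
    lidx = np.where((strain > max(offset, lift_from)) & (lift >= 0))[0]
    if lidx.size:
        i = lidx[0]
        return float(strain[i]), float(stress[i]), LIFT
    return float("nan"), float("nan"), NONE


def ultimate_point(curve: pd.DataFrame):
    """(strain, stress) at the peak; ties break toward smaller strain."""
    if len(curve) == 0:
        raise ValueError("empty curve")
    stress = curve["stress_MPa"].to_numpy()
    i = int(np.argmax(stress))
    return float(curve["strain"].iloc[i]), float(stress[i])


def extract_properties(curve: pd.DataFrame, window: int = 51,
                       offset: float = 0.01,
                       smooth_first: bool = True) -> MechanicalProperties:
    """Full property extraction from one recorded stress–strain curve."""
    sm = smooth_curve(curve, window) if smooth_first and len(curve) >= window \
        else curve
    e = youngs_modulus(sm)
    ey, sy, mode = yield_point(sm, modulus=e, offset=offset)
    eu, su = ultimate_point(sm)
    return MechanicalProperties(
        youngs_modulus=e, yield_strain=ey, yield_stress=sy,
        ultimate_strain=eu, ultimate_stress=su, yield_mode=mode)


def aggregate_replicates(props: Sequence[MechanicalProperties]) -> Dict:
    """Elementwise min/max/mean per property plus a yield-mode tally.

    NaN yields (mode NONE) are excluded from the yield-strain/stress
    statistics; the tally records how many replicates fell in each mode.
    """
    if not props:
        raise ValueError("no replicates to aggregate")
    out: Dict = {"n": len(props)}
    for name in PROPERTY_FIELDS:
        vals = np.array([getattr(p, name) for p in props], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[name] = {"min": float(vals.min()), "max": float(vals.max()),
                         "mean": float(vals.mean())}
        else:
            out[name] = {"min": float("nan"), "max": float("nan"),
                         "mean": float("nan")}
    out["yield_modes"] = {m: sum(1 for p in props if p.yield_mode == m)
                          for m in (DROP, LIFT, NONE)}
    return out


@dataclass
class StudyResult:
    """Per-position replicate properties and summaries of one study."""

    positions: List[float]
    target_mvfs: List[float]
    achieved_mvfs: List[List[float]]
    replicates: List[List[MechanicalProperties]]
    summaries: List[Dict]
    seeds: List[List[int]]
    failures: List[List[str]] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        """Study summary table: one row per insertion position."""
        rows = []
        for i, x in enumerate(self.positions):
            s = self.summaries[i]
            rows.append({
                "x": x,
                "target_MVF": self.target_mvfs[i],
                "achieved_MVF_mean": float(np.mean(self.achieved_mvfs[i])),
                "E_MPa": s["youngs_modulus"]["mean"],
                "yield_strain": s["yield_strain"]["mean"],
                "yield_stress_MPa": s["yield_stress"]["mean"],
                "ultimate_strain": s["ultimate_strain"]["mean"],
                "ultimate_stress_MPa": s["ultimate_stress"]["mean"],
                "n_drop": s["yield_modes"][DROP],
                "n_lift": s["yield_modes"][LIFT],
                "n_none": s["yield_modes"][NONE],
            })
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        doc = {
            "positions": self.positions,
            "target_mvfs": self.target_mvfs,
            "achieved_mvfs": self.achieved_mvfs,
            "seeds": self.seeds,
            "failures": self.failures,
            "replicates": [[asdict(p) for p in reps]
                           for reps in self.replicates],
            "summaries": self.summaries,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def plot_study(result: "StudyResult", path) -> None:
    """Min/max/mean panels of the five properties vs insertion position."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, axes = plt.subplots(1, 5, figsize=(18, 3.2))
    labels = {"youngs_modulus": "E (MPa)", "yield_stress": "yield stress",
              "yield_strain": "yield strain",
              "ultimate_strain": "ultimate strain",
              "ultimate_stress": "UTS (MPa)"}
    for ax, name in zip(axes, PROPERTY_FIELDS):
        x = result.positions
        ax.plot(x, [s[name]["min"] for s in result.summaries], "o",
                color="green", label="min")
        ax.plot(x, [s[name]["max"] for s in result.summaries], "o",
                color="red", label="max")
        ax.plot(x, [s[name]["mean"] for s in result.summaries], "o--",
                color="purple", label="mean")
        ax.set_xlabel("position x")
        ax.set_title(labels[name])
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_curves(curves, path, labels=None) -> None:
    """Overlayed stress-strain curves (one per study position)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    for k, c in enumerate(curves):
        lab = labels[k] if labels else None
        ax.plot(c["strain"], c["stress_MPa"], lw=0.8, label=lab)
    ax.set_xlabel("engineering strain")
    ax.set_ylabel("axial stress (MPa)")
    if labels:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _replicate_seed(base_seed: int, pos_index: int, rep: int) -> int:
    # distinct, reproducible, < 2^31
    return (base_seed * 100003 + pos_index * 1009 + rep) % (2 ** 31)


def run_one_replicate(geometry: GeometryConfig,
                      mineral: MineralizationConfig,
                      protocol: ProtocolConfig,
                      seed: int,
                      forcefield: Optional[ForceField] = None):
    """Build → mineralize → relax → pull for one seed.

    Mineral placement, velocity initialization and the thermostat consume
    independent child streams of the seed so that changing one stage does
    not shift another's draws.  Returns (curve DataFrame, achieved MVF).
    """
    ff = forcefield or default_forcefield()
    ss = np.random.SeedSequence(seed)
    s_min, s_vel, s_thermo = ss.spawn(3)
    model = build_fibril(geometry)
    if mineral.target_mvf > 0:
        model = mineralize(model, mineral, np.random.default_rng(s_min))
    achieved = compute_mvf(model)
    tables = ForceTables(ff)
    nlist = NeighborList(tables, protocol.neighbor_skin)
    state = SimulationState.from_model(
        model, protocol.temperature, np.random.default_rng(s_vel))
    rng_thermo = np.random.default_rng(s_thermo)
    relax(state, protocol, tables, nlist, rng_thermo)
    if protocol.cross_section_area is None:
        # freeze the collagen cross-section after relaxation: the stress
        # reference is mineral-independent, so properties are comparable
        # across insertion positions
        protocol = replace(protocol,
                           cross_section_area=collagen_cross_section(state))
    curve = tensile_run(state, protocol, tables, nlist, rng_thermo)
    return curve, achieved


def run_insertion_study(geometry: GeometryConfig,
                        mineral: Optional[MineralizationConfig] = None,
                        protocol: Optional[ProtocolConfig] = None,
                        positions: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
                        n_replicates: int = 5,
                        base_seed: int = 0,
                        forcefield: Optional[ForceField] = None,
                        smoothing_window: int = 51,
                        offset: float = 0.01) -> StudyResult:
    """Five-position insertion study.

    For each position: target MVF from the linear gradient, mineralize with
    a fresh seed per replicate, relax, pull, extract properties; aggregate
    min/max/mean over replicates.  Per-replicate failures are recorded and
    excluded; a position fails the study only if all its replicates fail.
    """
    mineral = mineral or MineralizationConfig()
    protocol = protocol or ProtocolConfig()
    result = StudyResult(positions=list(positions), target_mvfs=[],
                         achieved_mvfs=[], replicates=[], summaries=[],
                         seeds=[], failures=[])
    for pi, x in enumerate(positions):
        target = mvf_at_position(x)
        mcfg = replace(mineral, target_mvf=target)
        props: List[MechanicalProperties] = []
        mvfs: List[float] = []
        seeds: List[int] = []
        fails: List[str] = []
        for rep in range(n_replicates):
            seed = _replicate_seed(base_seed, pi, rep)
            seeds.append(seed)
            try:
                curve, achieved = run_one_replicate(
                    geometry, mcfg, protocol, seed, forcefield)
                if curve.attrs.get("error"):
                    raise RuntimeError(curve.attrs["error"])
                props.append(extract_properties(
                    curve, window=min(smoothing_window, len(curve)),
                    offset=offset))
                mvfs.append(achieved)
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                fails.append(f"x={x} rep={rep}: {exc}")
        if not props:
            raise RuntimeError(
                f"all {n_replicates} replicates failed at x={x}: {fails}")
        result.target_mvfs.append(target)
        result.achieved_mvfs.append(mvfs)
        result.replicates.append(props)
        result.summaries.append(aggregate_replicates(props))
        result.seeds.append(seeds)
        result.failures.append(fails)
    return result
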