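"""Synthetic pulmonary arterial trees, stenoses and inlet waveforms.

This module is the synthetic-data generator of the package. It builds
idealized branching pulmonary trees (MPA → LPA/RPA → lobar → segmental
branches), applies and removes focal stenoses defined by fractional
diameter reduction, and generates periodic inlet velocity waveforms with
explicit systolic/diastolic phases. These objects stand in for the
patient-specific CT segmentations a clinical study would use.

Conventions
-----------
* All quantities are SI (m, s, Pa). Use :mod:`pulmoflow.units` at the
  interface for mmHg/mm.
* Generation numbering: the main pulmonary artery (MPA, the root) is
  generation 1, the proximal left/right branches (LPA/RPA) generation 2,
  and so on; terminal (outlet) segments sit at the last generation.
* A segment's ``diameter`` is its healthy lumen diameter. A stenosis is
  an annotation on top of it; ``effective_diameter`` is what the flow
  sees. Removing the stenosis therefore restores the tree bit-exactly.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FluidProperties",
    "VesselSegment",
    "VascularTree",
    "StenosisSpec",
    "InflowWaveform",
    "TreeError",
    "build_idealized_tree",
    "apply_stenosis",
    "remove_stenosis",
    "branch_area_ratio",
    "generate_inflow_waveform",
]

SIDES = ("trunk", "left", "right")


class TreeError(ValueError):
    """Raised for invalid tree topologies, stenosis specs or waveforms."""


@dataclass(frozen=True)
class FluidProperties:
    """Bulk blood properties: density (kg/m³) and dynamic viscosity (Pa·s).

    Defaults are standard for blood: ρ = 1056 kg/m³ and μ = 3.5 cP
    (= 3.5e-3 Pa·s).
    """

    density: float = 1056.0
    viscosity: float = 3.5e-3

    def __post_init__(self) -> None:
        if not (self.density > 0):
            raise ValueError(f"density must be > 0, got {self.density}")
        if not (self.viscosity > 0):
            raise ValueError(f"viscosity must be > 0, got {self.viscosity}")


@dataclass(frozen=True)
class VesselSegment:
    """One straight vessel segment of the arterial tree.

    Parameters
    ----------
    id : str
        Unique identifier ("MPA", "LPA", "RPA.1", ...).
    parent_id : str or None
        Identifier of the upstream segment; ``None`` only for the root.
    length, diameter : float
        Segment length and healthy lumen diameter, in metres.
    side : {"trunk", "left", "right"}
        Which lung the segment feeds.
    stenosis : float or None
        Fractional diameter reduction in (0, 1) if the segment carries a
        focal stenosis, else ``None``.
    """

    id: str
    parent_id: str | None
    length: float
    diameter: float
    side: str
    stenosis: float | None = None

    def __post_init__(self) -> None:
        if not (self.length > 0):
            raise TreeError(f"segment {self.id!r}: length must be > 0")
        if not (self.diameter > 0):
            raise TreeError(f"segment {self.id!r}: diameter must be > 0")
        if self.side not in SIDES:
            raise TreeError(
                f"segment {self.id!r}: side must be one of {SIDES}, got {self.side!r}"
            )
        if self.stenosis is not None and not (0.0 < self.stenosis < 1.0):
            raise TreeError(
                f"segment {self.id!r}: stenosis fraction must be in (0, 1), "
                f"got {self.stenosis}"
            )

    # -- geometry -----------------------------------------------------
    @property
    def effective_diameter(self) -> float:
        """Lumen diameter seen by the flow (stenotic if stenosed)."""
        if self.stenosis is None:
            return self.diameter
        return self.diameter * (1.0 - self.stenosis)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def effective_radius(self) -> float:
        return self.effective_diameter / 2.0

    @property
    def area(self) -> float:
        """Healthy cross-sectional area A = π d²/4 (m²)."""
        return math.pi * self.diameter**2 / 4.0

    @property
    def effective_area(self) -> float:
        """Cross-sectional area of the (possibly stenotic) lumen (m²)."""
        return math.pi * self.effective_diameter**2 / 4.0


@dataclass(frozen=True)
class StenosisSpec:
    """A focal stenosis: target segment and fractional diameter reduction.

    Severity follows the clinical convention (D₀ − D_s)/D₀, i.e. a
    reduction of 0.438 narrows a 20 mm vessel to 11.24 mm.
    """

    segment_id: str
    diameter_reduction: float

    def __post_init__(self) -> None:
        if not (0.0 < self.diameter_reduction < 1.0):
            raise TreeError(
                "diameter_reduction must be in (0, 1), "
                f"got {self.diameter_reduction}"
            )


class VascularTree:
    """A branching arterial network with one inlet and many outlets.

    The tree is immutable in practice: stenosis application/removal
    return new trees. Segments are held in insertion order; topology
    maps (children, leaves, root) are derived at construction and the
    invariants are validated then:

    * exactly one root (the MPA);
    * every non-root parent exists; connected and acyclic;
    * at least one leaf on each of the left and right sides.
    """

    def __init__(self, segments: Iterable[VesselSegment]):
        self._segments: dict[str, VesselSegment] = {}
        for seg in segments:
            if seg.id in self._segments:
                raise TreeError(f"duplicate segment id {seg.id!r}")
            self._segments[seg.id] = seg
        self._children: dict[str, list[str]] = {sid: [] for sid in self._segments}
        roots = []
        for seg in self._segments.values():
            if seg.parent_id is None:
                roots.append(seg.id)
            else:
                if seg.parent_id not in self._segments:
                    raise TreeError(
                        f"segment {seg.id!r}: parent {seg.parent_id!r} does not exist"
                    )
                self._children[seg.parent_id].append(seg.id)
        if len(roots) != 1:
            raise TreeError(
                f"tree must have exactly one root segment, found {len(roots)}"
            )
        self._root_id = roots[0]
        # connectivity / acyclicity: BFS from the root must reach all segments
        seen = {self._root_id}
        frontier = [self._root_id]
        while frontier:
            nxt = []
            for sid in frontier:
                for cid in self._children[sid]:
                    if cid in seen:  # pragma: no cover - defensive
                        raise TreeError(f"cycle detected at segment {cid!r}")
                    seen.add(cid)
                    nxt.append(cid)
            frontier = nxt
        if len(seen) != len(self._segments):
            missing = sorted(set(self._segments) - seen)
            raise TreeError(
                f"tree is disconnected: segment {missing[0]!r} unreachable from root"
            )
        self._outlet_ids = tuple(
            sid for sid in self._segments if not self._children[sid]
        )
        for side in ("left", "right"):
            if not any(self._segments[o].side == side for o in self._outlet_ids):
                raise TreeError(f"tree has no outlet on the {side} side")

    # -- accessors ----------------------------------------------------
    @property
    def segments(self) -> Mapping[str, VesselSegment]:
        return dict(self._segments)

    @property
    def root_id(self) -> str:
        return self._root_id

    @property
    def root(self) -> VesselSegment:
        return self._segments[self._root_id]

    @property
    def outlet_ids(self) -> tuple[str, ...]:
        return self._outlet_ids

    @property
    def n_segments(self) -> int:
        return len(self._segments)

    @property
    def inlet_area(self) -> float:
        """Inlet cross-sectional area of the root segment (m²)."""
        return self.root.area

    def __getitem__(self, segment_id: str) -> VesselSegment:
        return self._segments[segment_id]

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self._segments

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VascularTree):
            return NotImplemented
        return self._segments == other._segments

    def children(self, segment_id: str) -> tuple[str, ...]:
        return tuple(self._children[segment_id])

    def outlet_ids_on_side(self, side: str) -> tuple[str, ...]:
        return tuple(o for o in self._outlet_ids if self._segments[o].side == side)

    def proximal_branch(self, side: str) -> VesselSegment:
        """The first-generation (proximal) branch on a side (LPA or RPA)."""
        for cid in self._children[self._root_id]:
            if self._segments[cid].side == side:
                return self._segments[cid]
        raise TreeError(f"tree has no proximal branch on the {side!r} side")

    def stenosed_segments(self) -> tuple[VesselSegment, ...]:
        return tuple(s for s in self._segments.values() if s.stenosis is not None)

    def _replace_segment(self, seg: VesselSegment) -> "VascularTree":
        segs = [seg if s.id == seg.id else s for s in self._segments.values()]
        return VascularTree(segs)

    # -- serialization ------------------------------------------------
    def to_records(self) -> list[dict]:
        return [
            {
                "id": s.id,
                "parent_id": s.parent_id,
                "length_m": s.length,
                "diameter_m": s.diameter,
                "side": s.side,
                "stenosis": s.stenosis,
            }
            for s in self._segments.values()
        ]

    def to_json(self, path: str | Path) -> None:
        """Write the tree as a JSON document, one record per segment."""
        Path(path).write_text(json.dumps(self.to_records(), indent=2) + "\n")

    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "VascularTree":
        segs = []
        for rec in records:
            try:
                segs.append(
                    VesselSegment(
                        id=str(rec["id"]),
                        parent_id=rec["parent_id"],
                        length=float(rec["length_m"]),
                        diameter=float(rec["diameter_m"]),
                        side=rec["side"],
                        stenosis=(
                            None if rec.get("stenosis") is None
                            else float(rec["stenosis"])
                        ),
                    )
                )
            except KeyError as exc:
                raise TreeError(
                    f"segment record {rec.get('id', '?')!r}: missing field {exc}"
                ) from exc
        return cls(segs)

    @classmethod
    def from_json(cls, path: str | Path) -> "VascularTree":
        """Read a tree from JSON, validating every invariant."""
        return cls.from_records(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------

def _side_prefix(side: str) -> str:
    return "LPA" if side == "left" else "RPA"


def build_idealized_tree(
    generations: int,
    left_outlets: int,
    right_outlets: int,
    root_diameter: float,
    taper: float = 0.2,
    length_ratio: float = 3.0,
) -> VascularTree:
    """Build a deterministic idealized pulmonary arterial tree.

    The MPA (generation 1) bifurcates into the proximal LPA and RPA
    (generation 2); each side then bifurcates symmetrically down to the
    requested number of generations, with the terminal generation
    fanning out so that each side carries exactly the requested number
    of outlets (extra leaves are attached to the last internal branch of
    the side, in id order). Diameters shrink by ``taper`` per generation
    and lengths follow ``length = length_ratio × diameter``.

    Parameters
    ----------
    generations : int
        Total number of generations including the MPA; ≥ 2. With
        ``generations=2`` the proximal branches are themselves the
        outlets, so both outlet counts must equal 1.
    left_outlets, right_outlets : int
        Number of terminal segments on each side (≥ 1).
    root_diameter : float
        MPA lumen diameter in metres.
    taper : float
        Fractional diameter reduction per generation, in (0, 1).
    length_ratio : float
        Segment length as a multiple of its diameter.
    """
    if generations < 2:
        raise TreeError("generations must be >= 2 (MPA plus its two branches)")
    if left_outlets < 1 or right_outlets < 1:
        raise TreeError("each side needs at least one outlet")
    if not (root_diameter > 0):
        raise TreeError("root_diameter must be > 0")
    if not (0.0 < taper < 1.0):
        raise TreeError("taper must be in (0, 1)")
    if not (length_ratio > 0):
        raise TreeError("length_ratio must be > 0")
    if generations == 2 and (left_outlets != 1 or right_outlets != 1):
        raise TreeError(
            "generations=2 admits exactly one outlet per side (the proximal "
            f"branches are the outlets); requested {left_outlets} left / "
            f"{right_outlets} right"
        )

    def diam(gen: int) -> float:
        return root_diameter * (1.0 - taper) ** (gen - 1)

    def seg(sid: str, parent: str | None, gen: int, side: str) -> VesselSegment:
        d = diam(gen)
        return VesselSegment(
            id=sid, parent_id=parent, length=length_ratio * d,
            diameter=d, side=side,
        )

    segments = [seg("MPA", None, 1, "trunk")]
    for side, n_out in (("left", left_outlets), ("right", right_outlets)):
        prefix = _side_prefix(side)
        segments.append(seg(prefix, "MPA", 2, side))
        if generations == 2:
            continue
        # internal layers: generations 3 .. generations-1, binary growth
        # capped so every terminal internal node receives >= 1 leaf
        layer = [prefix]
        for gen in range(3, generations):
            width = min(2 * len(layer), n_out)
            if width < len(layer):
                width = len(layer)  # never shrink: keep chains alive
            counts = [1] * len(layer)
            extra = width - len(layer)
            for i in range(extra):
                counts[i] += 1
            new_layer = []
            for node, cnt in zip(layer, counts):
                for k in range(1, cnt + 1):
                    cid = f"{node}.{k}"
                    segments.append(seg(cid, node, gen, side))
                    new_layer.append(cid)
            layer = new_layer
        # terminal generation: distribute n_out leaves over the last
        # internal layer, base share each, remainder on the last node
        k = len(layer)
        if n_out < k:  # pragma: no cover - prevented by width cap
            raise TreeError(
                f"cannot place {n_out} outlets on {k} terminal branches of the "
                f"{side} side with generations={generations}"
            )
        base, rem = divmod(n_out, k)
        counts = [base] * k
        counts[-1] += rem
        for node, cnt in zip(layer, counts):
            for j in range(1, cnt + 1):
                segments.append(seg(f"{node}.{j}", node, generations, side))

    tree = VascularTree(segments)
    assert len(tree.outlet_ids_on_side("left")) == left_outlets
    assert len(tree.outlet_ids_on_side("right")) == right_outlets
    return tree


# ---------------------------------------------------------------------
# stenosis manipulation
# ---------------------------------------------------------------------

def apply_stenosis(tree: VascularTree, spec: StenosisSpec) -> VascularTree:
    """Return a new tree with a focal stenosis on the target segment.

    The stenotic diameter is d_s = d₀·(1 − reduction). The input tree is
    left untouched. The root (inlet) segment cannot be stenosed.
    """
    if spec.segment_id not in tree:
        raise TreeError(f"unknown segment id {spec.segment_id!r}")
    if spec.segment_id == tree.root_id:
        raise TreeError("cannot place a stenosis on the root inlet segment")
    seg = tree[spec.segment_id]
    new_seg = dataclasses.replace(seg, stenosis=spec.diameter_reduction)
    return tree._replace_segment(new_seg)


def remove_stenosis(tree: VascularTree, segment_id: str) -> VascularTree:
    """Return a new tree with the segment restored to its healthy diameter."""
    if segment_id not in tree:
        raise TreeError(f"unknown segment id {segment_id!r}")
    seg = tree[segment_id]
    if seg.stenosis is None:
        raise TreeError(f"segment {segment_id!r} carries no stenosis")
    return tree._replace_segment(dataclasses.replace(seg, stenosis=None))


def remove_all_stenoses(tree: VascularTree) -> VascularTree:
    """Restore every stenosed segment (the virtual-surgery morphology)."""
    out = tree
    for seg in tree.stenosed_segments():
        out = remove_stenosis(out, seg.id)
    return out


def branch_area_ratio(
    tree: VascularTree, stenosed_side: str, method: str = "proximal"
) -> float:
    """Size ratio: stenosed-side area over non-stenosed-side area.

    ``method="proximal"`` (default) uses the effective cross-sectional
    areas of the first-generation branches (LPA/RPA), which is where a
    proximal focal stenosis shows up. ``method="outlet_total"`` uses the
    summed outlet areas of each side instead, mirroring how total distal
    areas are sometimes reported.
    """
    if stenosed_side not in ("left", "right"):
        raise TreeError(f"stenosed_side must be 'left' or 'right', got {stenosed_side!r}")
    other = "right" if stenosed_side == "left" else "left"
    if method == "proximal":
        a_sten = tree.proximal_branch(stenosed_side).effective_area
        a_non = tree.proximal_branch(other).effective_area
    elif method == "outlet_total":
        a_sten = sum(tree[o].effective_area for o in tree.outlet_ids_on_side(stenosed_side))
        a_non = sum(tree[o].effective_area for o in tree.outlet_ids_on_side(other))
    else:
        raise TreeError(f"unknown size-ratio method {method!r}")
    return a_sten / a_non


# ---------------------------------------------------------------------
# inflow waveform
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class InflowWaveform:
    """Periodic inlet velocity waveform with explicit phase boundaries.

    ``times``/``velocities`` are one period of ordered samples starting
    at t = 0 and ending at t = period with equal first/last velocities.
    When built by :func:`generate_inflow_waveform` the analytic
    parameters are retained and :meth:`velocity` evaluates the closed
    form; waveforms loaded from file interpolate linearly.
    """

    period: float
    systole_end: float
    times: np.ndarray
    velocities: np.ndarray
    inlet_area: float | None = None
    # analytic parameters (present for generated waveforms)
    peak_velocity_param: float | None = None
    diastolic_fraction: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.systole_end < self.period):
            raise TreeError("require 0 < systole_end < period")
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 4:
            raise TreeError("waveform needs >= 4 ordered (time, velocity) samples")
        if np.any(np.diff(t) <= 0):
            raise TreeError("waveform sample times must be strictly increasing")
        if abs(t[0]) > 1e-12 or abs(t[-1] - self.period) > 1e-9:
            raise TreeError("waveform samples must span exactly [0, period]")
        if np.any(v < 0):
            raise TreeError("waveform velocities must be non-negative")
        if abs(v[0] - v[-1]) > 1e-12 * max(1.0, v.max()):
            raise TreeError("waveform must be periodic: first and last velocities differ")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "velocities", v)
        if self.inlet_area is not None and not (self.inlet_area > 0):
            raise TreeError("inlet_area must be > 0 when given")

    @property
    def peak_velocity(self) -> float:
        return float(self.velocities.max())

    @property
    def peak_time(self) -> float:
        return float(self.times[int(np.argmax(self.velocities))])

    def velocity(self, t) -> np.ndarray:
        """Inlet velocity at time(s) ``t`` (periodically extended)."""
        tt = np.mod(np.asarray(t, dtype=float), self.period)
        if self.peak_velocity_param is not None:
            pk = self.peak_velocity_param
            d = self.diastolic_fraction * pk
            out = np.where(
                tt <= self.systole_end,
                d + (pk - d) * np.sin(np.pi * tt / self.systole_end),
                d,
            )
            return out if out.ndim else float(out)
        return np.interp(tt, self.times, self.velocities)

    def mean_velocity(self) -> float:
        """Cycle-averaged velocity (trapezoidal over the samples)."""
        return float(np.trapezoid(self.velocities, self.times) / self.period)

    def flow_per_cycle(self) -> float:
        """Inlet volume per cycle: inlet_area × ∫ v dt (m³)."""
        if self.inlet_area is None:
            raise TreeError("waveform has no inlet_area set")
        return float(self.inlet_area * np.trapezoid(self.velocities, self.times))

    def with_inlet_area(self, area: float) -> "InflowWaveform":
        return dataclasses.replace(self, inlet_area=area)

    # -- serialization ------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write one period as a 2-column CSV (time_s, velocity_m_per_s)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "velocity_m_per_s"])
            for t, v in zip(self.times, self.velocities):
                w.writerow([repr(float(t)), repr(float(v))])

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        systole_end: float,
        inlet_area: float | None = None,
    ) -> "InflowWaveform":
        with open(path, newline="") as fh:
            r = csv.reader(fh)
            header = next(r, None)
            if header is None or [h.strip() for h in header[:2]] != [
                "time_s", "velocity_m_per_s",
            ]:
                raise TreeError(
                    "waveform CSV must start with header 'time_s,velocity_m_per_s'"
                )
            rows = [(float(a), float(b)) for a, b, *_ in r]
        t = np.array([x for x, _ in rows])
        v = np.array([y for _, y in rows])
        return cls(
            period=float(t[-1]), systole_end=systole_end,
            times=t, velocities=v, inlet_area=inlet_area,
        )


def generate_inflow_waveform(
    peak_velocity: float,
    period: float = 0.925,
    systole_end: float = 0.380,
    diastolic_fraction: float = 0.05,
    n_samples: int = 1000,
    inlet_area: float | None = None,
) -> InflowWaveform:
    """Generate the half-sine systolic / constant-diastolic inlet waveform.

    Systole occupies [0, systole_end] with a half-sine pulse rising from
    the diastolic plateau to ``peak_velocity`` at systole_end/2; diastole
    is a constant plateau at ``diastolic_fraction × peak_velocity``. The
    defaults mirror a physiological cycle of 925 ms with systole from 0
    to 380 ms.

    The sample grid is a uniform grid over one period augmented with the
    exact peak time and the systole/diastole boundary, so the sampled
    maximum equals the configured peak exactly.
    """
    if not (peak_velocity > 0):
        raise TreeError("peak_velocity must be > 0")
    if not (0.0 < systole_end < period):
        raise TreeError("require 0 < systole_end < period")
    if not (0.0 <= diastolic_fraction < 1.0):
        raise TreeError("diastolic_fraction must be in [0, 1)")
    if n_samples < 4:
        raise TreeError("n_samples must be >= 4")
    base = np.linspace(0.0, period, n_samples)
    t = np.union1d(base, [systole_end / 2.0, systole_end])
    d = diastolic_fraction * peak_velocity
    v = np.where(
        t <= systole_end,
        d + (peak_velocity - d) * np.sin(np.pi * t / systole_end),
        d,
    )
    return InflowWaveform(
        period=period,
        systole_end=systole_end,
        times=t,
        velocities=v,
        inlet_area=inlet_area,
        peak_velocity_param=peak_velocity,
        diastolic_fraction=diastolic_fraction,
    )
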