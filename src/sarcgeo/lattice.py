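"""Filament-aware particle bookkeeping: polyline resampling, axial shift
propagation, duplicate removal, and point-group / helical symmetry expansion.

These are the coordinate manipulations a subtomogram-averaging pipeline
scripts around its refinement steps.  All of them report what they drop;
silent record loss is forbidden.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .crowns import CylinderModel
from .io import FilamentTrace, ParticleRecord, PointSet, normalize_angle

__all__ = [
    "SymmetryOp", "ShiftReport",
    "resample_trace", "axial_shift", "remove_duplicates", "expand_symmetry",
    "tangent_orientation",
]


@dataclass(frozen=True)
class SymmetryOp:
    """Cn / Dn point-group or helical symmetry about a cylinder axis."""

    kind: str                      # "Cn", "Dn" or "helical"
    axis: CylinderModel
    n: int = 1
    rise: float = 0.0              # Å, helical
    twist: float = 0.0             # deg, helical
    perp_axis: Optional[np.ndarray] = None  # two-fold axis direction for Dn

    def __post_init__(self):
        if self.kind not in {"Cn", "Dn", "helical"}:
            raise ValueError(f"unknown symmetry kind {self.kind!r}")
        if self.kind in {"Cn", "Dn"} and self.n < 1:
            raise ValueError("n must be >= 1")
        if self.kind == "helical" and self.rise == 0.0 and self.twist == 0.0:
            raise ValueError("helical op needs nonzero rise or twist")
        if self.perp_axis is not None:
            p = np.asarray(self.perp_axis, float).reshape(3)
            object.__setattr__(self, "perp_axis", p / np.linalg.norm(p))


@dataclass
class ShiftReport:
    n_in: int
    n_out: int
    dropped: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def tangent_orientation(tangent: np.ndarray) -> np.ndarray:
    """Z-Y-Z Euler angles (deg) whose rotated z axis equals the tangent.

    The in-plane spin about the tangent is undefined from a polyline, so the
    third angle carries it nominally and the first (rot) is NaN-flagged:
    tangent = (sin tilt cos psi, sin tilt sin psi, cos tilt).
    """
    t = np.asarray(tangent, float)
    t = t / np.linalg.norm(t)
    tilt = math.degrees(math.acos(np.clip(t[2], -1.0, 1.0)))
    psi = math.degrees(math.atan2(t[1], t[0])) if tilt > 1e-9 else 0.0
    return np.array([np.nan, tilt, normalize_angle(psi)])


def resample_trace(trace: FilamentTrace, spacing: float
                   ) -> list[ParticleRecord]:
    """Particles at arc positions 0, spacing, 2*spacing, ... along the trace.

    When the spacing exceeds the trace length a single record at the start is
    returned, class-labelled ``short-trace``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    total = trace.length
    if spacing > total:
        ori = tangent_orientation(trace.tangent_at(0.0))
        return [ParticleRecord(trace.filament_id, 1, trace.points[0], ori,
                               class_label="short-trace")]
    n = int(math.floor(total / spacing + 1e-9)) + 1
    out = []
    for i in range(n):
        s = i * spacing
        out.append(ParticleRecord(
            trace.filament_id, i + 1, trace.point_at(s),
            tangent_orientation(trace.tangent_at(s))))
    return out


def _project_onto_trace(trace: FilamentTrace, point: np.ndarray) -> float:
    """Arc-length position of the closest polyline point to ``point``."""
    p = np.asarray(point, float)
    a = trace.points[:-1]
    d = np.diff(trace.points, axis=0)
    seg_len2 = np.einsum("ij,ij->i", d, d)
    t = np.clip(np.einsum("ij,ij->i", p - a, d) / seg_len2, 0.0, 1.0)
    proj = a + t[:, None] * d
    dist2 = np.einsum("ij,ij->i", proj - p, proj - p)
    i = int(np.argmin(dist2))
    cs = trace.arclengths
    return float(cs[i] + t[i] * (cs[i + 1] - cs[i]))


def axial_shift(records: Sequence[ParticleRecord],
                traces: dict[str, FilamentTrace],
                delta: float, direction: str = "zward"
                ) -> tuple[list[ParticleRecord], ShiftReport]:
    """Move each record along its filament trace by arc length |delta|.

    ``direction`` is ``"zward"`` (away from the M band) or ``"mward"``;
    the trace's polarity flag translates that into increasing or decreasing
    arc length.  Records whose shift exits the trace are dropped and listed
    in the report.
    """
    if direction not in {"zward", "mward"}:
        raise ValueError("direction must be 'zward' or 'mward'")
    if delta == 0:
        raise ValueError("delta must be nonzero")
    out: list[ParticleRecord] = []
    report = ShiftReport(len(records), 0)
    for rec in records:
        trace = traces.get(rec.filament_id)
        if trace is None:
            raise KeyError(f"no trace for filament {rec.filament_id!r}")
        s0 = _project_onto_trace(trace, rec.position)
        zward_step = (direction == "zward") == trace.zward
        s1 = s0 + abs(delta) * (1.0 if zward_step else -1.0)
        if s1 < -1e-9 or s1 > trace.length + 1e-9:
            report.dropped.append(f"{rec.filament_id}/{rec.segment_index}")
            continue
        ori = tangent_orientation(trace.tangent_at(s1))
        if rec.orientation is not None and not np.isnan(rec.orientation[0]):
            ori[0] = rec.orientation[0]  # preserve known in-plane spin
        out.append(rec.moved_to(trace.point_at(s1), ori))
    report.n_out = len(out)
    return out, report


def remove_duplicates(records: Sequence[ParticleRecord], min_dist: float,
                      keep: str = "best-score") -> list[ParticleRecord]:
    """Greedy duplicate removal: keep a record iff no already-kept record
    lies within ``min_dist``.  Candidates are visited by descending score
    (``best-score``; missing scores last, input order among ties) or in
    input order (``first``).  Deterministic for a fixed input."""
    if min_dist <= 0:
        raise ValueError("min_dist must be positive")
    if keep not in {"best-score", "first"}:
        raise ValueError("keep must be 'best-score' or 'first'")
    order = list(range(len(records)))
    if keep == "best-score":
        order.sort(key=lambda i: (-(records[i].score
                                    if records[i].score is not None
                                    else -math.inf), i))
    kept: list[ParticleRecord] = []
    kept_pos = np.empty((0, 3))
    for i in order:
        p = records[i].position
        if len(kept_pos) and np.min(
                np.linalg.norm(kept_pos - p, axis=1)) < min_dist:
            continue
        kept.append(records[i])
        kept_pos = np.vstack([kept_pos, p])
    if len(kept_pos) > 1:  # postcondition, asserted on every run
        from scipy.spatial.distance import pdist
        assert pdist(kept_pos).min() >= min_dist
    return kept


def _axis_rotation(op_axis: CylinderModel, angle_deg: float) -> Rotation:
    return Rotation.from_rotvec(
        np.radians(angle_deg) * op_axis.axis_direction)


def _apply(records, rot: Rotation, about: np.ndarray,
           translation: np.ndarray):
    out = []
    for rec in records:
        pos = rot.apply(rec.position - about) + about + translation
        ori = rec.orientation
        if ori is not None:
            o = np.where(np.isnan(ori), 0.0, ori)
            r_old = Rotation.from_euler("ZYZ", o, degrees=True)
            with warnings.catch_warnings():
                # tilt=0 gimbal is routine for axis-aligned segments; the
                # composed rotation itself is well defined
                warnings.simplefilter("ignore", UserWarning)
                ori = (rot * r_old).as_euler("ZYZ", degrees=True)
            ori = np.array([normalize_angle(a) for a in ori])
        out.append(rec.moved_to(pos, ori))
    return out


def expand_symmetry(data: Sequence[ParticleRecord] | PointSet,
                    op: SymmetryOp,
                    n_copies: Optional[int] = None):
    """Expand records (or a PointSet) under a symmetry operator.

    Cn gives n rotated copies about the axis; Dn additionally applies a
    two-fold flip about the stated perpendicular axis (2n copies); helical
    gives ``n_copies`` copies at k*(rise, twist).  Orientations are composed
    with the same rotation (an undefined in-plane spin is taken as zero
    before composition).
    """
    is_points = isinstance(data, PointSet)
    if is_points:
        records = [ParticleRecord("ps", i + 1, c)
                   for i, c in enumerate(data.coords)]
    else:
        records = list(data)
    about = op.axis.axis_point
    axis = op.axis.axis_direction
    expanded: list[ParticleRecord] = []
    if op.kind in {"Cn", "Dn"}:
        for k in range(op.n):
            rot = _axis_rotation(op.axis, 360.0 * k / op.n)
            expanded.extend(_apply(records, rot, about, np.zeros(3)))
        if op.kind == "Dn":
            if op.perp_axis is None:
                raise ValueError("Dn expansion needs a perpendicular "
                                 "two-fold axis")
            flip = Rotation.from_rotvec(math.pi * op.perp_axis)
            base = list(expanded)
            expanded.extend(_apply(base, flip, about, np.zeros(3)))
    else:  # helical
        if n_copies is None or n_copies < 1:
            raise ValueError("helical expansion needs n_copies >= 1")
        for k in range(n_copies):
            rot = _axis_rotation(op.axis, k * op.twist)
            expanded.extend(_apply(records, rot, about,
                                   k * op.rise * axis))
    if is_points:
        ids = [f"{i}" for i in range(len(expanded))]
        return PointSet(ids, np.array([r.position for r in expanded]))
    return expanded
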