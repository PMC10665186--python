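"""Crown-pose quantification on a cylindrical filament.

The thick filament is modelled as a cylinder and each myosin interacting-heads
motif (IHM) as a triangle whose vertices are three landmarks: the ATP-binding
site of the free head, the same site of the blocked head, and the head--tail
junction.  At the triangle centroid a local orthonormal frame is erected with
the x axis tangential to the cylinder, the y axis radial (outward) and the z
axis along the cylinder axis.  The pose of the IHM is then

* three Euler angles (alpha, beta, gamma) of the triangle frame expressed in
  that local frame, extracted in **intrinsic Z-Y-X** order, and
* the cylindrical coordinates of the centroid: azimuth phi, radial distance r
  and axial height z, whose per-class successive differences give the helical
  twist and rise of the crown lattice.

Sign convention: beta is the rotation about the radial (y) axis; tilting the
triangle normal away from the filament axis, i.e. heads projected outward,
drives beta negative.  The triangle frame is canonical: e1 points from the
centroid toward the free-head landmark, e3 is the unit normal
(p_blocked - centroid) x (p_junction - centroid) ... see
:func:`triangle_frame`; e2 completes the right-handed set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io import PointSet, normalize_angle

__all__ = [
    "CylinderModel", "IHMLandmarks", "CrownPose",
    "fit_filament_axis", "crown_pose", "crown_series_stats",
    "classify_crowns", "unroll", "reroll",
    "local_cylinder_frame", "triangle_frame",
]

_DEGENERATE_AREA = 1e-6  # Å^2
_AXIS_TOL = 1e-6         # Å, centroid-on-axis rejection


@dataclass(frozen=True)
class CylinderModel:
    """Straight cylinder axis: a point on the axis and a unit direction
    (Z-ward positive by convention)."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: Optional[float] = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "axis_point",
                           np.asarray(self.axis_point, float).reshape(3))
        d = np.asarray(self.axis_direction, float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis_direction must be nonzero")
        object.__setattr__(self, "axis_direction", d / n)


@dataclass(frozen=True)
class IHMLandmarks:
    """The three IHM landmark points (Å): ATP-binding site of the free head,
    the same site of the blocked head, and the head--tail junction."""

    p_free: np.ndarray
    p_blocked: np.ndarray
    p_junction: np.ndarray

    def __post_init__(self):
        for name in ("p_free", "p_blocked", "p_junction"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), float).reshape(3))
        a = self.p_blocked - self.p_free
        b = self.p_junction - self.p_free
        if 0.5 * np.linalg.norm(np.cross(a, b)) < _DEGENERATE_AREA:
            raise ValueError("degenerate IHM triangle (collinear landmarks)")

    @property
    def centroid(self) -> np.ndarray:
        return (self.p_free + self.p_blocked + self.p_junction) / 3.0

    def as_array(self) -> np.ndarray:
        return np.stack([self.p_free, self.p_blocked, self.p_junction])


@dataclass
class CrownPose:
    """Pose of one IHM: Euler angles (deg, intrinsic Z-Y-X in the local
    cylinder frame) plus cylindrical coordinates of the centroid."""

    alpha: float
    beta: float
    gamma: float
    phi: float
    r: float
    z: float
    crown_class: Optional[int | str] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.r < 0:
            raise ValueError("radial distance must be >= 0")
        for name in ("alpha", "beta", "gamma", "phi"):
            setattr(self, name, normalize_angle(float(getattr(self, name))))


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

def _reference_perpendicular(axis: np.ndarray) -> np.ndarray:
    """Deterministic azimuth reference direction perpendicular to the axis."""
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, axis)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    ref = trial - np.dot(trial, axis) * axis
    return ref / np.linalg.norm(ref)


def local_cylinder_frame(cylinder: CylinderModel, point: np.ndarray
                         ) -> tuple[np.ndarray, float, float, float]:
    """Local frame at ``point``: columns (x tangential, y radial, z axial),
    together with the cylindrical coordinates (phi deg, r, z) of the point."""
    z_hat = cylinder.axis_direction
    v = np.asarray(point, float) - cylinder.axis_point
    z = float(np.dot(v, z_hat))
    v_perp = v - z * z_hat
    r = float(np.linalg.norm(v_perp))
    if r < _AXIS_TOL:
        raise ValueError("point lies on the cylinder axis; azimuth undefined")
    y_hat = v_perp / r
    x_hat = np.cross(y_hat, z_hat)
    ref = _reference_perpendicular(z_hat)
    phi = math.degrees(math.atan2(np.dot(v_perp, np.cross(z_hat, ref)),
                                  np.dot(v_perp, ref)))
    frame = np.column_stack([x_hat, y_hat, z_hat])
    return frame, phi, r, z


def triangle_frame(lm: IHMLandmarks) -> tuple[np.ndarray, np.ndarray]:
    """Canonical right-handed frame of the IHM triangle.

    e1: centroid -> p_free; e3: unit normal of the ordered cross product
    (p_free - centroid) x (p_blocked - centroid); e2 = e3 x e1.
    Returns (centroid, 3x3 matrix with columns e1, e2, e3).
    """
    c = lm.centroid
    u1 = lm.p_free - c
    u2 = lm.p_blocked - c
    e1 = u1 / np.linalg.norm(u1)
    n = np.cross(u1, u2)
    e3 = n / np.linalg.norm(n)
    e2 = np.cross(e3, e1)
    return c, np.column_stack([e1, e2, e3])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def fit_filament_axis(points: PointSet | np.ndarray, zward: bool = True
                      ) -> CylinderModel:
    """Total-least-squares axis through a point cloud (principal axis of the
    centred covariance).  The direction sign is chosen Z-ward (positive
    global-z component) when ``zward``.

    A cloud with no dominant direction (singular-value anisotropy ratio
    below 1.5) is fit anyway but carries a warning on the result.
    """
    xyz = points.coords if isinstance(points, PointSet) else np.asarray(points, float)
    xyz = xyz.reshape(-1, 3)
    uniq = np.unique(xyz, axis=0)
    if len(uniq) < 2:
        raise ValueError("axis fit needs at least 2 distinct points")
    centroid = xyz.mean(axis=0)
    _, s, vt = np.linalg.svd(xyz - centroid, full_matrices=False)
    direction = vt[0]
    warnings: tuple[str, ...] = ()
    if len(s) > 1 and s[1] > 0 and s[0] / s[1] < 1.5:
        warnings = ("low-anisotropy point cloud: axis poorly determined",)
    if zward and direction[2] < 0:
        direction = -direction
    elif zward and direction[2] == 0 and direction[0] < 0:
        direction = -direction
    mean_r = float(np.mean(np.linalg.norm(
        (xyz - centroid) - np.outer((xyz - centroid) @ direction, direction),
        axis=1)))
    return CylinderModel(centroid, direction, radius=mean_r, warnings=warnings)


def crown_pose(landmarks: IHMLandmarks, cylinder: CylinderModel,
               crown_class: Optional[int | str] = None) -> CrownPose:
    """Pose of one IHM triangle in the local cylinder frame at its centroid.

    Euler angles are extracted from the rotation taking the local frame to the
    triangle frame, in intrinsic Z-Y-X order.  Poses within 0.1 deg of the
    beta = +/-90 gimbal singularity report the alpha+gamma combination in
    alpha (gamma set to 0) and are flagged ``gimbal``.
    """
    c, tri = triangle_frame(landmarks)
    local, phi, r, z = local_cylinder_frame(cylinder, c)
    rel = local.T @ tri
    flags: tuple[str, ...] = ()
    rot = Rotation.from_matrix(rel)
    alpha, beta, gamma = rot.as_euler("ZYX", degrees=True)
    if abs(abs(beta) - 90.0) < 0.1:
        # gimbal: only alpha+gamma (or alpha-gamma) is determined
        flags = ("gimbal",)
        gamma = 0.0
    return CrownPose(alpha, beta, gamma, phi, r, z,
                     crown_class=crown_class, flags=flags)


def _wrapped_diff(a: float, b: float) -> float:
    return normalize_angle(b - a)


def crown_series_stats(poses: Sequence[CrownPose], repeat: float = 430.0,
                       layer_tol: float = 1.0) -> pd.DataFrame:
    """Per-class pose summaries plus helical rise and twist.

    Crowns are sorted axially and grouped into layers (z within
    ``layer_tol`` Å); the rise of a class is the mean z spacing between its
    successive layers and its twist the mean azimuthal step, where each crown
    is matched to the nearest-azimuth crown of the next layer (this makes the
    statistic well defined in the presence of Cn symmetry mates that share a
    layer).  A class with a single layer reports NaN rise/twist and is
    flagged.
    """
    if len(poses) < 2:
        raise ValueError("need at least 2 poses")
    rows = []
    classes = sorted({p.crown_class for p in poses}, key=lambda c: str(c))
    for cls in classes:
        sub = sorted((p for p in poses if p.crown_class == cls), key=lambda p: p.z)
        layers: list[list[CrownPose]] = [[sub[0]]]
        for p in sub[1:]:
            if p.z - layers[-1][0].z <= layer_tol:
                layers[-1].append(p)
            else:
                layers.append([p])
        rises, twists = [], []
        for la, lb in zip(layers[:-1], layers[1:]):
            za = np.mean([p.z for p in la])
            zb = np.mean([p.z for p in lb])
            rises.append(zb - za)
            for p in la:
                diffs = [_wrapped_diff(p.phi, q.phi) for q in lb]
                twists.append(min(diffs, key=abs))
        flagged = len(layers) < 2
        ang = {name: np.array([getattr(p, name) for p in sub])
               for name in ("alpha", "beta", "gamma", "r")}
        rows.append({
            "crown_class": cls,
            "n": len(sub),
            "n_layers": len(layers),
            **{f"{k}_mean": float(v.mean()) for k, v in ang.items()},
            **{f"{k}_sd": float(v.std(ddof=1)) if len(sub) > 1 else np.nan
               for k, v in ang.items()},
            "rise_A": float(np.mean(rises)) if rises else np.nan,
            "rise_sd_A": float(np.std(rises, ddof=1)) if len(rises) > 1 else np.nan,
            "twist_deg": float(np.mean(twists)) if twists else np.nan,
            "twist_sd_deg": float(np.std(twists, ddof=1)) if len(twists) > 1 else np.nan,
            "single_layer": flagged,
        })
    return pd.DataFrame(rows)


def classify_crowns(poses: Sequence[CrownPose], repeat: float = 430.0,
                    class_offsets: Sequence[float] = (0.0, 143.3, 286.7),
                    ) -> list[CrownPose]:
    """Assign each pose the crown class whose axial offset (modulo the
    repeat) is nearest to its z.  Ties break toward the lower class index and
    are flagged ``ambiguous``."""
    offs = np.asarray(class_offsets, float) % repeat
    if len(np.unique(np.round(offs, 9))) != len(offs):
        raise ValueError("class offsets must be distinct modulo the repeat")
    out = []
    for p in poses:
        zm = p.z % repeat
        d = np.abs(zm - offs)
        d = np.minimum(d, repeat - d)  # circular distance
        best = float(d.min())
        winners = np.flatnonzero(np.isclose(d, best, rtol=0, atol=1e-9))
        flags = p.flags
        if len(winners) > 1:
            flags = flags + ("ambiguous",)
        out.append(replace(p, crown_class=int(winners[0]) + 1, flags=flags))
    return out


def unroll(poses: Sequence[CrownPose], cylinder: CylinderModel | None = None,
           r_ref: Optional[float] = None) -> np.ndarray:
    """Map poses onto the cut-open cylinder plane: (s, z) with
    s = r_ref * phi_radians.  Isometric on the reference cylinder; the
    relative azimuthal order is preserved."""
    if r_ref is None:
        r_ref = float(np.mean([p.r for p in poses]))
    if r_ref <= 0:
        raise ValueError("reference radius must be positive")
    return np.array([[r_ref * math.radians(p.phi), p.z] for p in poses])


def reroll(planar: np.ndarray, r_ref: float) -> np.ndarray:
    """Inverse of :func:`unroll`: (s, z) -> (phi deg, z)."""
    if r_ref <= 0:
        raise ValueError("reference radius must be positive")
    planar = np.asarray(planar, float)
    return np.column_stack([np.degrees(planar[:, 0] / r_ref), planar[:, 1]])
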