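"""Synthetic ground-truth sarcomere lattices.

Generates the structures the analysis modules assume, with every generated
pose recorded, so each downstream stage can be tested against known truth:

* a three-fold-symmetric thick filament whose 430 Å axial pseudo-repeat
  contains three crown classes (layer plan P1-P3, A1-A28: 31 layers x 3 =
  93 IHMs), with per-class pose presets and optional Gaussian perturbations;
* titin chains: three alpha chains spanning the whole filament and three
  beta chains terminating at crown A1 (six chains cross a C-zone section,
  three a P-zone section);
* nine cMyBP-C stripes anchored at crown-2 layers (27 anchors under C3);
* sinuous coiled-coil tails of prescribed midline profile, for which the
  ground-truth midline is returned alongside the two chains;
* a sarcomere scene: thick filaments on a triangular lattice with hexagonal
  thin-filament interstices, flexible thick-to-thin links at 43-nm
  intervals with angles drawn from a stated normal distribution, and an
  optional mirror half about the M band.

Forward pose math here is written out as explicit rotation matrices,
independent of the analysis path in :mod:`sarcgeo.crowns`, so recovery tests
are genuine round trips.  The M band sits at z = 0 and +z is Z-ward; crown
class presets (radii, Euler offsets, triangle edge lengths) are illustrative
defaults on a plausible IHM scale, not measured values.
"""

from __future__ import annotations

import json
import math
import struct
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import FilamentTrace, LinkRecord, PointSet
from .sinuosity import Curve3D

__all__ = [
    "CrownPreset", "TitinPlan", "StripePlan", "LinkPlan", "ThinLattice",
    "NoiseSpec", "SceneSpec", "ThickFilament", "Scene",
    "canonical_triangle", "pose_triangle_vertices",
    "build_thick_filament", "build_tail_curve", "build_sarcomere_scene",
    "render_density", "write_mrc", "export_scene",
]

# ---------------------------------------------------------------------------
# elementary rotations (degrees) — deliberately hand-rolled so the forward
# pose path shares no code with the Euler extraction in crowns.py
# ---------------------------------------------------------------------------

def _rz(a):
    a = math.radians(a)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(a):
    a = math.radians(a)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rx(a):
    a = math.radians(a)
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _ref_perp(axis: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(trial, axis))) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    ref = trial - np.dot(trial, axis) * axis
    return ref / np.linalg.norm(ref)


# ---------------------------------------------------------------------------
# spec dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrownPreset:
    """Pose preset for one crown class.  Angles in degrees, lengths in Å."""
    radius: float
    azimuth_deg: float
    alpha: float
    beta: float
    gamma: float
    z_offset: float = 0.0
    edges: tuple[float, float, float] = (100.0, 95.0, 90.0)


@dataclass(frozen=True)
class TitinPlan:
    n_alpha: int = 3
    n_beta: int = 3
    beta_end_layer: str = "A1"
    radius: float = 155.0


@dataclass(frozen=True)
class StripePlan:
    """cMyBP-C stripe labels with axial anchor positions (Å)."""
    labels: tuple[str, ...] = tuple(f"S{k}" for k in range(1, 10))
    positions: tuple[float, ...] = tuple(
        ((3 * k + 1) * 430.0) / 3.0 for k in range(1, 10))
    radius: float = 145.0
    azimuth_deg: float = 40.0


@dataclass(frozen=True)
class LinkPlan:
    interval: float = 430.0
    angle_mean_deg: float = 40.0
    angle_sd_deg: float = 10.0
    n_domains: tuple[int, int] = (3, 4)
    domain_step: float = 40.0
    pivot_radius: float = 160.0
    span: Optional[tuple[float, float]] = None  # default: the C zone


@dataclass(frozen=True)
class ThinLattice:
    spacing: float = 235.0
    n_neighbours: int = 6


@dataclass(frozen=True)
class NoiseSpec:
    positional_sd: float = 0.0  # Å, isotropic rigid jitter of each triangle
    angular_sd: float = 0.0     # deg, per Euler angle

    def __post_init__(self):
        if self.positional_sd < 0 or self.angular_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def _default_presets() -> dict[int, CrownPreset]:
    # distinct radii / beta offsets so classes are distinguishable; the
    # published qualitative anchor is a strongly positive crown-2 beta
    return {
        1: CrownPreset(radius=130.0, azimuth_deg=0.0, alpha=0.0, beta=10.0, gamma=0.0),
        2: CrownPreset(radius=135.0, azimuth_deg=15.0, alpha=5.0, beta=30.0, gamma=-5.0),
        3: CrownPreset(radius=128.0, azimuth_deg=-10.0, alpha=-5.0, beta=-10.0, gamma=5.0),
    }


def _default_layers() -> tuple[str, ...]:
    return ("P1", "P2", "P3") + tuple(f"A{i}" for i in range(1, 29))


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the synthetic sarcomere; the defaults encode a relaxed
    cardiac C3 thick filament with a 430 Å repeat, 0 deg twist, 31 crown
    layers, 9 stripes and alpha/beta titin."""

    axial_repeat: float = 430.0
    crowns_per_repeat: int = 3
    rotational_symmetry: int = 3
    layer_plan: tuple[str, ...] = field(default_factory=_default_layers)
    crown_presets: dict[int, CrownPreset] = field(default_factory=_default_presets)
    twist_per_layer_deg: float = 0.0
    titin_plan: TitinPlan = TitinPlan()
    stripe_plan: StripePlan = StripePlan()
    thin_lattice: ThinLattice = ThinLattice()
    link_plan: LinkPlan = LinkPlan()
    noise: NoiseSpec = NoiseSpec()
    half_sarcomere: bool = True
    z_disc_positions: Optional[tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self):
        if self.axial_repeat <= 0:
            raise ValueError("axial_repeat must be positive")
        if self.crowns_per_repeat < 1:
            raise ValueError("crowns_per_repeat must be >= 1")
        if self.rotational_symmetry < 1:
            raise ValueError("rotational_symmetry must be >= 1")
        if len(self.layer_plan) % self.crowns_per_repeat and len(self.layer_plan) > 1:
            # tolerated, but classes then do not tile the plan evenly
            pass
        if len(self.layer_plan) < 1:
            raise ValueError("layer_plan must name at least one layer")

    @property
    def crown_spacing(self) -> float:
        return self.axial_repeat / self.crowns_per_repeat

    def layer_z(self, j: int) -> float:
        # (j * repeat) / cpr keeps multiples of the repeat exact in floats
        base = (j * self.axial_repeat) / self.crowns_per_repeat
        cls = self.layer_class(j)
        return base + self.crown_presets[cls].z_offset

    def layer_class(self, j: int) -> int:
        return (j % self.crowns_per_repeat) + 1

    @property
    def z_top(self) -> float:
        return (len(self.layer_plan) * self.axial_repeat) / self.crowns_per_repeat


# ---------------------------------------------------------------------------
# scene containers
# ---------------------------------------------------------------------------

@dataclass
class ThickFilament:
    filament_id: str
    trace: FilamentTrace
    crowns: pd.DataFrame        # ground-truth pose + landmark table
    titin: list[tuple[str, np.ndarray]]      # (kind, polyline)
    stripe_anchors: pd.DataFrame
    axis_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0., 0., 1.]))


@dataclass
class Scene:
    spec: SceneSpec
    thick: list[ThickFilament]
    thin: list[FilamentTrace]
    links: list[LinkRecord]
    m_band_z: float = 0.0
    z_disc_positions: Optional[tuple[float, float]] = None

    def ground_truth(self) -> pd.DataFrame:
        frames = []
        for f in self.thick:
            g = f.crowns.copy()
            g.insert(0, "filament_id", f.filament_id)
            frames.append(g)
        return pd.concat(frames, ignore_index=True)

    @property
    def n_crowns(self) -> int:
        return sum(len(f.crowns) for f in self.thick)

    @property
    def n_stripe_anchors(self) -> int:
        return sum(len(f.stripe_anchors) for f in self.thick)

    def titin_crossings(self, z: float) -> int:
        """Number of titin chains whose axial span contains global z,
        summed over thick filaments."""
        n = 0
        for f in self.thick:
            for _, poly in f.titin:
                lo, hi = poly[:, 2].min(), poly[:, 2].max()
                if lo <= z <= hi:
                    n += 1
        return n


# ---------------------------------------------------------------------------
# triangles and forward pose math
# ---------------------------------------------------------------------------

def canonical_triangle(edges: Sequence[float] = (100.0, 95.0, 90.0)) -> np.ndarray:
    """Vertices (free, blocked, junction) of the IHM landmark triangle in its
    canonical frame: centroid at the origin, centroid->free along +x, normal
    (free - c) x (blocked - c) along +z."""
    d_fb, d_fj, d_bj = edges
    x = (d_fb ** 2 + d_fj ** 2 - d_bj ** 2) / (2.0 * d_fb)
    y2 = d_fj ** 2 - x ** 2
    if y2 <= 0:
        raise ValueError("edge lengths violate the triangle inequality")
    v = np.array([[0.0, 0.0, 0.0],
                  [d_fb, 0.0, 0.0],
                  [x, math.sqrt(y2), 0.0]])
    v -= v.mean(axis=0)
    # spin about z so centroid->free lies along +x (normal unchanged)
    ang = math.degrees(math.atan2(v[0, 1], v[0, 0]))
    return (_rz(-ang) @ v.T).T


def pose_triangle_vertices(preset_pose: tuple[float, float, float],
                           phi: float, r: float, z: float,
                           axis_point: np.ndarray, axis_direction: np.ndarray,
                           edges: Sequence[float]) -> np.ndarray:
    """Place the canonical triangle at cylindrical coordinates (phi, r, z)
    with intrinsic Z-Y-X Euler angles relative to the local cylinder frame."""
    d = np.asarray(axis_direction, float)
    d = d / np.linalg.norm(d)
    ref = _ref_perp(d)
    t_ref = np.cross(d, ref)
    pr = math.radians(phi)
    radial = math.cos(pr) * ref + math.sin(pr) * t_ref
    centroid = np.asarray(axis_point, float) + z * d + r * radial
    y_hat = radial
    z_hat = d
    x_hat = np.cross(y_hat, z_hat)
    frame = np.column_stack([x_hat, y_hat, z_hat])
    a, b, g = preset_pose
    rot = _rz(a) @ _ry(b) @ _rx(g)
    verts = canonical_triangle(edges)
    return centroid + (frame @ rot @ verts.T).T


# ---------------------------------------------------------------------------
# thick filament
# ---------------------------------------------------------------------------

def _filament_rng(seed: int, index: int, mirrored: bool = False
                  ) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((seed, index, int(mirrored))))


def _build_thick(spec: SceneSpec, filament_id: str, origin: np.ndarray,
                 axis_sign: int, rng: np.random.Generator) -> ThickFilament:
    if len(spec.layer_plan) < spec.crowns_per_repeat and len(spec.layer_plan) > 1:
        raise ValueError("layer_plan shorter than one repeat")
    d = np.array([0.0, 0.0, float(axis_sign)])
    n_sym = spec.rotational_symmetry
    rows = []
    for j, label in enumerate(spec.layer_plan):
        cls = spec.layer_class(j)
        preset = spec.crown_presets[cls]
        z = spec.layer_z(j)
        for k in range(n_sym):
            phi = preset.azimuth_deg + 360.0 * k / n_sym \
                + spec.twist_per_layer_deg * j
            a = preset.alpha + (rng.normal(0, spec.noise.angular_sd)
                                if spec.noise.angular_sd else 0.0)
            b = preset.beta + (rng.normal(0, spec.noise.angular_sd)
                               if spec.noise.angular_sd else 0.0)
            g = preset.gamma + (rng.normal(0, spec.noise.angular_sd)
                                if spec.noise.angular_sd else 0.0)
            verts = pose_triangle_vertices((a, b, g), phi, preset.radius, z,
                                           origin, d, preset.edges)
            r_true, phi_true, z_true = preset.radius, phi, z
            if spec.noise.positional_sd:
                shift = rng.normal(0, spec.noise.positional_sd, 3)
                verts = verts + shift
                c = verts.mean(axis=0) - origin
                z_true = float(np.dot(c, d))
                perp = c - z_true * d
                r_true = float(np.linalg.norm(perp))
                ref = _ref_perp(d)
                phi_true = math.degrees(math.atan2(
                    float(np.dot(perp, np.cross(d, ref))),
                    float(np.dot(perp, ref))))
            rows.append({
                "layer": label, "crown_class": cls, "sym": k,
                "axis_sign": axis_sign,
                "alpha": a, "beta": b, "gamma": g,
                "phi": _wrap(phi_true), "r": r_true, "z": z_true,
                "fx": verts[0, 0], "fy": verts[0, 1], "fz": verts[0, 2],
                "bx": verts[1, 0], "by": verts[1, 1], "bz": verts[1, 2],
                "jx": verts[2, 0], "jy": verts[2, 1], "jz": verts[2, 2],
            })
    crowns = pd.DataFrame(rows)

    z_top = spec.z_top
    # trace along the axis, M band to tip
    n_nodes = max(int(z_top // spec.axial_repeat) + 1, 2)
    zs = np.linspace(0.0, z_top, n_nodes)
    trace = FilamentTrace(filament_id, origin + np.outer(zs, d), zward=axis_sign > 0)

    # titin: alpha chains span the filament, beta chains start at A1
    tp = spec.titin_plan
    titin: list[tuple[str, np.ndarray]] = []
    try:
        j_beta = spec.layer_plan.index(tp.beta_end_layer)
        z_beta = spec.layer_z(j_beta)
    except ValueError:
        z_beta = 0.0
    ref = _ref_perp(d)
    t_ref = np.cross(d, ref)

    def _chain(z0, z1, phi_deg):
        zz = np.linspace(z0, z1, max(int((z1 - z0) // spec.axial_repeat) + 1, 2))
        pr = math.radians(phi_deg)
        radial = math.cos(pr) * ref + math.sin(pr) * t_ref
        return origin + np.outer(zz, d) + tp.radius * radial

    for i in range(tp.n_alpha):
        titin.append(("alpha", _chain(0.0, z_top, 360.0 * i / max(tp.n_alpha, 1))))
    for i in range(tp.n_beta):
        titin.append(("beta", _chain(z_beta, z_top,
                                     60.0 + 360.0 * i / max(tp.n_beta, 1))))

    sp = spec.stripe_plan
    srows = []
    for label, zpos in zip(sp.labels, sp.positions):
        for k in range(n_sym):
            pr = math.radians(sp.azimuth_deg + 360.0 * k / n_sym)
            radial = math.cos(pr) * ref + math.sin(pr) * t_ref
            p = origin + zpos * d + sp.radius * radial
            srows.append({"stripe": label, "sym": k,
                          "x": p[0], "y": p[1], "z": p[2]})
    anchors = pd.DataFrame(srows)
    return ThickFilament(filament_id, trace, crowns, titin, anchors,
                         axis_point=np.asarray(origin, float), axis_direction=d)


def _wrap(a: float) -> float:
    a = math.fmod(a, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


def build_thick_filament(spec: SceneSpec) -> Scene:
    """Single ground-truth thick filament at the origin (+z axis)."""
    rng = _filament_rng(spec.seed, 0)
    fil = _build_thick(spec, "T0", np.zeros(3), +1, rng)
    scene = Scene(spec, [fil], [], [],
                  z_disc_positions=spec.z_disc_positions)
    if not spec.half_sarcomere:
        rng_m = _filament_rng(spec.seed, 0, mirrored=True)
        scene.thick.append(_build_thick(spec, "T0m", np.zeros(3), -1, rng_m))
    return scene


# ---------------------------------------------------------------------------
# coiled-coil tails
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TailProfile:
    amplitude: float = 0.0     # Å, lateral sinusoid amplitude
    wavelength: float = 430.0  # Å
    kink_position: Optional[float] = None  # fraction of length in (0, 1)
    kink_angle: float = 0.0    # deg

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.kink_position is not None and not (0.0 < self.kink_position < 1.0):
            raise ValueError("kink_position must lie in (0, 1)")


@dataclass(frozen=True)
class Superhelix:
    radius: float = 5.0   # Å, coiled-coil superhelical radius
    pitch: float = 140.0  # Å


def build_tail_curve(length: float, profile: TailProfile = TailProfile(),
                     superhelix: Superhelix = Superhelix(),
                     seed: int = 0, spacing: float = 1.5,
                     noise_sd: float = 0.0
                     ) -> tuple[PointSet, PointSet, Curve3D]:
    """Two coiled-coil chains winding about a prescribed midline.

    The midline runs along +z with a lateral sinusoid of the stated amplitude
    and wavelength in the x-z plane; an optional kink rotates the distal part
    of the midline by ``kink_angle`` about the y axis at the stated fraction
    of the length.  Returns (chain_a, chain_b, ground-truth midline).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    n = max(int(length / spacing), 4)
    t = np.linspace(0.0, length, n + 1)
    x = profile.amplitude * np.sin(2.0 * math.pi * t / profile.wavelength)
    mid = np.column_stack([x, np.zeros_like(t), t])
    if profile.kink_position is not None and profile.kink_angle != 0.0:
        tk = profile.kink_position * length
        i = int(np.searchsorted(t, tk))
        pivot = mid[i]
        rot = _ry(profile.kink_angle)
        mid[i:] = pivot + (rot @ (mid[i:] - pivot).T).T
    midline = Curve3D(mid)

    # parallel-transported frames along the midline
    tang = np.gradient(mid, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    normal = np.zeros_like(tang)
    n0 = np.array([1.0, 0.0, 0.0])
    n0 = n0 - np.dot(n0, tang[0]) * tang[0]
    normal[0] = n0 / np.linalg.norm(n0)
    for i in range(1, len(tang)):
        v = normal[i - 1] - np.dot(normal[i - 1], tang[i]) * tang[i]
        normal[i] = v / np.linalg.norm(v)
    binorm = np.cross(tang, normal)
    s = midline.arclengths
    theta = 2.0 * math.pi * s / superhelix.pitch
    rng = np.random.default_rng(np.random.SeedSequence((seed,)))
    chains = []
    for phase in (0.0, math.pi):
        offs = superhelix.radius * (
            np.cos(theta + phase)[:, None] * normal
            + np.sin(theta + phase)[:, None] * binorm)
        pts = mid + offs
        if noise_sd:
            pts = pts + rng.normal(0.0, noise_sd, pts.shape)
        chains.append(pts)
    ids_a = [f"A/{i}" for i in range(len(mid))]
    ids_b = [f"B/{i}" for i in range(len(mid))]
    return PointSet(ids_a, chains[0]), PointSet(ids_b, chains[1]), midline


# ---------------------------------------------------------------------------
# sarcomere scene
# ---------------------------------------------------------------------------

def _triangular_lattice(a: float, n: int) -> np.ndarray:
    """First n points of a triangular lattice, sorted by distance from the
    origin (ties broken lexicographically for determinism)."""
    m = max(2, int(math.ceil(math.sqrt(n))) + 2)
    pts = []
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            x = a * (i + 0.5 * j)
            y = a * (math.sqrt(3.0) / 2.0) * j
            pts.append((x, y))
    pts.sort(key=lambda p: (round(p[0] ** 2 + p[1] ** 2, 6), p[0], p[1]))
    return np.array(pts[:n])


def _interstitial_sites(a: float, n: int) -> np.ndarray:
    """Trigonal interstices of the triangular lattice (two per unit cell),
    where thin filaments sit; sorted by distance from the origin."""
    m = max(2, int(math.ceil(math.sqrt(n / 2.0))) + 2)
    pts = []
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            bx = a * (i + 0.5 * j)
            by = a * (math.sqrt(3.0) / 2.0) * j
            for (cx, cy) in ((0.5 * a, a / (2.0 * math.sqrt(3.0))),
                             (0.0, a / math.sqrt(3.0))):
                pts.append((bx + cx, by + cy))
    uniq = sorted({(round(x, 6), round(y, 6)) for x, y in pts},
                  key=lambda p: (round(p[0] ** 2 + p[1] ** 2, 6), p[0], p[1]))
    return np.array(uniq[:n])


def build_sarcomere_scene(spec: SceneSpec, n_thick: int = 7,
                          n_thin: int = 14) -> Scene:
    """Thick filaments on a triangular lattice with thin filaments at the
    hexagonal interstices, cMyBP-C links every link interval, and a mirror
    half about the M band unless ``spec.half_sarcomere``."""
    if spec.link_plan is not None and n_thin < 1:
        raise ValueError("link plan requires at least one thin filament")
    a = spec.thin_lattice.spacing * math.sqrt(3.0)
    thick_xy = _triangular_lattice(a, n_thick)
    thin_xy = _interstitial_sites(a, n_thin)

    z_lo = -spec.z_top if not spec.half_sarcomere else 0.0
    thin = []
    for i, (x, y) in enumerate(thin_xy):
        zz = np.linspace(z_lo, spec.z_top, max(
            int((spec.z_top - z_lo) // spec.axial_repeat) + 1, 2))
        pts = np.column_stack([np.full_like(zz, x), np.full_like(zz, y), zz])
        thin.append(FilamentTrace(f"t{i}", pts, zward=True))

    thick = []
    for i, (x, y) in enumerate(thick_xy):
        origin = np.array([x, y, 0.0])
        rng = _filament_rng(spec.seed, i)
        thick.append(_build_thick(spec, f"T{i}", origin, +1, rng))
        if not spec.half_sarcomere:
            rng_m = _filament_rng(spec.seed, i, mirrored=True)
            thick.append(_build_thick(spec, f"T{i}m", origin, -1, rng_m))

    links = _build_links(spec, thick, thin)
    return Scene(spec, thick, thin, links,
                 z_disc_positions=spec.z_disc_positions)


def _build_links(spec: SceneSpec, thick: list[ThickFilament],
                 thin: list[FilamentTrace]) -> list[LinkRecord]:
    lp = spec.link_plan
    if lp is None or not thin:
        return []
    try:
        j_a1 = spec.layer_plan.index("A1")
        z_c0 = spec.layer_z(j_a1)
    except ValueError:
        z_c0 = 0.0
    span = lp.span if lp.span is not None else (z_c0, spec.z_top)
    count = int(math.floor((span[1] - span[0]) / lp.interval))
    links: list[LinkRecord] = []
    thin_xy = np.array([t.points[0, :2] for t in thin])
    for fi, fil in enumerate(thick):
        rng = np.random.default_rng(
            np.random.SeedSequence((spec.seed, 7919, fi)))
        origin_xy = fil.axis_point[:2]
        j_near = int(np.argmin(np.linalg.norm(thin_xy - origin_xy, axis=1)))
        target = thin[j_near]
        radial = thin_xy[j_near] - origin_xy
        nr = np.linalg.norm(radial)
        radial = radial / nr if nr > 0 else np.array([1.0, 0.0])
        radial3 = np.array([radial[0], radial[1], 0.0])
        sign = 1.0 if fil.axis_direction[2] > 0 else -1.0
        for k in range(count):
            z = sign * (span[0] + k * lp.interval)
            pivot = np.array([*(origin_xy + lp.pivot_radius * radial), z])
            theta = rng.normal(lp.angle_mean_deg, lp.angle_sd_deg)
            nd = int(rng.integers(lp.n_domains[0], lp.n_domains[1] + 1))
            tr = math.radians(theta)
            direction = math.sin(tr) * radial3 + math.cos(tr) * np.array(
                [0.0, 0.0, sign])
            pts = pivot + np.outer(np.arange(1, nd + 1) * lp.domain_step,
                                   direction)
            links.append(LinkRecord(pivot, pts, fil.filament_id,
                                    target.filament_id, angle_deg=theta))
    return links


# ---------------------------------------------------------------------------
# coarse density rendering
# ---------------------------------------------------------------------------

def _scene_points(scene: Scene) -> np.ndarray:
    pts = []
    for f in scene.thick:
        pts.append(f.crowns[["fx", "fy", "fz"]].to_numpy())
        pts.append(f.crowns[["bx", "by", "bz"]].to_numpy())
        pts.append(f.crowns[["jx", "jy", "jz"]].to_numpy())
        if len(f.stripe_anchors):
            pts.append(f.stripe_anchors[["x", "y", "z"]].to_numpy())
    for t in scene.thin:
        pts.append(t.points)
    return np.vstack(pts)


def render_density(scene: Scene, voxel: float, sigma: float,
                   max_voxels: int = 64_000_000
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Sum of isotropic Gaussian blobs at the scene landmark points on a
    regular grid.  Returns (volume[z, y, x], origin Å)."""
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    pts = _scene_points(scene)
    pad = 4.0 * sigma
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    shape = np.ceil((hi - lo) / voxel).astype(int) + 1
    if int(np.prod(shape)) > max_voxels:
        raise MemoryError(
            f"grid {tuple(shape)} exceeds the {max_voxels}-voxel cap; "
            "use a larger voxel size")
    vol = np.zeros(shape[::-1], dtype=np.float32)  # z, y, x
    rad = int(math.ceil(4.0 * sigma / voxel))
    axes = np.arange(-rad, rad + 1)
    zz, yy, xx = np.meshgrid(axes, axes, axes, indexing="ij")
    for p in pts:
        idx = (p - lo) / voxel
        i0 = np.round(idx).astype(int)
        frac = idx - i0
        g = np.exp(-(((xx - frac[0]) ** 2 + (yy - frac[1]) ** 2
                      + (zz - frac[2]) ** 2) * voxel ** 2)
                   / (2.0 * sigma ** 2))
        sl = tuple(slice(i0[2 - k] - rad, i0[2 - k] + rad + 1) for k in range(3))
        if any(s.start < 0 or s.stop > vol.shape[d] for d, s in enumerate(sl)):
            continue  # padded box keeps this from happening in practice
        vol[sl] += g.astype(np.float32)
    return vol, lo


def write_mrc(volume: np.ndarray, voxel: float, path: str | Path) -> None:
    """Minimal MRC2014 writer (mode 2, float32, little-endian)."""
    vol = np.ascontiguousarray(volume, dtype="<f4")
    nz, ny, nx = vol.shape
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, 2)                      # mode
    struct.pack_into("<3i", header, 28, nx, ny, nz)            # mx,my,mz
    struct.pack_into("<3f", header, 40, nx * voxel, ny * voxel, nz * voxel)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)               # mapc,r,s
    struct.pack_into("<3f", header, 76, float(vol.min()), float(vol.max()),
                     float(vol.mean()))
    struct.pack_into("<i", header, 88, 1)                      # ispg
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])          # little-endian
    struct.pack_into("<f", header, 216, float(vol.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(vol.tobytes())


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_scene(scene: Scene, out_dir: str | Path) -> None:
    """Ground-truth TSV tables plus a JSON echo of the generating spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene.ground_truth().to_csv(out / "crowns.tsv", sep="\t", index=False)
    rows = []
    for f in scene.thick:
        for kind, poly in f.titin:
            for p in poly:
                rows.append({"filament_id": f.filament_id, "kind": kind,
                             "x": p[0], "y": p[1], "z": p[2]})
    pd.DataFrame(rows).to_csv(out / "titin.tsv", sep="\t", index=False)
    lrows = []
    for ln in scene.links:
        lrows.append({"thick_id": ln.thick_id, "thin_id": ln.thin_id,
                      "px": ln.pivot[0], "py": ln.pivot[1], "pz": ln.pivot[2],
                      "angle_deg": ln.angle_deg,
                      "n_domains": len(ln.domain_points)})
    pd.DataFrame(lrows).to_csv(out / "links.tsv", sep="\t", index=False)
    blob = asdict(scene.spec)
    blob["crown_presets"] = {str(k): asdict(v)
                             for k, v in scene.spec.crown_presets.items()}
    (out / "scene_spec.json").write_text(json.dumps(blob, indent=1, default=str))
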