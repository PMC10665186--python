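"""Coiled-coil midline tracing and the sinuosity / SCP statistic.

A myosin tail is a two-chain coiled coil.  Its midline is the 3D curve through
the midpoints of corresponding alpha-carbon couples of the two chains.  For a
curve (or a windowed sub-curve) the sinuosity is

    S = C / L,

the ratio of curve length C to the Euclidean end-to-end distance L, and the
sinusoidal compression percentage is

    SCP = (S - 1) x 100,

so a straight tail scores 0 and increasingly undulating tails score higher.
Arc length is the polyline sum over the traced midpoints — no spline is
fitted; resampling happens only inside :func:`curvature_profile`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .io import PointSet

__all__ = [
    "Curve3D", "SinuosityResult",
    "coiled_coil_midline", "sinuosity", "scp_profile", "curvature_profile",
    "resample_curve",
]


@dataclass
class Curve3D:
    """An ordered 3D polyline (Å) with cumulative arc length per point."""

    points: np.ndarray  # (n, 3)

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValueError("curve needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("curve contains non-finite coordinates")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("arc length must be strictly increasing")
        self.arclengths = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclengths[-1])

    def subcurve(self, start: float, end: float) -> "Curve3D":
        """Sub-curve between two arc-length positions (endpoints
        interpolated on the polyline)."""
        if not (0.0 <= start < end <= self.length + 1e-9):
            raise ValueError("window outside curve extent")
        cs = self.arclengths
        i0 = int(np.searchsorted(cs, start, side="right"))
        i1 = int(np.searchsorted(cs, end, side="left"))
        pts = [self._point_at(start)] + list(self.points[i0:i1]) + [self._point_at(end)]
        arr = np.array(pts)
        keep = np.r_[True, np.linalg.norm(np.diff(arr, axis=0), axis=1) > 1e-12]
        return Curve3D(arr[keep])

    def _point_at(self, s: float) -> np.ndarray:
        cs = self.arclengths
        s = float(np.clip(s, 0, cs[-1]))
        i = min(int(np.searchsorted(cs, s, side="right") - 1), len(cs) - 2)
        f = (s - cs[i]) / (cs[i + 1] - cs[i])
        return (1 - f) * self.points[i] + f * self.points[i + 1]


@dataclass
class SinuosityResult:
    C: float                 # curve length, Å
    L: float                 # end-to-end distance, Å
    S: float                 # sinuosity, dimensionless
    SCP: float               # (S - 1) * 100, percent
    window: Optional[tuple[float, float]] = None


def coiled_coil_midline(chain_a: PointSet, chain_b: PointSet,
                        offset: int = 0) -> Curve3D:
    """Midline through the midpoints of alpha-carbon couples.

    Couples are (A_i, B_{i+offset}) by sequence index, truncated to the
    common range; heptad-register estimation is deliberately not attempted.
    """
    a = chain_a.coords
    b = chain_b.coords
    if offset >= 0:
        n = min(len(a), len(b) - offset)
        couples = (a[:n], b[offset:offset + n])
    else:
        n = min(len(a) + offset, len(b))
        couples = (a[-offset:-offset + n], b[:n])
    if n < 2:
        raise ValueError("fewer than 2 alpha-carbon couples after pairing")
    mid = 0.5 * (couples[0] + couples[1])
    keep = np.r_[True, np.linalg.norm(np.diff(mid, axis=0), axis=1) > 1e-12]
    return Curve3D(mid[keep])


def sinuosity(curve: Curve3D,
              window: Optional[tuple[float, float]] = None) -> SinuosityResult:
    """Sinuosity S = C/L and SCP = (S-1)x100 of a curve or windowed
    sub-curve.  Near-closed curves (L < 1 Å) are rejected: the statistic is
    unstable there."""
    sub = curve if window is None else curve.subcurve(*window)
    C = sub.length
    L = float(np.linalg.norm(sub.points[-1] - sub.points[0]))
    if L < 1.0:
        raise ValueError("end-to-end distance below 1 Å; sinuosity unstable")
    S = C / L
    return SinuosityResult(C, L, S, (S - 1.0) * 100.0, window)


def scp_profile(curve: Curve3D, window_len: float,
                step: float) -> list[SinuosityResult]:
    """SCP in sliding arc-length windows of length ``window_len`` advanced by
    ``step``; the final window is anchored at the curve end."""
    if step <= 0:
        raise ValueError("step must be positive")
    if window_len > curve.length:
        raise ValueError("window_len exceeds curve length")
    out = []
    s = 0.0
    last_start = curve.length - window_len
    while True:
        start = min(s, last_start)
        out.append(sinuosity(curve, (start, start + window_len)))
        if start >= last_start - 1e-9:
            break
        s += step
    return out


def resample_curve(curve: Curve3D, spacing: float) -> Curve3D:
    """Even arc-length resampling (linear interpolation on the polyline)."""
    n = max(int(round(curve.length / spacing)), 2)
    s = np.linspace(0.0, curve.length, n + 1)
    pts = np.column_stack([
        np.interp(s, curve.arclengths, curve.points[:, k]) for k in range(3)])
    return Curve3D(pts)


def curvature_profile(curve: Curve3D, smoothing_len: float,
                      prominence: float = 1e-4
                      ) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    """Discrete curvature along the curve and its prominent maxima.

    The curve is resampled at ``smoothing_len`` arc spacing, then the
    curvature at each interior point is that of the circle through the point
    and its two neighbours (Menger curvature, kappa = 4*Area/(a*b*c)).

    Returns ``(arc_positions, curvature, maxima)`` where maxima is a list of
    ``(arc_position, curvature)`` sorted by descending curvature.
    """
    if len(curve.points) < 3:
        raise ValueError("need at least 3 points for curvature")
    spacing = np.diff(curve.arclengths)
    if smoothing_len < float(np.median(spacing)):
        raise ValueError("smoothing_len below the median point spacing")
    rs = resample_curve(curve, smoothing_len)
    p = rs.points
    a = np.linalg.norm(p[1:-1] - p[:-2], axis=1)
    b = np.linalg.norm(p[2:] - p[1:-1], axis=1)
    c = np.linalg.norm(p[2:] - p[:-2], axis=1)
    cross = np.linalg.norm(np.cross(p[1:-1] - p[:-2], p[2:] - p[:-2]), axis=1)
    kappa = 2.0 * cross / (a * b * c)
    s = rs.arclengths[1:-1]
    idx, _ = find_peaks(kappa, prominence=prominence)
    maxima = sorted(((float(s[i]), float(kappa[i])) for i in idx),
                    key=lambda t: -t[1])
    return s, kappa, maxima
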