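"""Axial periodicity spectra, pixel-size calibration, cMyBP-C link angles
and scene census statistics.

The canonical use: the myosin crown lattice repeats every 143.3 Å axially
(three crowns per 430 Å pseudo-repeat); the position of that peak in a power
spectrum measured in pixels calibrates the pixel size of a reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .crowns import CylinderModel
from .io import LinkRecord

__all__ = [
    "Spectrum", "LinkRecord",
    "axial_power_spectrum", "profile_power_spectrum", "calibrate_pixel_size",
    "link_angle", "link_angle_distribution", "scene_census",
]

MYOSIN_CROWN_PERIOD_A = 143.3  # published crown repeat used for calibration


@dataclass
class Spectrum:
    """1D power spectrum over a period grid (descending, same units as the
    input positions)."""

    period: np.ndarray
    power: np.ndarray
    dominant_period: float
    peak_meta: dict = field(default_factory=dict)


def _spectrum(values: np.ndarray, sample_spacing: float, data_extent: float,
              pad_factor: int) -> Spectrum:
    values = np.asarray(values, float)
    values = values - values.mean()
    if not np.any(values):
        raise ValueError("flat profile: no periodicity to measure")
    n_fft = int(len(values) * max(pad_factor, 1))
    power = np.abs(np.fft.rfft(values, n=n_fft)) ** 2
    freq = np.fft.rfftfreq(n_fft, d=sample_spacing)
    # exclude DC and periods longer than half the box
    valid = freq > 2.0 / data_extent
    if not np.any(valid & (power > 0)):
        raise ValueError("no non-DC power in the valid period range")
    idx = int(np.argmax(np.where(valid, power, -np.inf)))
    # three-point parabolic interpolation in log power
    delta = 0.0
    if 0 < idx < len(power) - 1 and power[idx - 1] > 0 and power[idx + 1] > 0:
        la, lb, lc = np.log(power[idx - 1: idx + 2])
        denom = la - 2.0 * lb + lc
        if denom != 0:
            delta = 0.5 * (la - lc) / denom
    f_peak = freq[idx] + delta * (freq[1] - freq[0])
    dom = 1.0 / f_peak
    with np.errstate(divide="ignore"):
        period = np.where(freq > 0, 1.0 / freq, np.inf)
    return Spectrum(period[valid][::-1].copy(), power[valid][::-1].copy(),
                    float(dom),
                    {"peak_index": idx, "interp_delta": float(delta),
                     "frequency": float(f_peak)})


def axial_power_spectrum(z_positions: Sequence[float],
                         box_length: Optional[float] = None,
                         pad_factor: int = 8,
                         bin_size: float = 2.0) -> Spectrum:
    """Power spectrum of a set of axial impulse positions (Å).

    The impulses are binned onto a regular grid (bin <= 2 Å), mean
    subtracted, Fourier transformed with zero padding, and the dominant
    period read off the largest non-DC peak with parabolic interpolation.
    """
    z = np.asarray(z_positions, float)
    if len(np.unique(z)) < 2:
        raise ValueError("need at least 2 distinct positions")
    bin_size = min(bin_size, 2.0)
    if box_length is None:
        box_length = float(z.max() - z.min()) + bin_size
    if box_length <= 0:
        raise ValueError("box_length must be positive")
    n_bins = int(math.ceil(box_length / bin_size))
    hist, _ = np.histogram(z - z.min(), bins=n_bins, range=(0.0, box_length))
    return _spectrum(hist.astype(float), bin_size, box_length, pad_factor)


def profile_power_spectrum(values: Sequence[float], sample_spacing: float = 1.0,
                           pad_factor: int = 8) -> Spectrum:
    """Power spectrum of a regularly sampled 1D density profile; the period
    grid is in the units of ``sample_spacing`` (e.g. pixels)."""
    values = np.asarray(values, float)
    if len(values) < 4:
        raise ValueError("need at least 4 samples")
    extent = len(values) * sample_spacing
    return _spectrum(values, sample_spacing, extent, pad_factor)


def calibrate_pixel_size(measured_period_px: float,
                         reference_period_A: float = MYOSIN_CROWN_PERIOD_A
                         ) -> float:
    """Å per pixel from a measured period in pixels and its physical
    reference value (default: the 143.3 Å crown repeat)."""
    if measured_period_px <= 0 or reference_period_A <= 0:
        raise ValueError("periods must be positive")
    return reference_period_A / measured_period_px


# ---------------------------------------------------------------------------
# cMyBP-C links
# ---------------------------------------------------------------------------

def link_angle(link: LinkRecord, cylinder: CylinderModel,
               fold: bool = False, segment: int = -1) -> float:
    """Angle (deg) between a link and the thick-filament axis, with the C7
    pivot as origin.  By default the terminal (thin-filament-proximal)
    domain point defines the link vector; ``segment`` selects another.
    ``fold`` maps the result onto [0, 90]."""
    v = link.domain_points[segment] - link.pivot
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("zero-length link vector")
    cosang = float(np.dot(v / n, cylinder.axis_direction))
    ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    if ang >= 180.0:
        ang = 0.0
    return min(ang, 180.0 - ang) if fold else ang


def link_angle_distribution(links: Sequence[LinkRecord] | Sequence[float],
                            cylinder: Optional[CylinderModel] = None,
                            bin_width: float = 5.0, fold: bool = False
                            ) -> tuple[pd.DataFrame, dict]:
    """Histogram and summary of link angles.

    Accepts measured angles directly or LinkRecords (whose stored angle is
    used when present, otherwise measured against ``cylinder``).  The
    summary always reports n; the ``circular`` flag reminds that linear
    mean/sd are approximations for angular data near the wrap point.
    """
    if len(links) < 1:
        raise ValueError("need at least one link")
    angles = []
    for ln in links:
        if isinstance(ln, LinkRecord):
            if ln.angle_deg is not None:
                angles.append(float(ln.angle_deg))
            elif cylinder is not None:
                angles.append(link_angle(ln, cylinder, fold=fold))
            else:
                raise ValueError("LinkRecord without angle needs a cylinder")
        else:
            angles.append(float(ln))
    angles = np.asarray(angles)
    lo = math.floor(angles.min() / bin_width) * bin_width
    hi = math.ceil(angles.max() / bin_width) * bin_width
    hi = max(hi, lo + bin_width)
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(angles, bins=edges)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})
    summary = {
        "n": int(len(angles)),
        "mean": float(angles.mean()),
        "sd": float(angles.std(ddof=1)) if len(angles) > 1 else 0.0,
        "circular": bool(angles.max() - angles.min() > 180.0),
    }
    return hist, summary


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def scene_census(scene) -> dict:
    """Raw composition counts of a synthetic scene.

    Reports filament counts and their raw quotient (3 significant figures),
    total crowns and stripe anchors, titin chains crossing representative
    P-zone and C-zone cross-sections, and the sarcomere length (µm) when
    both Z-disc planes are present.
    """
    spec = scene.spec
    try:
        j_a1 = spec.layer_plan.index("A1")
        z_a1 = spec.layer_z(j_a1)
    except ValueError:
        z_a1 = spec.z_top / 4.0
    z_p = 0.5 * z_a1
    z_c = 0.5 * (z_a1 + spec.z_top)
    n_thick = len(scene.thick)
    n_thin = len(scene.thin)
    out = {
        "n_thick": n_thick,
        "n_thin": n_thin,
        "thin_thick_quotient": _round_sig(n_thin / n_thick) if n_thick else math.nan,
        "n_crowns": scene.n_crowns,
        "n_stripe_anchors": scene.n_stripe_anchors,
        "titin_chains_c_zone": scene.titin_crossings(z_c),
        "titin_chains_p_zone": scene.titin_crossings(z_p),
        "n_links": len(scene.links),
    }
    zd = scene.z_disc_positions
    if zd is not None:
        out["sarcomere_length_um"] = abs(zd[1] - zd[0]) / 1.0e4
    return out
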