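"""Particle bookkeeping: resampling, axial shifts, dedup, symmetry."""

import math

import numpy as np
import pytest

from sarcgeo.crowns import CylinderModel
from sarcgeo.io import FilamentTrace, ParticleRecord, PointSet
from sarcgeo.lattice import (SymmetryOp, axial_shift, expand_symmetry,
                             remove_duplicates, resample_trace)


def _straight_trace(length=1000.0, n=11, fid="f"):
    z = np.linspace(0, length, n)
    return FilamentTrace(fid, np.column_stack([np.zeros(n), np.zeros(n), z]))


def _quarter_circle_trace(r=500.0, n=400, fid="q"):
    t = np.linspace(0, np.pi / 2, n)
    return FilamentTrace(fid, np.column_stack([r * np.cos(t), r * np.sin(t),
                                               np.zeros(n)]))


class TestResampleTrace:
    def test_straight_trace_regular_spacing(self):
        trace = _straight_trace(100.0, 5)
        recs = resample_trace(trace, 18.0)
        assert len(recs) == 6
        np.testing.assert_allclose([r.position[2] for r in recs],
                                   [0, 18, 36, 54, 72, 90])

    def test_quarter_circle_arc_positions(self):
        r, s = 500.0, 50.0
        trace = _quarter_circle_trace(r=r, n=20000)
        recs = resample_trace(trace, s)
        # oracle: closed-form arc position -> angle s*k/r
        for k, rec in enumerate(recs):
            ang = s * k / r
            np.testing.assert_allclose(rec.position[:2],
                                       [r * math.cos(ang), r * math.sin(ang)],
                                       atol=1e-3)

    def test_consecutive_arc_separation(self):
        trace = _quarter_circle_trace(n=40000)
        recs = resample_trace(trace, 30.0)
        cs = trace.arclengths
        for a, b in zip(recs[:-1], recs[1:]):
            # both lie on the polyline; their arc positions differ by 30
            assert np.linalg.norm(b.position - a.position) <= 30.0 + 1e-6

    def test_spacing_exceeding_length_gives_flagged_single(self):
        trace = _straight_trace(100.0)
        recs = resample_trace(trace, 130.0)
        assert len(recs) == 1
        assert recs[0].class_label == "short-trace"

    def test_orientation_tangent_convention(self):
        recs = resample_trace(_straight_trace(), 100.0)
        ori = recs[0].orientation
        assert np.isnan(ori[0])      # in-plane spin undefined
        assert ori[1] == pytest.approx(0.0)  # tilt 0 for +z tangent


class TestAxialShift:
    def test_straight_zward_shift(self):
        trace = _straight_trace(2000.0)
        rec = ParticleRecord("f", 1, [0.0, 0.0, 0.0])
        moved, report = axial_shift([rec], {"f": trace}, 430.0, "zward")
        assert report.n_dropped == 0
        np.testing.assert_allclose(moved[0].position, [0, 0, 430.0],
                                   atol=1e-9)

    def test_shift_off_the_end_drops_and_reports(self):
        trace = _straight_trace(1000.0)
        rec = ParticleRecord("f", 1, [0.0, 0.0, 800.0])
        moved, report = axial_shift([rec], {"f": trace}, 430.0, "zward")
        assert moved == []
        assert report.n_dropped == 1

    def test_mward_respects_trace_polarity(self):
        trace = _straight_trace(1000.0)
        rec = ParticleRecord("f", 1, [0.0, 0.0, 500.0])
        moved, _ = axial_shift([rec], {"f": trace}, 200.0, "mward")
        assert moved[0].position[2] == pytest.approx(300.0)

    def test_curved_trace_shift_is_arc_length(self):
        r = 500.0
        trace = _quarter_circle_trace(r=r, n=50000)
        start = trace.points[0]
        rec = ParticleRecord("q", 1, start)
        moved, _ = axial_shift([rec], {"q": trace}, 430.0, "zward")
        ang = 430.0 / r
        np.testing.assert_allclose(moved[0].position[:2],
                                   [r * math.cos(ang), r * math.sin(ang)],
                                   atol=1e-3)

    def test_round_trip_returns_interior_anchor(self):
        for trace in (_straight_trace(3000.0), _quarter_circle_trace(700.0,
                                                                     60000)):
            s0 = trace.point_at(trace.length / 2)
            rec = ParticleRecord(trace.filament_id, 1, s0)
            fwd, _ = axial_shift([rec], {trace.filament_id: trace},
                                 300.0, "zward")
            back, _ = axial_shift(fwd, {trace.filament_id: trace},
                                  300.0, "mward")
            np.testing.assert_allclose(back[0].position, s0, atol=1e-5)

    def test_missing_trace_names_filament(self):
        rec = ParticleRecord("ghost", 1, [0, 0, 0])
        with pytest.raises(KeyError, match="ghost"):
            axial_shift([rec], {}, 430.0)


class TestRemoveDuplicates:
    def test_close_pair_collapses(self):
        recs = [ParticleRecord("f", 1, [0, 0, 0], score=1.0),
                ParticleRecord("f", 2, [10, 0, 0], score=0.5)]
        kept = remove_duplicates(recs, 50.0)
        assert len(kept) == 1
        assert kept[0].score == 1.0

    def test_all_far_apart_all_kept(self):
        recs = [ParticleRecord("f", i, [i * 100.0, 0, 0]) for i in range(5)]
        assert len(remove_duplicates(recs, 50.0)) == 5

    def test_matches_brute_force_reference(self, rng):
        recs = [ParticleRecord("f", i, rng.uniform(0, 500, 3),
                               score=float(rng.uniform()))
                for i in range(500)]
        min_dist = 40.0
        kept = remove_duplicates(recs, min_dist, keep="best-score")
        # independent O(n^2) greedy reference
        order = sorted(range(len(recs)),
                       key=lambda i: (-recs[i].score, i))
        ref = []
        for i in order:
            p = recs[i].position
            if all(np.linalg.norm(p - recs[j].position) >= min_dist
                   for j in ref):
                ref.append(i)
        assert [id(k) for k in kept] == [id(recs[i]) for i in ref]

    def test_output_min_pairwise_distance(self, rng):
        recs = [ParticleRecord("f", i, rng.uniform(0, 300, 3))
                for i in range(200)]
        kept = remove_duplicates(recs, 60.0, keep="first")
        pos = np.array([k.position for k in kept])
        from scipy.spatial.distance import pdist
        assert pdist(pos).min() >= 60.0


class TestExpandSymmetry:
    def _axis(self):
        return CylinderModel(np.zeros(3), np.array([0.0, 0.0, 1.0]))

    def test_helical_rise_no_twist(self):
        rec = ParticleRecord("f", 1, [130.0, 0, 0])
        op = SymmetryOp("helical", self._axis(), rise=430.0, twist=0.0)
        out = expand_symmetry([rec], op, n_copies=4)
        np.testing.assert_allclose([r.position[2] for r in out],
                                   [0, 430, 860, 1290])
        # azimuth unchanged
        assert all(r.position[0] == pytest.approx(130.0) for r in out)

    def test_helical_twist(self):
        rec = ParticleRecord("f", 1, [130.0, 0, 0])
        op = SymmetryOp("helical", self._axis(), rise=0.0, twist=120.0)
        out = expand_symmetry([rec], op, n_copies=3)
        phis = [math.degrees(math.atan2(r.position[1], r.position[0])) % 360
                for r in out]
        np.testing.assert_allclose(phis, [0, 120, 240], atol=1e-9)

    def test_c3_triples_count(self):
        pts = PointSet(["a", "b"], [[130.0, 0, 0], [0, 130.0, 100.0]])
        op = SymmetryOp("Cn", self._axis(), n=3)
        assert len(expand_symmetry(pts, op)) == 6

    def test_c3_and_helical_commute(self):
        rec = ParticleRecord("f", 1, [130.0, 10.0, 5.0],
                             [10.0, 20.0, 30.0])
        c3 = SymmetryOp("Cn", self._axis(), n=3)
        hel = SymmetryOp("helical", self._axis(), rise=430.0, twist=40.0)
        a = expand_symmetry(expand_symmetry([rec], c3), hel, n_copies=3)
        b = expand_symmetry(expand_symmetry([rec], hel, n_copies=3), c3)
        pa = sorted(tuple(np.round(r.position, 9)) for r in a)
        pb = sorted(tuple(np.round(r.position, 9)) for r in b)
        assert pa == pb

    def test_dn_doubles_cn_and_requires_perp_axis(self):
        rec = ParticleRecord("f", 1, [130.0, 0, 50.0])
        axis = self._axis()
        with pytest.raises(ValueError, match="perpendicular"):
            expand_symmetry([rec], SymmetryOp("Dn", axis, n=3))
        op = SymmetryOp("Dn", axis, n=3, perp_axis=[1.0, 0.0, 0.0])
        out = expand_symmetry([rec], op)
        assert len(out) == 6
        zs = sorted(round(r.position[2], 6) for r in out)
        assert zs[:3] == [-50.0] * 3  # flipped copies below the equator

    def test_orientation_composed_with_symmetry_rotation(self):
        from scipy.spatial.transform import Rotation
        rec = ParticleRecord("f", 1, [130.0, 0, 0], [10.0, 20.0, 30.0])
        op = SymmetryOp("Cn", self._axis(), n=2)
        out = expand_symmetry([rec], op)
        r0 = Rotation.from_euler("ZYZ", out[0].orientation, degrees=True)
        r1 = Rotation.from_euler("ZYZ", out[1].orientation, degrees=True)
        rel = r1 * r0.inv()
        np.testing.assert_allclose(rel.magnitude(), np.pi, atol=1e-9)

    def test_helical_needs_motion(self):
        with pytest.raises(ValueError):
            SymmetryOp("helical", self._axis(), rise=0.0, twist=0.0)
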