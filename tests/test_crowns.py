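"""Crown pose quantification: axis fits, Euler extraction, series stats."""

import numpy as np
import pytest

from sarcgeo import SceneSpec, build_thick_filament
from sarcgeo.crowns import (CylinderModel, IHMLandmarks, classify_crowns,
                            crown_pose, crown_series_stats,
                            fit_filament_axis, reroll, unroll)
from sarcgeo.io import PointSet
from sarcgeo.synth import pose_triangle_vertices

from conftest import random_rigid_transform

Z = np.array([0.0, 0.0, 1.0])


def _landmarks_from_vertices(v):
    return IHMLandmarks(v[0], v[1], v[2])


def _pose_landmarks(euler, phi, r, z, axis_point=(0, 0, 0), axis_dir=Z,
                    edges=(100.0, 95.0, 90.0)):
    v = pose_triangle_vertices(euler, phi, r, z, np.asarray(axis_point, float),
                               np.asarray(axis_dir, float), edges)
    return _landmarks_from_vertices(v)


class TestFitFilamentAxis:
    def test_points_on_z_axis(self):
        pts = PointSet([str(i) for i in range(5)],
                       np.column_stack([np.zeros(5), np.zeros(5),
                                        np.arange(5.0) * 100]))
        cyl = fit_filament_axis(pts)
        np.testing.assert_allclose(np.abs(cyl.axis_direction), [0, 0, 1],
                                   atol=1e-12)
        assert not cyl.warnings

    def test_helix_recovers_axis_within_half_degree(self, rng):
        t = np.linspace(0, 20 * np.pi, 50)  # 10 repeats of a 430 Å pitch
        true_dir = np.array([0.2, -0.1, 1.0])
        true_dir /= np.linalg.norm(true_dir)
        rot, _ = random_rigid_transform(rng)
        # helix about true_dir: build in frame then rotate
        base = np.column_stack([130 * np.cos(t), 130 * np.sin(t),
                                t * 430 / (2 * np.pi)])
        ref = np.cross(true_dir, [1.0, 0, 0])
        ref /= np.linalg.norm(ref)
        frame = np.column_stack([ref, np.cross(true_dir, ref), true_dir])
        pts = (frame @ base.T).T
        cyl = fit_filament_axis(pts)
        cos = abs(np.dot(cyl.axis_direction, true_dir))
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 0.5

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            fit_filament_axis(np.zeros((3, 3)))  # coincident points

    def test_isotropic_cloud_flagged(self, rng):
        pts = rng.normal(size=(200, 3))
        cyl = fit_filament_axis(pts)
        assert cyl.warnings


class TestCrownPose:
    def test_identity_pose(self, z_axis_cylinder):
        lm = _pose_landmarks((0.0, 0.0, 0.0), 0.0, 130.0, 50.0)
        p = crown_pose(lm, z_axis_cylinder)
        assert p.alpha == pytest.approx(0.0, abs=1e-9)
        assert p.beta == pytest.approx(0.0, abs=1e-9)
        assert p.gamma == pytest.approx(0.0, abs=1e-9)
        assert p.r == pytest.approx(130.0, abs=1e-9)
        assert p.phi == pytest.approx(0.0, abs=1e-9)
        assert p.z == pytest.approx(50.0, abs=1e-9)

    def test_rotation_about_axis_preserves_euler_angles(self, z_axis_cylinder):
        e = (10.0, -25.0, 5.0)
        p0 = crown_pose(_pose_landmarks(e, 0.0, 130.0, 0.0), z_axis_cylinder)
        p1 = crown_pose(_pose_landmarks(e, 120.0, 130.0, 0.0), z_axis_cylinder)
        for name in ("alpha", "beta", "gamma", "r"):
            assert getattr(p1, name) == pytest.approx(getattr(p0, name),
                                                      abs=1e-9)
        assert (p1.phi - p0.phi) % 360 == pytest.approx(120.0, abs=1e-9)

    @pytest.mark.parametrize("euler", [
        (10.0, -25.0, 5.0), (0.0, 30.0, 0.0), (-170.0, 60.0, 170.0),
        (45.0, -89.0, 45.0),
    ])
    def test_round_trip_recovery(self, euler, z_axis_cylinder):
        lm = _pose_landmarks(euler, 33.0, 131.5, 77.0)
        p = crown_pose(lm, z_axis_cylinder)
        assert p.alpha == pytest.approx(euler[0], abs=1e-6)
        assert p.beta == pytest.approx(euler[1], abs=1e-6)
        assert p.gamma == pytest.approx(euler[2], abs=1e-6)

    def test_generator_presets_recovered_exactly(self, single_filament,
                                                 z_axis_cylinder):
        g = single_filament.ground_truth()
        for row in g.itertuples():
            lm = IHMLandmarks((row.fx, row.fy, row.fz),
                              (row.bx, row.by, row.bz),
                              (row.jx, row.jy, row.jz))
            p = crown_pose(lm, z_axis_cylinder)
            assert p.alpha == pytest.approx(row.alpha, abs=1e-6)
            assert p.beta == pytest.approx(row.beta, abs=1e-6)
            assert p.gamma == pytest.approx(row.gamma, abs=1e-6)
            assert p.r == pytest.approx(row.r, abs=1e-6)
            assert p.z == pytest.approx(row.z, abs=1e-6)

    def test_rigid_motion_equivariance(self, rng, z_axis_cylinder):
        e, phi, r, z = (12.0, -40.0, 61.0), 25.0, 133.0, 210.0
        p0 = crown_pose(_pose_landmarks(e, phi, r, z), z_axis_cylinder)
        for _ in range(5):
            rot, trans = random_rigid_transform(rng)
            lm = _pose_landmarks(e, phi, r, z)
            moved = IHMLandmarks(rot @ lm.p_free + trans,
                                 rot @ lm.p_blocked + trans,
                                 rot @ lm.p_junction + trans)
            cyl = CylinderModel(rot @ np.zeros(3) + trans, rot @ Z)
            p1 = crown_pose(moved, cyl)
            for name in ("alpha", "beta", "gamma", "r"):
                assert getattr(p1, name) == pytest.approx(
                    getattr(p0, name), abs=1e-6)
            assert p1.z == pytest.approx(p0.z, abs=1e-6)

    def test_centroid_on_axis_rejected(self, z_axis_cylinder):
        lm = IHMLandmarks([50.0, 0, 0], [-25.0, 43.3, 0], [-25.0, -43.3, 0])
        with pytest.raises(ValueError, match="axis"):
            crown_pose(lm, z_axis_cylinder)

    def test_degenerate_triangle_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            IHMLandmarks([0, 0, 0], [1, 0, 0], [2, 0, 0])

    def test_gimbal_adjacent_pose_flagged(self, z_axis_cylinder):
        lm = _pose_landmarks((20.0, 89.95, 10.0), 0.0, 130.0, 0.0)
        p = crown_pose(lm, z_axis_cylinder)
        assert "gimbal" in p.flags
        assert p.gamma == 0.0


class TestCrownSeriesStats:
    def test_noise_free_lattice_rise_and_twist(self, single_filament,
                                               z_axis_cylinder):
        g = single_filament.ground_truth()
        poses = [crown_pose(IHMLandmarks((r.fx, r.fy, r.fz),
                                         (r.bx, r.by, r.bz),
                                         (r.jx, r.jy, r.jz)),
                            z_axis_cylinder, crown_class=r.crown_class)
                 for r in g.itertuples()]
        stats = crown_series_stats(poses, repeat=430.0)
        assert np.allclose(stats["rise_A"], 430.0, atol=1e-9)
        assert np.allclose(stats["twist_deg"], 0.0, atol=1e-9)

    def test_generated_twist_recovered(self, z_axis_cylinder):
        # single-strand helix: one crown per layer, 120 deg per repeat
        poses = []
        for k in range(6):
            lm = _pose_landmarks((0, 10, 0), 120.0 * k, 130.0, 430.0 * k)
            poses.append(crown_pose(lm, z_axis_cylinder, crown_class=1))
        stats = crown_series_stats(poses, repeat=430.0)
        assert stats.loc[0, "twist_deg"] == pytest.approx(120.0, abs=1e-9)
        assert stats.loc[0, "rise_A"] == pytest.approx(430.0, abs=1e-9)

    def test_angular_noise_sd_recovered(self, z_axis_cylinder):
        from sarcgeo.synth import NoiseSpec
        sd = 2.0
        spec = SceneSpec(seed=11, noise=NoiseSpec(angular_sd=sd))
        g = build_thick_filament(spec).ground_truth()
        poses = [crown_pose(IHMLandmarks((r.fx, r.fy, r.fz),
                                         (r.bx, r.by, r.bz),
                                         (r.jx, r.jy, r.jz)),
                            z_axis_cylinder, crown_class=r.crown_class)
                 for r in g.itertuples()]
        stats = crown_series_stats(poses)
        # sd of the sd estimator ~ sd/sqrt(2(n-1)), n about 30 per class
        tol = 3 * sd / np.sqrt(2 * 29)
        for col in ("alpha_sd", "beta_sd", "gamma_sd"):
            assert np.all(np.abs(stats[col] - sd) < tol)

    def test_single_pose_per_class_flagged(self, z_axis_cylinder):
        poses = [crown_pose(_pose_landmarks((0, 0, 0), 0, 130, z),
                            z_axis_cylinder, crown_class=c)
                 for z, c in ((0.0, 1), (143.3, 2), (430.0, 1))]
        stats = crown_series_stats(poses)
        by_cls = stats.set_index("crown_class")
        assert by_cls.loc[2, "single_layer"]
        assert np.isnan(by_cls.loc[2, "rise_A"])
        assert not by_cls.loc[1, "single_layer"]


class TestClassifyCrowns:
    def _pose(self, z):
        from sarcgeo.crowns import CrownPose
        return CrownPose(0, 0, 0, 0, 130.0, z)

    def test_offsets_map_to_classes(self):
        poses = classify_crowns([self._pose(z) for z in (0.0, 143.3, 286.7)],
                                430.0, (0.0, 143.3, 286.7))
        assert [p.crown_class for p in poses] == [1, 2, 3]

    def test_wrap_at_full_repeat(self):
        (p,) = classify_crowns([self._pose(430.0)], 430.0, (0.0, 143.3, 286.7))
        assert p.crown_class == 1

    def test_midway_tie_breaks_low_and_flags(self):
        (p,) = classify_crowns([self._pose(71.65)], 430.0,
                               (0.0, 143.3, 286.7))
        assert p.crown_class == 1
        assert "ambiguous" in p.flags

    def test_duplicate_offsets_rejected(self):
        with pytest.raises(ValueError):
            classify_crowns([self._pose(0.0)], 430.0, (0.0, 430.0))


class TestUnroll:
    def _poses(self, z_axis_cylinder):
        return [crown_pose(_pose_landmarks((0, 0, 0), phi, 130.0, z),
                           z_axis_cylinder)
                for phi, z in ((0.0, 0.0), (120.0, 430.0))]

    def test_arc_length_spacing(self, z_axis_cylinder):
        planar = unroll(self._poses(z_axis_cylinder), r_ref=130.0)
        assert planar[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert planar[1, 0] - planar[0, 0] == pytest.approx(
            130.0 * 2 * np.pi / 3, abs=1e-6)

    def test_unroll_reroll_inverse(self, z_axis_cylinder):
        poses = self._poses(z_axis_cylinder)
        back = reroll(unroll(poses, r_ref=130.0), r_ref=130.0)
        for p, (phi, z) in zip(poses, back):
            assert phi == pytest.approx(p.phi, abs=1e-9)
            assert z == pytest.approx(p.z, abs=1e-9)

    def test_nonpositive_reference_radius_rejected(self, z_axis_cylinder):
        with pytest.raises(ValueError):
            unroll(self._poses(z_axis_cylinder), r_ref=0.0)
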