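"""Calibration, line fits, angles and the full measurement report."""

import numpy as np
import pytest

from softceph import cephalometry as ceph
from softceph.cephalometry import Line2D
from softceph.schema import LandmarkSet, Pose
from softceph.synthetic_faces import FaceParams, generate_face


class TestScale:
    def test_fifty_px_bar(self, schema):
        pts = np.ones((34, 2))
        pts[32] = (10, 10)
        pts[33] = (10, 60)
        assert ceph.mm_per_pixel(LandmarkSet(pts), schema) == pytest.approx(0.2)

    def test_ten_px_bar(self, schema):
        pts = np.ones((34, 2))
        pts[32] = (10, 10)
        pts[33] = (10, 20)
        assert ceph.mm_per_pixel(LandmarkSet(pts), schema) == pytest.approx(1.0)

    def test_coincident_scale_points_raise(self, schema):
        pts = np.ones((34, 2))
        with pytest.raises(ValueError):
            ceph.mm_per_pixel(LandmarkSet(pts), schema)


class TestPointToLine:
    def test_point_on_line(self):
        line = Line2D((0.0, 0.0), (0.0, 1.0))
        assert ceph.point_to_line_distance((0, 50), line) == 0.0

    def test_vertical_line_drop(self):
        line = Line2D((0.0, 0.0), (0.0, 1.0))
        assert ceph.point_to_line_distance((5, 50), line) == pytest.approx(5.0)

    def test_rigid_invariance(self):
        p = np.array([3.0, 7.0])
        a = np.array([1.0, 1.0])
        d = np.array([1.0, 2.0]) / np.sqrt(5)
        base = ceph.point_to_line_distance(p, Line2D(tuple(a), tuple(d)))
        shift = np.array([12.5, -4.0])
        moved = ceph.point_to_line_distance(
            p + shift, Line2D(tuple(a + shift), tuple(d)))
        assert moved == pytest.approx(base)


class TestMidline:
    def _lm(self, schema, coords):
        pts = np.zeros((34, 2))
        vis = np.zeros(34, bool)
        for name, xy in coords.items():
            pts[schema.index(name)] = xy
            vis[schema.index(name)] = True
        return LandmarkSet(pts, vis)

    def test_exact_vertical_fit(self, schema):
        names = ("N", "Prn", "Sn", "Ss", "Ls", "Sl")
        lm = self._lm(schema, {n: (50.0, 10.0 * i)
                               for i, n in enumerate(names)})
        line = ceph.fit_facial_midline(lm, schema)
        assert ceph.point_to_line_distance((53, 25), line) == pytest.approx(3.0)

    def test_diagonal_fit_direction(self, schema):
        names = ("N", "Prn", "Sn", "Ss", "Ls", "Sl")
        lm = self._lm(schema, {n: (10.0 * i, 10.0 * i)
                               for i, n in enumerate(names)})
        line = ceph.fit_facial_midline(lm, schema)
        assert abs(line.direction[0]) == pytest.approx(1 / np.sqrt(2))
        assert abs(line.direction[1]) == pytest.approx(1 / np.sqrt(2))

    def test_symmetric_noise_keeps_intercept(self, schema):
        # +/- eps x-noise around a vertical line: least-squares intercept
        # stays within eps (oracle: normal equations of x-on-y regression)
        names = ("N", "Prn", "Sn", "Ss", "Ls", "Sl")
        eps = 0.5
        xs = [50 + eps, 50 - eps, 50 + eps, 50 - eps, 50 + eps, 50 - eps]
        lm = self._lm(schema, {n: (xs[i], 10.0 * i)
                               for i, n in enumerate(names)})
        line = ceph.fit_facial_midline(lm, schema)
        assert ceph.point_to_line_distance((50, 25), line) <= eps

    def test_too_few_points_raise(self, schema):
        lm = self._lm(schema, {"N": (1.0, 2.0)})
        with pytest.raises(ValueError):
            ceph.fit_facial_midline(lm, schema)


class TestOcclusalSlope:
    def test_level_mouth(self):
        assert ceph.occlusal_slope((40, 120), (160, 120)) == 0.0

    def test_patient_left_higher_gives_positive_k(self):
        # CL 12 px higher on screen than CR, 120 px apart -> k = +0.1
        assert ceph.occlusal_slope((40, 120), (160, 108)) == pytest.approx(0.1)

    def test_swap_invariance(self):
        k1 = ceph.occlusal_slope((40, 120), (160, 108))
        k2 = ceph.occlusal_slope((160, 108), (40, 120))
        assert k1 == pytest.approx(k2)

    def test_vertical_commissure_line_raises(self):
        with pytest.raises(ValueError):
            ceph.occlusal_slope((40, 100), (40, 150))


class TestAngle:
    def test_collinear_opposite(self):
        assert ceph.angle_at_vertex((0, 10), (0, 0), (0, -10)) == \
            pytest.approx(180.0)

    def test_arccos_example(self):
        assert ceph.angle_at_vertex((0, 100), (0, 0), (20, -40)) == \
            pytest.approx(153.4349488, abs=1e-4)

    def test_perpendicular(self):
        assert ceph.angle_at_vertex((10, 0), (0, 0), (0, 10)) == \
            pytest.approx(90.0)

    def test_scale_invariance(self):
        a, v, b = (3.0, 1.0), (1.0, -2.0), (-4.0, 2.0)
        base = ceph.angle_at_vertex(a, v, b)
        s = 7.3
        scaled = ceph.angle_at_vertex(
            tuple(np.array(a) * s), tuple(np.array(v) * s),
            tuple(np.array(b) * s))
        assert scaled == pytest.approx(base)

    def test_coincident_raises(self):
        with pytest.raises(ValueError):
            ceph.angle_at_vertex((1, 1), (1, 1), (2, 2))


class TestMeasure:
    def test_symmetric_face_equal_cheilion_distances(self, schema):
        smp = generate_face(FaceParams(pose=Pose.RFV, chin_offset_mm=0.0,
                                       occlusal_k=0.0, seed=1))
        rep = ceph.measure(smp.landmarks, Pose.RFV, schema)
        assert rep.d6 == pytest.approx(rep.d7)
        assert rep.d8 == pytest.approx(0.0, abs=1e-9)

    def test_lateral_facial_angle_recovery(self, schema):
        smp = generate_face(FaceParams(pose=Pose.RLV, facial_angle_deg=160.0,
                                       seed=2))
        rep = ceph.measure(smp.landmarks, Pose.RLV, schema)
        assert rep.facial_angle == pytest.approx(160.0, abs=0.01)

    def test_point_on_eline_zero_distance(self):
        line = Line2D((0.0, 0.0), (0.0, 1.0))
        # Ls placed exactly on the Prn-Pog line
        assert ceph.point_to_line_distance((0.0, 30.0), line) == 0.0

    def test_pose_gating(self, schema):
        smp = generate_face(FaceParams(pose=Pose.RFV, seed=3))
        rep = ceph.measure(smp.landmarks, Pose.RFV, schema)
        assert rep.d1 is None and rep.d3 is None
        assert rep.facial_angle is None
        assert rep.k is not None and rep.d8 is not None

    def test_mouth_opening_distances(self, schema):
        lmo = generate_face(FaceParams(pose=Pose.LMO, mouth_opening_mm=40.0,
                                       seed=4))
        rep = ceph.measure(lmo.landmarks, Pose.LMO, schema)
        assert rep.d1 == pytest.approx(40.0)
        smo = generate_face(FaceParams(pose=Pose.SMO, mouth_opening_mm=15.0,
                                       seed=5))
        assert ceph.measure(smo.landmarks, Pose.SMO,
                            schema).d2 == pytest.approx(15.0)

    def test_rigid_transform_invariance(self, schema):
        smp = generate_face(FaceParams(pose=Pose.RFV, chin_offset_mm=5.0,
                                       occlusal_k=0.03, seed=6))
        rep = ceph.measure(smp.landmarks, Pose.RFV, schema)
        th = np.deg2rad(9.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        lm2 = smp.landmarks.copy()
        lm2.points = smp.landmarks.points @ R.T + np.array([31.0, -12.0])
        rep2 = ceph.measure(lm2, Pose.RFV, schema)
        for f in ("d6", "d7", "d8", "d9", "d10", "mm_per_px"):
            assert getattr(rep2, f) == pytest.approx(getattr(rep, f),
                                                     abs=1e-6), f

    def test_missing_landmark_flags_measurement_not_report(self, schema):
        smp = generate_face(FaceParams(pose=Pose.RFV, seed=7))
        lm = smp.landmarks.copy()
        lm.visible[schema.index("CR")] = False
        rep = ceph.measure(lm, Pose.RFV, schema)
        assert rep.d7 is None and rep.k is None
        assert rep.d8 is not None
        assert any("d7" in w for w in rep.warnings)
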