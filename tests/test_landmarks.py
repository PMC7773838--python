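"""Femoral-head landmark construction: d, e, f selection and the circle fit."""

import numpy as np
import pytest

from hipdx.angles import AngleTriplet
from hipdx.errors import LandmarkError
from hipdx.geometry import Contour, Point
from hipdx.landmarks import (find_lateral_point, find_superior_point,
                             fit_femoral_head, vertical_reference)
from hipdx.synthetic import PelvisSimConfig, construct_pelvis


def polygon_circle(cx, cy, r, n=360, t0=0.0, t1=360.0):
    t = np.radians(np.linspace(t0, t1, n))
    return Contour(np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)]))


class TestSuperiorPoint:
    def test_circle_apex(self):
        c = polygon_circle(0, 0, 10, n=360, t0=0, t1=359)
        p = find_superior_point(c)
        assert p.y == pytest.approx(-10.0, abs=0.01)
        assert p.x == pytest.approx(0.0, abs=0.2)

    def test_flat_top_tie_break(self):
        # two equal-y top vertices; winner is the one nearest the centroid x
        v = np.array([[0.0, 0.0], [10.0, 0.0], [16.0, 5.0], [-2.0, 5.0]])
        p = find_superior_point(Contour(v))
        cx = v[:, 0].mean()  # = 6: vertex (10, 0) is nearer than (0, 0)
        assert p == Point(10.0, 0.0)
        assert abs(p.x - cx) <= abs(0.0 - cx)
        # exact distance tie falls back to the lowest index
        v2 = np.array([[0.0, 0.0], [10.0, 0.0], [12.0, 5.0], [-2.0, 5.0]])
        assert find_superior_point(Contour(v2)) == Point(0.0, 0.0)

    def test_synthetic_apex_recovered(self, simple_pelvis):
        ann, _ = simple_pelvis
        hip = ann.right_hip
        contour = hip.femoral_head_contour
        p = find_superior_point(contour)
        # apex of the generating circle: the contour's min-y vertex must lie
        # within one vertex spacing of it
        spacing = np.linalg.norm(np.diff(contour.vertices, axis=0), axis=1).max()
        top = contour.vertices[np.argmin(contour.vertices[:, 1])]
        assert np.hypot(p.x - top[0], p.y - top[1]) <= spacing


def neck_contour(side="right", r_head=100.0, r_neck=80.0):
    """Head arc plus a concave neck arc that protrudes laterally past the head."""
    sign = -1.0 if side == "right" else 1.0
    # head arc: medial end over the apex down to the junction below lateral
    t = np.radians(np.linspace(400, 170, 150)) if side == "right" else \
        np.radians(np.linspace(140, 370, 150))
    head = np.column_stack([r_head * np.cos(t), r_head * np.sin(t)])
    tj = np.radians(170 if side == "right" else 370)
    p0 = r_head * np.array([np.cos(tj), np.sin(tj)])
    n = p0 / np.linalg.norm(p0)
    cn = p0 + r_neck * n  # neck curvature center on the outside: sign flip
    tn0 = np.degrees(np.arctan2(-n[1], -n[0]))
    tn = np.radians(np.linspace(tn0, tn0 + (40 if side == "right" else -40), 40))
    neck = cn + r_neck * np.column_stack([np.cos(tn), np.sin(tn)])
    v = np.vstack([head, neck[1:]])
    if side == "left":
        pass  # already mirrored by construction angles
    return Contour(v)


class TestLateralPoint:
    def test_circle_extreme_x_right(self):
        c = polygon_circle(50, 50, 10, n=360, t0=0, t1=359)
        p = find_lateral_point(c, "right", neck_present=False)
        assert p.x == pytest.approx(40.0, abs=0.01)

    def test_mirrored_left(self):
        c = polygon_circle(50, 50, 10, n=360, t0=0, t1=359)
        mirrored = Contour(c.vertices * np.array([-1.0, 1.0]))
        p_r = find_lateral_point(c, "right")
        p_l = find_lateral_point(mirrored, "left")
        assert p_l.x == pytest.approx(-p_r.x, abs=1e-9)
        assert p_l.y == pytest.approx(p_r.y, abs=1e-9)

    def test_neck_excluded_by_inflection(self):
        c = neck_contour("right")
        # without the inflection restriction the neck wins the lateral extreme
        naive = find_lateral_point(c, "right", neck_present=False)
        assert naive.x < -100.0
        p = find_lateral_point(c, "right", neck_present=True)
        assert p.x == pytest.approx(-100.0, abs=1.5)
        assert abs(p.y) < 20.0

    def test_no_inflection_raises(self):
        c = polygon_circle(0, 0, 10, n=180, t0=120, t1=420)
        with pytest.raises(LandmarkError):
            find_lateral_point(c, "right", neck_present=True)


class TestFitFemoralHead:
    def test_center_recovery_on_synthetic_hip(self, simple_pelvis):
        ann, _ = simple_pelvis
        fit = fit_femoral_head(ann.right_hip)
        # the generator places the right head center at (3R, 5R) with R=100
        assert np.hypot(fit.center.x - 300.0, fit.center.y - 500.0) < 0.01 * fit.radius
        assert fit.radius == pytest.approx(100.0, rel=0.01)

    def test_defining_points_on_circle(self, simple_pelvis):
        ann, _ = simple_pelvis
        fit = fit_femoral_head(ann.left_hip)
        for p in (fit.superior_point, fit.lateral_point, fit.inferior_intersection):
            d = np.hypot(p.x - fit.center.x, p.y - fit.center.y)
            assert abs(d - fit.radius) < 1e-6 * fit.radius

    def test_f_matches_analytic_circle_line_intersection(self, simple_pelvis):
        ann, _ = simple_pelvis
        hip = ann.right_hip
        fit = fit_femoral_head(hip)
        e = np.array(fit.lateral_point)
        g = np.array(hip.inferior_acetabular_edge)
        center, r = np.array([300.0, 500.0]), 100.0
        u = (g - e) / np.linalg.norm(g - e)
        # |e - center + s u| = r with e on the circle: s = -2 (e-center)·u
        s = -2.0 * float((e - center) @ u)
        f_expected = e + s * u
        assert np.hypot(fit.inferior_intersection.x - f_expected[0],
                        fit.inferior_intersection.y - f_expected[1]) < 0.05

    def test_translation_and_scale_invariance(self):
        def angles_of(ann):
            from hipdx.angles import measure_pelvis
            r, l, _ = measure_pelvis(ann)
            return np.array(r.triplet.as_tuple() + l.triplet.as_tuple())

        cfg = PelvisSimConfig(target_right=AngleTriplet(25, 45, 10),
                              target_left=AngleTriplet(35, 38, 3))
        ann, _ = construct_pelvis(cfg)
        base = angles_of(ann)

        def transform(ann, fn):
            import copy
            from hipdx.annotations import HipAnnotation, PelvisAnnotation
            def tf_hip(h):
                return HipAnnotation(
                    side=h.side,
                    acetabulum_contour=Contour(fn(h.acetabulum_contour.vertices)),
                    femoral_head_contour=Contour(fn(h.femoral_head_contour.vertices)),
                    lateral_acetabular_edge=Point(*fn(np.array([h.lateral_acetabular_edge]))[0]),
                    inferior_acetabular_edge=Point(*fn(np.array([h.inferior_acetabular_edge]))[0]),
                    sourcil_inferomedial_point=Point(*fn(np.array([h.sourcil_inferomedial_point]))[0]),
                )
            return PelvisAnnotation(image_id=ann.image_id,
                                    right_hip=tf_hip(ann.right_hip),
                                    left_hip=tf_hip(ann.left_hip))

        shifted = transform(ann, lambda v: v + np.array([123.4, -77.1]))
        scaled = transform(ann, lambda v: v * 2.71828)
        assert np.allclose(angles_of(shifted), base, atol=1e-9)
        assert np.allclose(angles_of(scaled), base, atol=1e-9)


class TestVerticalReference:
    def test_horizontal_baseline(self):
        tr = vertical_reference(Point(0, 0), Point(100, 0), Point(0, 0), length=50)
        assert tr.vertical_reference_point == pytest.approx((0.0, -50.0))

    def test_tilted_baseline_rotates_reference(self):
        th = np.radians(10.0)
        cl = Point(100 * np.cos(th), 100 * np.sin(th))
        tr = vertical_reference(Point(0, 0), cl, Point(0, 0), length=1.0)
        ref = np.array(tr.vertical_reference_point)
        expected = np.array([np.sin(th), -np.cos(th)])
        assert np.allclose(ref, expected, atol=1e-12)

    def test_swapped_centers_same_direction(self):
        a, b, c = Point(10, 20), Point(200, 35), Point(10, 20)
        t1 = vertical_reference(a, b, c)
        t2 = vertical_reference(b, a, c)
        assert t1.vertical_reference_point == pytest.approx(
            t2.vertical_reference_point, abs=1e-12)
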