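"""Rotated-box geometry: conversions, intersection, IoU, NMS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rotphenex.errors import DegenerateGeometryError, InvalidArgumentError
from rotphenex.rotgeom import (
    QuadBox, RotatedBox, from_quad, intersection_area, rotated_iou,
    rotated_nms, to_quad, wrap_angle,
)

from conftest import random_box, raster_iou, shapely_poly


class TestWrapAngle:
    @pytest.mark.parametrize(
        "raw,expected",
        [(0.0, 0.0), (90.0, -90.0), (125.0, -55.0), (-90.0, -90.0),
         (180.0, 0.0), (-270.0, -90.0), (89.999, 89.999)],
    )
    def test_known_values(self, raw, expected):
        assert wrap_angle(raw) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-1e6, 1e6))
    @settings(max_examples=200, derandomize=True)
    def test_range_and_periodicity(self, theta):
        w = wrap_angle(theta)
        assert -90.0 <= w < 90.0
        assert abs((theta - w) % 180.0) < 1e-6 or abs((theta - w) % 180.0 - 180.0) < 1e-6

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(InvalidArgumentError):
            wrap_angle(bad)


class TestRotatedBox:
    def test_sides_canonicalized_long_side_second(self):
        b = RotatedBox(0, 0, w=10, h=4, theta=0)
        assert (b.w, b.h) == (4, 10)
        assert b.theta == pytest.approx(-90.0)

    def test_square_angle_mod_90(self):
        b = RotatedBox(0, 0, 5, 5, 80.0)
        assert -45.0 <= b.theta < 45.0
        assert set(map(tuple, np.round(to_quad(b).as_array(), 6))) == set(
            map(tuple, np.round(to_quad(RotatedBox(0, 0, 5, 5, 80.0)).as_array(), 6))
        )

    def test_nonpositive_sides_rejected(self):
        with pytest.raises(InvalidArgumentError):
            RotatedBox(0, 0, 0.0, 4, 0)


class TestQuadConversion:
    def test_axis_aligned_corners(self):
        q = to_quad(RotatedBox(0, 0, w=2, h=4, theta=0))
        assert set(map(tuple, np.round(q.as_array(), 9))) == {
            (-2, -1), (2, -1), (2, 1), (-2, 1)
        }
        v = q.as_array()
        assert np.hypot(*(v[1] - v[2])) == pytest.approx(4)  # v2->v3 long
        assert np.hypot(*(v[2] - v[3])) == pytest.approx(2)  # v3->v4 short

    def test_vertical_corners(self):
        q = to_quad(RotatedBox(0, 0, w=2, h=4, theta=90))
        assert set(map(tuple, np.round(q.as_array(), 9))) == {
            (-1, -2), (1, -2), (1, 2), (-1, 2)
        }

    def test_random_side_lengths(self, rng):
        for _ in range(300):
            b = random_box(rng)
            v = to_quad(b).as_array()
            sides = [np.hypot(*(v[(i + 1) % 4] - v[i])) for i in range(4)]
            assert sides == pytest.approx([b.w, b.h, b.w, b.h], abs=1e-9)

    def test_round_trip_identity_bulk(self, rng):
        """Five-param -> quad -> five-param is the identity (mod 180) for 10^4 boxes."""
        for _ in range(10_000):
            b = random_box(rng, w_range=(2.0, 20.0))
            r = from_quad(to_quad(b))
            assert abs(r.cx - b.cx) <= 1e-6
            assert abs(r.cy - b.cy) <= 1e-6
            assert abs(r.w - b.w) <= 1e-6
            assert abs(r.h - b.h) <= 1e-6
            d = abs(r.theta - b.theta) % 180.0
            assert min(d, 180.0 - d) <= 1e-6

    def test_from_quad_any_cyclic_start(self, rng):
        b = random_box(rng)
        verts = list(to_quad(b).vertices)
        for s in range(4):
            r = from_quad(QuadBox(verts[s:] + verts[:s]))
            assert (r.cx, r.cy, r.w, r.h) == pytest.approx(
                (b.cx, b.cy, b.w, b.h), abs=1e-6
            )

    def test_degenerate_quad_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            from_quad(QuadBox([(0, 0), (1, 0), (2, 0), (3, 0)]))

    def test_non_rectangular_quad_uses_min_area_fit(self):
        # a slightly sheared rectangle still yields a sensible enclosing box
        q = QuadBox([(0, 0), (10, 0.5), (10.2, 4.5), (0.2, 4.0)])
        r = from_quad(q)
        assert r.h >= r.w > 0
        assert shapely_poly(r).buffer(1e-6).contains(
            __import__("shapely").Polygon(q.vertices)
        )


class TestIntersectionArea:
    def test_identical_unit_squares(self):
        q = to_quad(RotatedBox(0.5, 0.5, 1, 1, 0))
        assert intersection_area(q, q) == pytest.approx(1.0)

    def test_disjoint(self):
        a = to_quad(RotatedBox(1, 1, 2, 2, 0))
        b = to_quad(RotatedBox(11, 11, 2, 2, 0))
        assert intersection_area(a, b) == 0.0

    def test_offset_squares(self):
        a = to_quad(RotatedBox(1, 1, 2, 2, 0))
        b = to_quad(RotatedBox(2, 2, 2, 2, 0))
        assert intersection_area(a, b) == pytest.approx(1.0, abs=1e-3)

    def test_against_shapely(self, rng):
        for _ in range(200):
            a = random_box(rng, canvas=100)
            b = random_box(rng, canvas=100)
            mine = intersection_area(to_quad(a), to_quad(b))
            ref = shapely_poly(a).intersection(shapely_poly(b)).area
            assert mine == pytest.approx(ref, abs=1e-8 * max(1.0, ref))

    def test_bounded_by_min_area(self, rng):
        for _ in range(100):
            a, b = random_box(rng, canvas=60), random_box(rng, canvas=60)
            inter = intersection_area(to_quad(a), to_quad(b))
            assert inter <= min(a.area, b.area) + 1e-9


class TestRotatedIoU:
    def test_identical(self, rng):
        b = random_box(rng)
        assert rotated_iou(b, b) == pytest.approx(1.0)

    def test_disjoint(self):
        assert rotated_iou(RotatedBox(0, 0, 2, 4, 10), RotatedBox(50, 50, 2, 4, 10)) == 0.0

    def test_square_vs_rotated_square_matches_raster(self):
        a = RotatedBox(0, 0, 1, 1, 0)
        b = RotatedBox(0, 0, 1, 1, 45)
        # closed form: intersection of unit square with its 45-degree twin
        # is a regular octagon of area 2*(sqrt(2)-1)
        expected = (2 * (np.sqrt(2) - 1)) / (2 - 2 * (np.sqrt(2) - 1))
        assert rotated_iou(a, b) == pytest.approx(expected, abs=1e-9)
        assert rotated_iou(a, b) == pytest.approx(raster_iou(a, b), abs=1e-3)

    def test_symmetry_and_invariance(self, rng):
        for _ in range(50):
            a, b = random_box(rng, canvas=80), random_box(rng, canvas=80)
            i1 = rotated_iou(a, b)
            assert i1 == pytest.approx(rotated_iou(b, a), abs=1e-12)
            # joint translation
            i2 = rotated_iou(a.translated(13.7, -4.2), b.translated(13.7, -4.2))
            assert i2 == pytest.approx(i1, abs=1e-9)
            # joint rotation about the origin by 30 degrees
            i3 = rotated_iou(_rot_about_origin(a, 30.0), _rot_about_origin(b, 30.0))
            assert i3 == pytest.approx(i1, abs=1e-9)

    def test_axis_aligned_equals_classical_formula(self, rng):
        for _ in range(100):
            a = RotatedBox(rng.uniform(0, 50), rng.uniform(0, 50),
                           rng.uniform(2, 10), rng.uniform(10, 30), 0.0)
            b = RotatedBox(rng.uniform(0, 50), rng.uniform(0, 50),
                           rng.uniform(2, 10), rng.uniform(10, 30), 0.0)
            ix = max(0.0, min(a.cx + a.h / 2, b.cx + b.h / 2) - max(a.cx - a.h / 2, b.cx - b.h / 2))
            iy = max(0.0, min(a.cy + a.w / 2, b.cy + b.w / 2) - max(a.cy - a.w / 2, b.cy - b.w / 2))
            inter = ix * iy
            classical = inter / (a.area + b.area - inter) if inter else 0.0
            assert rotated_iou(a, b) == pytest.approx(classical, abs=1e-12)


def _rot_about_origin(b: RotatedBox, deg: float) -> RotatedBox:
    t = np.radians(deg)
    # screen-CCW rotation in y-down coordinates
    cx = b.cx * np.cos(t) + b.cy * np.sin(t)
    cy = -b.cx * np.sin(t) + b.cy * np.cos(t)
    return RotatedBox(cx, cy, b.w, b.h, wrap_angle(b.theta + deg))


def _brute_force_nms(dets, thr):
    order = sorted(range(len(dets)), key=lambda i: -dets[i][1])
    kept = []
    suppressed = set()
    for i in order:
        if i in suppressed:
            continue
        kept.append(i)
        for j in order:
            if j not in suppressed and j != i:
                if rotated_iou(dets[i][0], dets[j][0]) > thr:
                    suppressed.add(j)
    return kept


class TestRotatedNMS:
    def test_empty_and_single(self, rng):
        assert rotated_nms([]) == []
        assert rotated_nms([(random_box(rng), 0.7)], 0.5) == [0]

    def test_identical_pair_keeps_best(self, rng):
        b = random_box(rng)
        assert rotated_nms([(b, 0.9), (b, 0.8)], 0.5) == [0]

    def test_matches_brute_force_on_random_sets(self, rng):
        for trial in range(5):
            dets = [
                (random_box(rng, canvas=120), float(rng.uniform(0.05, 1.0)))
                for _ in range(50)
            ]
            assert set(rotated_nms(dets, 0.3)) == set(_brute_force_nms(dets, 0.3))
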