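"""Heron's-formula triangle-height diameter estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselcal import (PhantomSpec, SnakeContour, generate_phantom, heron_area,
                       measure_segment, measure_vessel, perpendicular_distance,
                       select_contour_points, side_lengths, triangle_height)

coord = st.floats(-100, 100, allow_nan=False)
point = st.tuples(coord, coord)


def tube_contour(row_c=20.0, half=4.0, c0=5.0, c1=35.0, step=1.0):
    """Closed rectangle-ish contour of a horizontal tube at rows row_c±half."""
    cols = np.arange(c0, c1 + step, step)
    top = [(row_c - half, c) for c in cols]
    bottom = [(row_c + half, c) for c in cols[::-1]]
    return SnakeContour(points=np.array(top + bottom), closed=True)


class TestSideLengths:
    def test_three_four_five(self):
        a, b, c = side_lengths((0, 0), (3, 4), (0, 4))
        assert a == pytest.approx(5.0)

    def test_coincident_points_all_zero(self):
        assert side_lengths((2, 2), (2, 2), (2, 2)) == (0, 0, 0)

    @settings(deadline=None, derandomize=True)
    @given(n=point, p=point, m=point)
    def test_matches_hypot_oracle(self, n, p, m):
        a, b, c = side_lengths(n, p, m)
        assert a == pytest.approx(math.hypot(n[0] - p[0], n[1] - p[1]))
        assert b == pytest.approx(math.hypot(m[0] - p[0], m[1] - p[1]))
        assert c == pytest.approx(math.hypot(n[0] - m[0], n[1] - m[1]))


class TestHeronArea:
    def test_right_triangle(self):
        assert heron_area(3, 4, 5) == pytest.approx(6.0)

    def test_degenerate_collinear(self):
        assert heron_area(2, 3, 5) == pytest.approx(0.0)

    def test_gross_violation_rejected(self):
        with pytest.raises(ValueError, match="triangle inequality"):
            heron_area(1, 1, 5)

    def test_matches_cross_product_oracle_on_random_triangles(self, rng):
        for _ in range(1000):
            pts = rng.uniform(-50, 50, size=(3, 2))
            a, b, c = side_lengths(*pts)
            u, v = pts[1] - pts[0], pts[2] - pts[0]
            expected = abs(u[0] * v[1] - u[1] * v[0]) / 2.0
            assert heron_area(a, b, c) == pytest.approx(expected, abs=1e-9)


class TestTriangleHeight:
    def test_right_triangle_altitude(self):
        assert triangle_height(6.0, 5.0) == pytest.approx(2.4)

    def test_zero_area_zero_height(self):
        assert triangle_height(0.0, 3.0) == 0.0

    def test_zero_base_rejected(self):
        with pytest.raises(ValueError):
            triangle_height(1.0, 0.0)

    def test_equals_perpendicular_distance_identity(self, rng):
        for _ in range(1000):
            n, p, m = rng.uniform(-50, 50, size=(3, 2))
            a, b, c = side_lengths(n, p, m)
            if a < 1e-6:
                continue
            h = triangle_height(heron_area(a, b, c), a)
            assert h == pytest.approx(perpendicular_distance(m, n, p), abs=1e-9)


class TestSelectContourPoints:
    def test_tube_sides_assigned_correctly(self):
        contour = tube_contour(row_c=20, half=4)
        m_up, m_down = select_contour_points((20, 10), (20, 30), contour)
        assert {m_up[0], m_down[0]} == {16.0, 24.0}

    def test_feet_near_segment_midpoint(self):
        contour = tube_contour(row_c=20, half=4)
        m_up, m_down = select_contour_points((20, 10), (20, 30), contour)
        assert abs(m_up[1] - 20) <= 0.5 and abs(m_down[1] - 20) <= 0.5

    def test_one_sided_contour_warns_and_skips(self):
        one_side = SnakeContour(points=[(16.0, c) for c in range(5, 36)],
                                closed=False)
        with pytest.warns(UserWarning, match="one side"):
            assert select_contour_points((20, 10), (20, 30), one_side) is None

    def test_coincident_segment_rejected(self):
        with pytest.raises(ValueError):
            select_contour_points((1, 1), (1, 1), tube_contour())


class TestMeasureSegment:
    def test_tube_phantom_width_recovered_exactly(self):
        m = measure_segment((20, 10), (20, 30), tube_contour(half=4))
        assert m.diameter == pytest.approx(8.0)
        assert m.h1 == pytest.approx(4.0) and m.h2 == pytest.approx(4.0)

    def test_symmetric_contour_gives_equal_heights(self):
        m = measure_segment((20, 10), (20, 30), tube_contour(half=3.25))
        assert m.h1 == pytest.approx(m.h2)

    def test_swap_and_rigid_motion_invariance(self, rng):
        contour = tube_contour(half=4)
        n, p = np.array([20.0, 10.0]), np.array([20.0, 30.0])
        d0 = measure_segment(n, p, contour).diameter
        assert measure_segment(p, n, contour).diameter == pytest.approx(d0)
        # rotate everything by 30 degrees about an arbitrary center
        th = math.radians(30)
        rot = np.array([[math.cos(th), -math.sin(th)],
                        [math.sin(th), math.cos(th)]])
        center = np.array([13.0, -7.0])
        def xf(pts):
            return (np.asarray(pts, float) - center) @ rot.T + center
        rotated = SnakeContour(points=xf(contour.points), closed=True)
        d1 = measure_segment(xf(n), xf(p), rotated).diameter
        assert d1 == pytest.approx(d0, abs=1e-6)


class TestMeasureVessel:
    def test_one_measurement_per_consecutive_pair(self):
        contour = tube_contour(half=4)
        cp = np.array([(20, 8), (20, 20), (20, 32)])
        ms, skipped = measure_vessel(cp, contour)
        assert len(ms) == 2 and skipped == []
        assert [m.segment_index for m in ms] == [0, 1]

    def test_straight_tube_constant_width(self):
        img, truth = generate_phantom(PhantomSpec(width_px=8.0))
        from vesselcal import (SnakeParams, binarize, douglas_peucker,
                               evolve_snake, initialize_vessel_contour,
                               skeletonize, trace_branches)
        mask = binarize(img)
        br = trace_branches(skeletonize(mask))[0]
        contour = evolve_snake(initialize_vessel_contour(mask, br, 2), img,
                               SnakeParams())
        # characteristic points on the straight interior of the centerline
        interior = br.points.astype(float)[5:-5]
        cp = interior[:: len(interior) // 4]
        ms, _ = measure_vessel(cp, contour)
        assert len(ms) >= 3
        for m in ms:
            # <= 1 px with float slack: even widths centered between pixel
            # rows put both edges exactly on pixel boundaries, the worst
            # case for the discrete edge localization
            assert abs(m.diameter - 8.0) <= 1.0 + 1e-9

    def test_tapering_tube_monotone_width(self):
        img, truth = generate_phantom(
            PhantomSpec(shape="tapering", width_px=12.0, width_end_px=4.0,
                        image_size=(128, 128)))
        from vesselcal import (SnakeParams, binarize, evolve_snake,
                               initialize_vessel_contour, skeletonize,
                               trace_branches)
        mask = binarize(img)
        br = trace_branches(skeletonize(mask))[0]
        contour = evolve_snake(initialize_vessel_contour(mask, br, 2), img,
                               SnakeParams())
        cp = br.points.astype(float)[::10]
        ms, _ = measure_vessel(cp, contour)
        diam = [m.diameter for m in ms]
        assert len(diam) >= 5
        # non-increasing within 1 px slack
        for earlier, later in zip(diam, diam[1:]):
            assert later <= earlier + 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            measure_vessel(np.array([[0.0, 0.0]]), tube_contour())
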