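"""Active-contour energies and the greedy minimizer."""

import numpy as np
import pytest

from vesselcal import (PhantomSpec, SnakeContour, SnakeParams, binarize,
                       circular_contour, evolve_snake, external_energy_field,
                       generate_phantom, initialize_vessel_contour,
                       internal_energy, skeletonize, total_energy,
                       trace_branches)
from vesselcal.snake import sample_field


def disc_image(size=96, radius=20.0, lo=50.0, hi=200.0):
    c = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size]
    d = np.hypot(rows - c, cols - c)
    return lo + (hi - lo) * np.clip(radius - d + 0.5, 0, 1), (c, c)


class TestExternalEnergyField:
    def test_constant_image_gives_zero_field(self):
        field = external_energy_field(np.full((20, 20), 77.0), sigma=1.0)
        np.testing.assert_allclose(field, 0.0)

    def test_gamma_zero_gives_zero_field(self, rng):
        img = rng.uniform(0, 255, size=(20, 20))
        np.testing.assert_allclose(
            external_energy_field(img, sigma=1.0, gamma=0.0), 0.0)

    def test_field_nonpositive_everywhere(self, rng):
        img = rng.uniform(0, 255, size=(30, 30))
        assert (external_energy_field(img, 1.0, 1.2) <= 0).all()

    def test_step_edge_minimum_on_edge_column(self):
        img = np.zeros((21, 40))
        img[:, 20:] = 150.0
        field = external_energy_field(img, sigma=1.0, gamma=1.0)
        # deepest energy along the row must sit at the edge transition
        col = np.argmin(field[10])
        assert col in (19, 20)
        # independent finite-difference oracle on the smoothed image
        from scipy.ndimage import gaussian_filter
        sm = gaussian_filter(img, 1.0)
        gr = np.zeros_like(sm)
        gc = np.zeros_like(sm)
        gr[1:-1, :] = (sm[2:, :] - sm[:-2, :]) / 2.0
        gc[:, 1:-1] = (sm[:, 2:] - sm[:, :-2]) / 2.0
        inner = (slice(1, -1), slice(1, -1))
        np.testing.assert_allclose(field[inner],
                                   -(gr ** 2 + gc ** 2)[inner], atol=1e-9)

    def test_translation_equivariance(self, rng):
        img = np.zeros((40, 40))
        img[10:20, 10:20] = rng.uniform(100, 200, size=(10, 10))
        f1 = external_energy_field(img, 1.0, 1.2)
        f2 = external_energy_field(np.roll(img, 5, axis=1), 1.0, 1.2)
        inner = (slice(0, 40), slice(8, 32))
        np.testing.assert_allclose(np.roll(f1, 5, axis=1)[inner], f2[inner],
                                   atol=1e-9)


class TestInternalEnergy:
    def test_collinear_equal_spacing_has_zero_curvature(self):
        c = SnakeContour(points=[(0, 0), (0, 2), (0, 4), (0, 6)], closed=False)
        _, e_curv = internal_energy(c, 1, SnakeParams())
        assert e_curv == 0.0

    def test_zero_weights_give_zero_energy(self):
        c = SnakeContour(points=[(0, 0), (1, 3), (5, 2)], closed=False)
        assert internal_energy(c, 1, SnakeParams(alpha=0, beta=0)) == (0, 0)

    def test_hand_computed_differences(self):
        # points (0,0),(1,0),(2,1): spacings 1 and sqrt(2), mean 1.2071;
        # second difference at index 1 is (0,1)
        c = SnakeContour(points=[(0, 0), (1, 0), (2, 1)], closed=False)
        e_cont, e_curv = internal_energy(c, 1, SnakeParams(alpha=1, beta=1))
        dbar = (1 + np.sqrt(2)) / 2
        assert e_cont == pytest.approx((dbar - 1.0) ** 2)
        assert e_curv == pytest.approx(1.0)
        e_cont_raw, _ = internal_energy(
            c, 1, SnakeParams(continuity="raw"))
        assert e_cont_raw == pytest.approx(1.0)

    def test_index_out_of_range(self):
        c = SnakeContour(points=[(0, 0), (1, 0), (2, 0)], closed=False)
        with pytest.raises(IndexError):
            internal_energy(c, 7, SnakeParams())


class TestEvolveSnake:
    def test_fixed_point_when_started_on_energy_minimum(self):
        # synthetic energy valley along one column; points start in the trough
        rows, cols = np.mgrid[0:40, 0:40].astype(float)
        valley = -np.exp(-((cols - 20.0) ** 2) / 8.0)
        params = SnakeParams(alpha=0, beta=0)
        init = SnakeContour(points=[(r, 20.0) for r in range(5, 35, 3)],
                            closed=False)
        out = evolve_snake(init, np.zeros((40, 40)), params, fieldgrid=valley)
        np.testing.assert_allclose(out.points, init.points)
        assert len(out.energy_trace) == 1

    def test_disc_phantom_convergence(self):
        img, center = disc_image()
        init = circular_contour(center, 30.0, 24)
        out = evolve_snake(init, img, SnakeParams())
        r = np.hypot(*(out.points - np.array(center)).T)
        assert abs(r.mean() - 20.0) <= 1.0

    def test_energy_trace_non_increasing_on_varied_runs(self, rng):
        for _ in range(5):
            img = rng.uniform(0, 255, size=(48, 48))
            init = circular_contour((23.5, 23.5), rng.uniform(8, 18), 16)
            out = evolve_snake(init, img, SnakeParams(max_iterations=40))
            assert np.all(np.diff(out.energy_trace) <= 1e-9)

    def test_trace_matches_total_energy_of_result(self):
        img, center = disc_image()
        out = evolve_snake(circular_contour(center, 26.0, 20), img,
                           SnakeParams())
        field = external_energy_field(img, 1.0, 1.2)
        e = total_energy(out.points, True, SnakeParams(),
                         sample_field(field, out.points))
        assert out.energy_trace[-1] == pytest.approx(e, rel=1e-9)

    def test_out_of_bounds_init_rejected(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError, match="bounds"):
            evolve_snake(circular_contour((10, 10), 15, 12), img, SnakeParams())

    def test_tube_sides_within_tolerance(self):
        img, truth = generate_phantom(PhantomSpec(width_px=8.0))
        mask = binarize(img)
        br = trace_branches(skeletonize(mask))[0]
        init = initialize_vessel_contour(mask, br, margin=2)
        out = evolve_snake(init, img, SnakeParams())
        # points well inside the tube's column range, split by side
        row_c = truth.centerline[:, 0].mean()
        cmin, cmax = truth.centerline[:, 1].min(), truth.centerline[:, 1].max()
        pts = out.points
        side = pts[(pts[:, 1] > cmin + 3) & (pts[:, 1] < cmax - 3)]
        for sgn in (+1, -1):
            edge = row_c + sgn * 4.0
            sel = side[np.sign(side[:, 0] - row_c) == sgn]
            rms = np.sqrt(np.mean((sel[:, 0] - edge) ** 2))
            assert rms <= 0.75, f"side {sgn} RMS {rms}"


class TestInitializeVesselContour:
    def test_margin_zero_contour_on_mask_boundary(self, tube_phantom):
        img, truth = tube_phantom
        mask = binarize(img)
        br = trace_branches(skeletonize(mask))[0]
        c = initialize_vessel_contour(mask, br, margin=0)
        # subpixel boundary lies within half a pixel of the mask edge
        from scipy import ndimage
        dist_out = ndimage.distance_transform_edt(~mask.astype(bool))
        dist_in = ndimage.distance_transform_edt(mask.astype(bool))
        d = sample_field((dist_out - dist_in).astype(float), c.points)
        assert np.abs(d).max() <= 1.0

    def test_counterclockwise_orientation(self, tube_phantom):
        img, _ = tube_phantom
        mask = binarize(img)
        br = trace_branches(skeletonize(mask))[0]
        c = initialize_vessel_contour(mask, br, margin=2)
        x, y = c.points[:, 1], -c.points[:, 0]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area > 0

    def test_disjoint_vessel_not_enclosed(self):
        img = np.full((96, 96), 50.0)
        img[20:26, 10:86] = 200.0
        img[70:76, 10:86] = 200.0
        mask = binarize(img)
        branches = trace_branches(skeletonize(mask))
        first = min(branches, key=lambda b: b.points[0, 0])
        c = initialize_vessel_contour(mask, first, margin=2)
        assert c.points[:, 0].max() < 40, "second tube must stay outside"

    def test_branch_off_mask_rejected(self):
        from vesselcal import CenterlineBranch
        mask = np.zeros((20, 20), dtype=np.uint8)
        br = CenterlineBranch(points=np.array([[5, 5], [5, 6]]),
                              start_kind="endpoint", end_kind="endpoint")
        with pytest.raises(ValueError):
            initialize_vessel_contour(mask, br)
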