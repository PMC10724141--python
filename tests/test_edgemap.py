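"""Segmentation, boundary tracing, velocity/signal maps, region splits."""

import numpy as np
import pytest

import celledge as ce
from celledge.containers import CellMovie, MaskSeries
from celledge.errors import BoundaryError, ParameterError, SegmentationError

from conftest import disk_mask, make_disk_movie


def flood_fill_area(mask):
    """Independent connected-component area: breadth-first flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    best = 0
    for r0, c0 in zip(rows, cols):
        if seen[r0, c0]:
            continue
        stack, size = [(r0, c0)], 0
        seen[r0, c0] = True
        while stack:
            r, c = stack.pop()
            size += 1
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                        and mask[rr, cc] and not seen[rr, cc]):
                    seen[rr, cc] = True
                    stack.append((rr, cc))
        best = max(best, size)
    return best


class TestSegmentCell:
    def test_constant_frame_is_a_segmentation_error(self):
        movie = CellMovie(np.zeros((1, 2, 32, 32)), 0.26, 40.0, ["volume"])
        with pytest.raises(SegmentationError, match="frame 0"):
            ce.segment_cell(movie, "volume")

    def test_otsu_recovers_a_uniform_rectangle_exactly(self):
        frame = np.zeros((40, 50))
        frame[10:25, 5:30] = 100.0
        movie = CellMovie(frame[None, None], 0.26, 40.0, ["volume"])
        masks = ce.segment_cell(movie, "volume", min_area=10)
        expected = frame > 0
        np.testing.assert_array_equal(masks[0], expected)

    def test_noisy_disk_area_within_two_percent(self):
        movie = make_disk_movie([20], fg=100.0, bg=10.0, noise_sd=1.0, seed=9)
        masks = ce.segment_cell(movie, "volume")
        area = flood_fill_area(masks[0])
        assert abs(area - np.pi * 400) / (np.pi * 400) < 0.02

    def test_fixed_threshold_method(self):
        movie = make_disk_movie([15])
        masks = ce.segment_cell(movie, "volume", method="fixed_threshold",
                                fixed_threshold=55.0)
        assert masks[0].sum() == disk_mask(15).sum()


class TestExtractBoundary:
    def test_contours_have_requested_position_count(self, growing_disk_maps):
        _, _, boundaries, _ = growing_disk_maps
        for c in boundaries.contours:
            assert c.shape == (100, 2)

    def test_disk_perimeter_close_to_circumference(self):
        masks = MaskSeries(disk_mask(30)[None])
        b = ce.extract_boundary(masks, 100)
        closed = np.vstack([b.contours[0], b.contours[0][:1]])
        perimeter = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
        assert abs(perimeter - 2 * np.pi * 30) / (2 * np.pi * 30) < 0.05

    def test_identical_masks_give_identical_contours(self):
        masks = MaskSeries(np.repeat(disk_mask(20)[None], 3, axis=0))
        b = ce.extract_boundary(masks, 64)
        np.testing.assert_array_equal(b.contours[0], b.contours[1])
        np.testing.assert_array_equal(b.contours[1], b.contours[2])

    def test_mask_on_border_is_rejected(self):
        mask = np.ones((20, 20), dtype=bool)
        with pytest.raises(BoundaryError, match="border"):
            ce.extract_boundary(MaskSeries(mask[None]), 16)

    def test_too_few_positions_rejected(self):
        with pytest.raises(ParameterError, match="n_positions"):
            ce.extract_boundary(MaskSeries(disk_mask(10)[None]), 4)


class TestVelocityMap:
    def test_static_disk_has_zero_velocity(self):
        masks = MaskSeries(np.repeat(disk_mask(20)[None], 4, axis=0))
        b = ce.extract_boundary(masks, 100)
        v = ce.compute_velocity_map(b, masks, 0.26, 40.0)
        np.testing.assert_allclose(v.values, 0.0, atol=1e-9)

    def test_growing_disk_velocity_near_analytic_rate(self, growing_disk_maps):
        # 1 px/frame at 0.26 um/px and 40 s: 0.39 um/min outward
        _, _, _, v = growing_disk_maps
        assert v.values.mean() == pytest.approx(0.39, rel=0.10)
        # per-entry spread is limited by mask digitization (the 1-px ring
        # between two digitized circles genuinely varies in local width)
        assert np.all(np.abs(v.values - 0.39) < 0.25 * 0.39 + 0.06)
        assert np.all(v.values > 0)

    def test_shrinking_disk_mirrors_growing(self):
        movie = make_disk_movie([25, 24, 23, 22, 21, 20])
        masks = ce.segment_cell(movie, "volume")
        b = ce.extract_boundary(masks, 100)
        v = ce.compute_velocity_map(b, masks, 0.26, 40.0)
        assert v.values.mean() == pytest.approx(-0.39, rel=0.10)
        assert np.all(v.values < 0)

    def test_time_reversal_negates_the_map(self, growing_disk_maps):
        _, masks, _, v = growing_disk_maps
        rev = MaskSeries(masks.masks[::-1].copy())
        b_rev = ce.extract_boundary(rev, 100)
        v_rev = ce.compute_velocity_map(b_rev, rev, 0.26, 40.0)
        np.testing.assert_allclose(
            v_rev.values, -v.values[:, ::-1], atol=1e-6
        )

    def test_matches_analytic_ground_truth_on_synthetic_movie(self):
        p = ce.SyntheticParams(n_frames=31, noise_sd=0.0, coupling_gain=0.0,
                               seed=1)
        movie, truth = ce.generate_cell_movie(p)
        masks = ce.segment_cell(movie, "volume")
        b = ce.extract_boundary(masks, p.n_positions)
        v = ce.compute_velocity_map(b, masks, p.pixel_size, p.frame_interval)
        r = np.corrcoef(v.values.ravel(), truth.true_velocity_map.ravel())[0, 1]
        assert r > 0.95

    def test_frame_count_mismatch_rejected(self, growing_disk_maps):
        _, masks, boundaries, _ = growing_disk_maps
        short = MaskSeries(masks.masks[:-1].copy())
        with pytest.raises(ce.errors.DimensionError):
            ce.compute_velocity_map(boundaries, short, 0.26, 40.0)


class TestSignalMap:
    def test_uniform_intensity_gives_constant_map(self):
        movie = make_disk_movie([20, 20], fg=7.0, bg=0.0)
        masks = MaskSeries(np.repeat(disk_mask(20)[None], 2, axis=0))
        b = ce.extract_boundary(masks, 50)
        s = ce.compute_signal_map(movie, "volume", masks, b)
        np.testing.assert_allclose(s.values, 7.0)
        assert s.whole_cell_mean == pytest.approx(7.0)

    def test_zero_band_depth_rejected(self):
        movie = make_disk_movie([20])
        masks = MaskSeries(disk_mask(20)[None])
        b = ce.extract_boundary(masks, 50)
        with pytest.raises(ParameterError, match="band_depth"):
            ce.compute_signal_map(movie, "volume", masks, b, band_depth=0.0)

    def test_gradient_disk_matches_brute_force_oracle(self):
        h = w = 61
        yy, xx = np.mgrid[0:h, 0:w]
        frame = 50.0 + 0.7 * xx + 0.3 * yy  # linear gradient
        mask = np.hypot(xx - 30.2, yy - 29.7) <= 20  # slightly off-centre
        movie = CellMovie(frame[None, None], 0.26, 40.0, ["sig"])
        masks = MaskSeries(mask[None])
        b = ce.extract_boundary(masks, 40)
        s = ce.compute_signal_map(movie, "sig", masks, b, band_depth=3.0)

        # explicit per-pixel loop: band membership from a hand-rolled
        # distance-to-background, assignment by nearest contour point
        band_px = round(3.0 / 0.26)
        bg_rows, bg_cols = np.nonzero(~mask)
        contour = b.contours[0]
        sums = np.zeros(40)
        counts = np.zeros(40)
        for r in range(h):
            for c in range(w):
                if not mask[r, c]:
                    continue
                d_bg = np.sqrt(((bg_rows - r) ** 2 + (bg_cols - c) ** 2).min())
                if d_bg > band_px:
                    continue
                d = (contour[:, 0] - c) ** 2 + (contour[:, 1] - r) ** 2
                p = int(np.argmin(d))
                sums[p] += frame[r, c]
                counts[p] += 1
        expected = sums / counts
        np.testing.assert_allclose(s.values[:, 0], expected, rtol=1e-6)
        assert s.whole_cell_mean == pytest.approx(frame[mask].mean())

    def test_volume_channel_of_uniform_synthetic_cell_is_constant(
        self, null_movie
    ):
        p, movie, _ = null_movie
        masks = ce.segment_cell(movie, "volume")
        b = ce.extract_boundary(masks, 100)
        s = ce.compute_signal_map(movie, "volume", masks, b)
        np.testing.assert_allclose(s.values, p.volume_intensity)


class TestCentralPeripheralSplit:
    def test_five_pixel_band_reports_1_3_um(self):
        masks = MaskSeries(disk_mask(20)[None])
        split = ce.split_central_peripheral(masks, band_pixels=5,
                                            pixel_size=0.26)
        assert split.band_width_um == pytest.approx(1.3)

    def test_small_disk_is_all_peripheral(self):
        masks = MaskSeries(disk_mask(3, image_size=20)[None])
        split = ce.split_central_peripheral(masks, band_pixels=5,
                                            pixel_size=0.26)
        assert split.central[0].sum() == 0
        np.testing.assert_array_equal(split.peripheral[0], masks[0])

    def test_peripheral_area_close_to_annulus(self):
        masks = MaskSeries(disk_mask(20)[None])
        split = ce.split_central_peripheral(masks, band_pixels=5,
                                            pixel_size=0.26)
        annulus = np.pi * (20**2 - 15**2)
        assert abs(split.peripheral[0].sum() - annulus) / annulus < 0.05

    def test_regions_partition_the_mask_exactly(self):
        masks = MaskSeries(disk_mask(17)[None])
        split = ce.split_central_peripheral(masks, band_pixels=5,
                                            pixel_size=0.26)
        union = split.peripheral[0] | split.central[0]
        inter = split.peripheral[0] & split.central[0]
        np.testing.assert_array_equal(union, masks[0])
        assert not inter.any()


class TestRescaleMapPositions:
    def test_same_size_is_identity(self, growing_disk_maps):
        _, _, _, v = growing_disk_maps
        out = ce.rescale_map_positions(v, 100)
        np.testing.assert_allclose(out.values, v.values, atol=1e-12)

    def test_constant_map_stays_constant(self):
        v = ce.VelocityMap(np.full((30, 8), 0.5), 0.26, 40.0)
        out = ce.rescale_map_positions(v, 100)
        np.testing.assert_allclose(out.values, 0.5)

    def test_interior_ramp_preserved(self):
        ramp = np.linspace(0, 1, 50)[:, None] * np.ones((1, 4))
        v = ce.VelocityMap(ramp, 0.26, 40.0)
        out = ce.rescale_map_positions(v, 200)
        # away from the circular wrap the ramp is reproduced linearly
        pos = np.arange(200) * 50 / 200
        interior = (pos >= 1) & (pos <= 48)
        expected = pos[interior] / 49
        np.testing.assert_allclose(out.values[interior, 0], expected,
                                   atol=1e-6)

    def test_too_few_output_rows_rejected(self, growing_disk_maps):
        _, _, _, v = growing_disk_maps
        with pytest.raises(ParameterError, match="n_out"):
            ce.rescale_map_positions(v, 1)
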