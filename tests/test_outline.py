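"""Segmentation and the five outline indices against analytic oracles."""

import numpy as np
import pytest

from mycophen import outline, plate_io, synth

from conftest import small_spec


def _disk_mask(r, pad=4):
    n = int(np.ceil(r)) + pad
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    return xx ** 2 + yy ** 2 <= r * r


def _ellipse_mask(a, b, pad=4):
    n = int(np.ceil(max(a, b))) + pad
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    return (xx / a) ** 2 + (yy / b) ** 2 <= 1.0


class TestSegmentation:
    def test_zero_noise_iou(self, small_plate, small_calib):
        _, img, truth = small_plate
        mask = outline.segment_mycelium(img, small_calib)
        inter = (mask.mask & truth.colony_mask).sum()
        union = (mask.mask | truth.colony_mask).sum()
        assert inter / union >= 0.97

    def test_noisy_grooved_iou(self, small_calib):
        spec = small_spec(noise_sigma=4.0, groove_amplitude=15.0, seed=5)
        img, truth = synth.render_plate(spec)
        mask = outline.segment_mycelium(img, small_calib)
        inter = (mask.mask & truth.colony_mask).sum()
        union = (mask.mask | truth.colony_mask).sum()
        assert inter / union >= 0.95

    def test_blank_dish_flagged_empty(self, small_calib):
        spec = small_spec()
        img = np.full((256, 256), spec.background_gray, dtype=np.uint8)
        mask = outline.segment_mycelium(img, small_calib)
        assert mask.empty and mask.pixel_count == 0 and mask.boundary_count == 0

    def test_colony_filling_dish(self):
        spec = synth.ColonySpec(colony_semi_axis_h=44.9, colony_semi_axis_v=44.9)
        img, truth = synth.render_plate(spec)
        calib = plate_io.detect_dish(np.zeros_like(img), detector="provided_mask",
                                     dish_mask=truth.dish_mask)
        mask = outline.segment_mycelium(img, calib)
        assert not mask.empty
        assert mask.pixel_count == pytest.approx(calib.interior_pixel_count, rel=0.02)

    def test_counts_match_brute_force(self, small_plate, small_calib):
        _, img, _ = small_plate
        mask = outline.segment_mycelium(img, small_calib)
        assert mask.pixel_count == int(mask.mask.sum())
        rows, cols = np.nonzero(mask.mask)
        axes = outline.bounding_axes(mask)
        assert axes.ZL == cols.max() - cols.min() + 1
        assert axes.ZS == rows.max() - rows.min() + 1


class TestBoundary:
    def test_single_pixel(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        nv, _ = outline.trace_boundary(m)
        assert nv == 1

    def test_filled_square_edge_count(self):
        m = np.zeros((14, 14), dtype=bool)
        m[2:12, 2:12] = True  # 10x10: edge pixels = 4*10 - 4
        nv, poly = outline.trace_boundary(m)
        assert nv == 36
        assert len(poly) > 0

    def test_digitized_disk_circumference(self):
        nv, _ = outline.trace_boundary(_disk_mask(100))
        assert 0.85 * 2 * np.pi * 100 <= nv <= 1.15 * 2 * np.pi * 100

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            outline.trace_boundary(np.zeros((4, 4), dtype=bool))


class TestBoundingAxes:
    def test_single_pixel(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1, 3] = True
        axes = outline.bounding_axes(m)
        assert (axes.ZL, axes.ZS) == (1, 1)

    def test_digitized_disk_extent(self):
        axes = outline.bounding_axes(_disk_mask(100))
        assert abs(axes.ZL - 201) <= 1 and abs(axes.ZS - 201) <= 1

    def test_ellipse_extent(self):
        axes = outline.bounding_axes(_ellipse_mask(100, 50))
        assert abs(axes.ZL - 201) <= 1 and abs(axes.ZS - 101) <= 1

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            outline.bounding_axes(np.zeros((4, 4), dtype=bool))


class TestIndices:
    def test_radius_circle(self, small_plate, small_calib):
        _, img, _ = small_plate
        feats = outline.measure_outline(img, small_calib)
        assert feats.R_mm == pytest.approx(15.0, rel=0.02)

    def test_radius_ellipse_is_mean_semi_extent(self, small_calib):
        spec = small_spec(colony_semi_axis_h=10.0, colony_semi_axis_v=20.0)
        img, _ = synth.render_plate(spec)
        feats = outline.measure_outline(img, small_calib)
        assert feats.R_mm == pytest.approx(15.0, rel=0.02)

    def test_perimeter_circle(self, small_plate, small_calib):
        _, img, _ = small_plate
        feats = outline.measure_outline(img, small_calib)
        assert feats.L_mm == pytest.approx(2 * np.pi * 15, rel=0.05)

    def test_area_circle(self, small_plate, small_calib):
        _, img, _ = small_plate
        feats = outline.measure_outline(img, small_calib)
        assert feats.A_mm2 == pytest.approx(np.pi * 15 ** 2, rel=0.03)

    def test_saturated_dish_indices(self):
        spec = synth.ColonySpec(colony_semi_axis_h=44.9, colony_semi_axis_v=44.9)
        img, truth = synth.render_plate(spec)
        calib = plate_io.detect_dish(np.zeros_like(img), detector="provided_mask",
                                     dish_mask=truth.dish_mask)
        feats = outline.measure_outline(img, calib)
        assert feats.R_mm == pytest.approx(45.0, rel=0.02)
        assert feats.L_mm == pytest.approx(2 * np.pi * 45, rel=0.05)
        assert feats.A_mm2 == pytest.approx(np.pi * 45 ** 2, rel=0.02)

    def test_monotone_in_colony_size(self, small_calib):
        vals = []
        for r in (8.0, 12.0, 16.0, 20.0):
            img, _ = synth.render_plate(small_spec(colony_semi_axis_h=r,
                                                   colony_semi_axis_v=r))
            vals.append(outline.measure_outline(img, small_calib))
        for a, b in zip(vals, vals[1:]):
            assert b.R_mm > a.R_mm and b.L_mm > a.L_mm and b.A_mm2 > a.A_mm2

    @pytest.mark.parametrize("a,b", [(15, 15), (10, 20), (25, 18), (8, 8)])
    def test_isoperimetric_bound(self, small_calib, a, b):
        img, _ = synth.render_plate(small_spec(colony_semi_axis_h=a,
                                               colony_semi_axis_v=b))
        feats = outline.measure_outline(img, small_calib)
        assert feats.L_mm ** 2 / (4 * np.pi * feats.A_mm2) >= 0.9


class TestRates:
    def test_growth_rate_zero_and_value(self):
        assert outline.growth_rate(outline.TimepointPair(10, 10, 1, 1)) == 0.0
        pair = outline.TimepointPair(R1=7.63, R2=29.59, A1=0, A2=0)
        assert outline.growth_rate(pair) == pytest.approx(3.66, abs=0.005)

    def test_change_speed_value(self):
        pair = outline.TimepointPair(R1=0, R2=0, A1=600.0, A2=3300.0)
        assert outline.change_speed(pair) == pytest.approx(450.0)

    def test_negative_growth_flagged_not_clamped(self):
        pair = outline.TimepointPair(R1=10.0, R2=4.0, A1=5, A2=5)
        with pytest.warns(UserWarning, match="negative"):
            assert outline.growth_rate(pair) == pytest.approx(-1.0)

    def test_nonincreasing_days_rejected(self):
        with pytest.raises(ValueError, match="t2"):
            outline.TimepointPair(R1=1, R2=2, A1=1, A2=2, t1=8, t2=8)
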