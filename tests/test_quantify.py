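import math

import numpy as np
import pytest
from scipy import ndimage

from platequant import CoordinateError
from platequant.gridfit import GridLayout
from platequant.quantify import (
    ColonyBounds,
    ColonyMeasurement,
    fit_colony_bounds,
    flag_colony,
    flag_plate,
    measure_colony,
    quantify_plate,
)
from platequant.synth import SyntheticPlateSpec, generate_plate
from conftest import run_pipeline


def disk_mask(shape, cy, cx, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def oracle_measure(crop):
    """Brute-force area/perimeter/circularity by per-pixel neighbor loops."""
    crop = np.asarray(crop, bool)
    h, w = crop.shape
    A = P = 0
    for i in range(h):
        for j in range(w):
            if not crop[i, j]:
                continue
            A += 1
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not crop[ni, nj]:
                    P += 1
                    break
    return A, P, (4 * math.pi * A / P**2 if A else 0.0)


def make_measurement(size, circularity):
    return ColonyMeasurement(
        row=1, col=1, x=0, y=0, size=size, circularity=circularity,
        bounds=ColonyBounds(0, 0, 0, 0),
    )


class TestFitColonyBounds:
    def test_isolated_disk_fully_enclosed(self):
        mask = disk_mask((100, 100), 50, 50, 10)
        b = fit_colony_bounds(mask, (50, 50), 40.0)
        assert b.source == "fitted"
        outside = mask.copy()
        outside[b.top : b.bottom + 1, b.left : b.right + 1] = False
        assert not outside.any()

    def test_background_center_gives_default_square(self):
        b = fit_colony_bounds(np.zeros((100, 100), bool), (50, 50), 40.0)
        assert b.source == "default-square"
        assert b.right - b.left == 40 and b.bottom - b.top == 40

    def test_boundary_falls_between_touching_neighbors(self):
        mask = disk_mask((100, 160), 50, 60, 10) | disk_mask((100, 160), 50, 100, 10)
        b = fit_colony_bounds(mask, (50, 60), 40.0)
        # right boundary lands in the inter-colony valley
        assert 70 <= b.right <= 90

    def test_center_outside_image_rejected(self):
        with pytest.raises(CoordinateError):
            fit_colony_bounds(np.zeros((50, 50), bool), (80, 10), 40.0)


class TestMeasureColony:
    def test_empty_region_convention(self):
        assert measure_colony(
            np.zeros((30, 30), bool), ColonyBounds(5, 25, 5, 25)
        ) == (0, 0, 0.0)

    def test_solid_square(self):
        mask = np.zeros((40, 40), bool)
        mask[10:30, 10:30] = True
        A, P, circ = measure_colony(mask, ColonyBounds(5, 34, 5, 34))
        assert (A, P) == (400, 76)
        assert circ == pytest.approx(4 * math.pi * 400 / 76**2)

    def test_single_pixel_reported_as_computed(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        A, P, circ = measure_colony(mask, ColonyBounds(0, 4, 0, 4))
        assert (A, P) == (1, 1)
        assert circ == pytest.approx(4 * math.pi)

    @pytest.mark.parametrize("builder", [
        lambda m: disk_mask(m, 20, 20, 15),
        lambda m: disk_mask(m, 20, 20, 7) | disk_mask(m, 20, 26, 7),
        lambda m: np.pad(np.ones((8, 30), bool), 5)[: m[0], : m[1]],
    ])
    def test_matches_bruteforce_oracle(self, builder):
        mask = builder((41, 41))
        bounds = ColonyBounds(0, 40, 0, 40)
        assert measure_colony(mask, bounds) == pytest.approx(oracle_measure(mask))

    def test_bounds_edge_counts_as_background(self):
        # a colony clipped by the rectangle contributes perimeter at the edge
        mask = np.ones((10, 10), bool)
        A, P, _ = measure_colony(mask, ColonyBounds(0, 9, 0, 9))
        assert A == 100 and P == 36


class TestFlagColony:
    def test_isolated_disk_unflagged(self):
        mask = disk_mask((100, 100), 50, 50, 10)
        b = fit_colony_bounds(mask, (50, 50), 40.0)
        A, _, circ = measure_colony(mask, b)
        m = ColonyMeasurement(1, 1, 50, 50, A, circ, b)
        assert flag_colony(m, mask) == []

    def test_merged_colonies_flag_overlap(self):
        mask = disk_mask((100, 160), 50, 60, 12) | disk_mask((100, 160), 50, 84, 12)
        b = fit_colony_bounds(mask, (50, 60), 40.0)
        A, _, circ = measure_colony(mask, b)
        m = ColonyMeasurement(1, 1, 60, 50, A, circ, b)
        assert "overlap" in flag_colony(m, mask)

    def test_elongated_bar_flags_low_circularity(self):
        mask = np.zeros((60, 60), bool)
        mask[28:32, 10:50] = True  # 40x4 bar, circularity ~ 0.285
        b = ColonyBounds(20, 40, 5, 55)
        A, P, circ = measure_colony(mask, b)
        assert circ == pytest.approx(4 * math.pi * 160 / 84**2)
        m = ColonyMeasurement(1, 1, 30, 30, A, circ, b)
        assert "lowcirc" in flag_colony(m, mask)


class TestFlagPlate:
    def test_ten_percent_tiny_flags(self):
        ms = [make_measurement(100, 1.0)] * 90 + [make_measurement(5, 1.0)] * 10
        assert "many-small-colonies" in flag_plate(ms)

    def test_nine_percent_tiny_does_not_flag(self):
        ms = [make_measurement(100, 1.0)] * 91 + [make_measurement(5, 1.0)] * 9
        assert flag_plate(ms) == []

    def test_homogeneous_plate_clean(self):
        assert flag_plate([make_measurement(80, 0.95)] * 96) == []

    def test_low_circularity_fraction(self):
        ms = [make_measurement(100, 0.9)] * 90 + [make_measurement(100, 0.5)] * 10
        assert flag_plate(ms) == ["many-low-circularity"]

    @pytest.mark.parametrize("n_bad, flagged", [(9, False), (10, True), (11, True)])
    def test_threshold_is_a_step_function(self, n_bad, flagged):
        ms = [make_measurement(100, 1.0)] * (100 - n_bad) + \
             [make_measurement(2, 1.0)] * n_bad
        assert ("many-small-colonies" in flag_plate(ms)) is flagged


class TestQuantifyPlate:
    def test_exact_area_recovery(self, clean_96):
        rgb, truth, spec = clean_96
        mask, grid = run_pipeline(rgb, spec.n_rows, spec.n_cols)
        result = quantify_plate(mask, grid)
        expected = np.array([c.pixel_count for c in truth.cells])
        np.testing.assert_array_equal(result.sizes, expected)

    def test_speckles_removed_areas_match_erosion_oracle(self):
        spec = SyntheticPlateSpec(seed=21, speckle_count=200)
        rgb, truth = generate_plate(spec)
        mask, grid = run_pipeline(rgb, spec.n_rows, spec.n_cols)
        result = quantify_plate(mask, grid, remove_noise=True)
        structure = np.ones((3, 3), bool)
        speckle_mask = np.zeros(mask.shape, bool)
        speckle_mask[truth.speckles[:, 0], truth.speckles[:, 1]] = True
        for cell, m in zip(truth.cells, result.measurements):
            # oracle: erode the ground-truth disk plus any speckles (a
            # speckle fused to a colony rim can rescue a rim pixel)
            ideal = disk_mask(mask.shape, int(cell.y), int(cell.x), cell.radius)
            eroded = ndimage.binary_erosion(
                ideal | speckle_mask, structure, border_value=0
            )
            b = m.bounds
            expected = eroded[b.top : b.bottom + 1, b.left : b.right + 1].sum()
            assert m.size == expected

    def test_empty_cell_reports_zero_without_overlap(self):
        spec = SyntheticPlateSpec(seed=22, missing_fraction=0.15)
        rgb, truth = generate_plate(spec)
        mask, grid = run_pipeline(rgb, spec.n_rows, spec.n_cols)
        result = quantify_plate(mask, grid)
        absent = [m for c, m in zip(truth.cells, result.measurements)
                  if not c.present]
        assert absent
        for m in absent:
            assert m.size == 0 and m.circularity == 0.0
            assert "overlap" not in m.flags

    def test_size_monotone_in_radius(self):
        radii = {(1, c): 3 + c for c in range(1, 9)}
        radii.update({(r, c): 10 for r in (2, 3, 4) for c in range(1, 9)})
        spec = SyntheticPlateSpec(
            seed=23, n_rows=4, n_cols=8, spacing=44, radius_sampler=radii,
        )
        rgb, _ = generate_plate(spec)
        mask, grid = run_pipeline(rgb, 4, 8)
        sizes = quantify_plate(mask, grid).sizes[:8]
        assert (np.diff(sizes) > 0).all()

    def test_disks_rounder_than_bars(self):
        mask = np.zeros((120, 120), bool)
        mask[20:70, 30:40] = True          # 5:1 rectangle, area 500
        mask |= disk_mask((120, 120), 90, 60, 13)  # disk, area ~531
        _, _, circ_bar = measure_colony(mask, ColonyBounds(15, 75, 25, 45))
        _, _, circ_disk = measure_colony(mask, ColonyBounds(75, 105, 45, 75))
        assert circ_disk > circ_bar

    def test_row_major_ordering(self, clean_96):
        rgb, _, spec = clean_96
        mask, grid = run_pipeline(rgb, spec.n_rows, spec.n_cols)
        result = quantify_plate(mask, grid)
        for k, m in enumerate(result.measurements):
            assert m.row == 1 + k // spec.n_cols
            assert m.col == 1 + k % spec.n_cols
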