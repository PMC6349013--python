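"""Well segmentation, DW/SW taxonomy, pocket statistics, summary rows."""

import numpy as np
import pytest

from bindscape.errors import InputError
from bindscape.geometry import GeoPosition, geo_to_unit
from bindscape.landscape import GridMap, assign_cell, build_grid, cell_center
from bindscape.wells import (
    PocketMask,
    fraction_percent,
    high_bp_cells,
    high_bp_fraction,
    pocket_fraction,
    probability_surface,
    segment_wells,
    summarize_system,
    summary_table,
)


def grid_with(dG_patches=(), count_patches=()):
    """Construct a GridMap by painting rectangular patches.

    Patches are (i_lon0, i_lat0, w, h, value); dG defaults to 0 everywhere
    (a flat landscape) so wells exist only where painted.
    """
    grid = GridMap()
    grid.dG[:, :] = 0.0
    grid.counts[:, :] = 1
    for i_lon0, i_lat0, w, h, v in dG_patches:
        for dx in range(w):
            for dy in range(h):
                grid.dG[(i_lat0 + dy) % 60, (i_lon0 + dx) % 120] = v
    for i_lon0, i_lat0, w, h, v in count_patches:
        for dx in range(w):
            for dy in range(h):
                grid.counts[(i_lat0 + dy) % 60, (i_lon0 + dx) % 120] = v
    return grid


def naive_label_without_wrap(mask):
    """Flood fill with 8-connectivity but no longitude wrap (the control)."""
    from skimage.measure import label

    return label(mask, connectivity=2)


class TestSegmentWells:
    def test_flat_landscape_has_no_wells(self):
        assert segment_wells(grid_with()) == []

    def test_single_block_is_one_deep_well(self):
        grid = grid_with([(50, 30, 3, 3, -10.0)])
        wells = segment_wells(grid)
        assert len(wells) == 1
        w = wells[0]
        assert w.category == "DW" and w.area == 9 and w.min_dG == -10.0

    def test_shallow_well_category(self):
        wells = segment_wells(grid_with([(10, 10, 2, 2, -6.0)]))
        assert [w.category for w in wells] == ["SW"]

    def test_boundary_band_cells_are_not_wells(self):
        # the -4.1..0 band is barrier, not well; strict < at the threshold
        wells = segment_wells(grid_with([(10, 10, 2, 2, -4.1)]))
        assert wells == []

    def test_dateline_block_is_one_well_where_naive_labeling_splits_it(self):
        grid = grid_with([(118, 20, 4, 3, -9.0)])  # wraps 118,119,0,1
        mask = np.where(np.isnan(grid.dG), False, grid.dG < -4.1)
        naive = naive_label_without_wrap(mask)
        assert naive.max() == 2  # the control genuinely splits the block
        wells = segment_wells(grid)
        assert len(wells) == 1
        assert wells[0].area == 12

    def test_well_cut_monotonicity_and_dw_nesting(self):
        grid = grid_with(
            [(30, 30, 2, 2, -9.0), (31, 31, 3, 2, -5.0), (70, 10, 2, 2, -4.5)]
        )
        loose = segment_wells(grid, well_cut=-4.1)
        tight = segment_wells(grid, well_cut=-4.8)
        assert sum(w.area for w in tight) <= sum(w.area for w in loose)
        loose_cells = {c for w in loose for c in w.cells}
        for w in tight:
            assert set(w.cells) <= loose_cells
        # every DW member cell is a well cell under the outer threshold
        for w in loose:
            if w.category == "DW":
                assert w.min_dG < -8.2


class TestPocketFraction:
    @pytest.mark.parametrize(
        "total,inside,expected",
        [(99, 78, 78.79), (83, 49, 59.04), (54, 6, 11.11), (0, 0, 0.00),
         (20, 0, 0.00)],
    )
    def test_printed_deep_well_percentages(self, total, inside, expected):
        assert fraction_percent(inside, total) == expected

    def test_counts_dw_member_cells_against_mask(self):
        grid = grid_with([(60, 30, 3, 3, -9.0), (10, 10, 2, 2, -9.0)])
        wells = segment_wells(grid)
        center = cell_center(61, 31)
        mask = PocketMask(center=center, radius_deg=8.0)
        total, inside, pct = pocket_fraction(wells, mask)
        assert total == 13
        assert inside == 9
        assert pct == fraction_percent(9, 13)


class TestHighBp:
    @pytest.mark.parametrize(
        "total,inside,expected", [(11, 7, 63.64), (11, 1, 9.09), (18, 6, 33.33)]
    )
    def test_printed_high_bp_percentages(self, total, inside, expected):
        assert fraction_percent(inside, total) == expected

    def test_strict_threshold(self):
        grid = grid_with(count_patches=[(0, 0, 120, 60, 360)])
        assert high_bp_cells(grid) == set()
        grid.counts[5, 5] = 361
        assert high_bp_cells(grid) == {(5, 5)}

    def test_threshold_monotonicity(self):
        grid = grid_with(count_patches=[(10, 10, 4, 4, 500), (50, 50, 2, 2, 380)])
        assert high_bp_cells(grid, 450) <= high_bp_cells(grid, 360)

    def test_fraction_against_cap_mask(self):
        grid = grid_with(count_patches=[(60, 30, 2, 2, 400)])
        cells = high_bp_cells(grid)
        mask = PocketMask(center=cell_center(60, 30), radius_deg=4.0)
        total, inside, pct = high_bp_fraction(cells, mask)
        assert total == 4 and 1 <= inside <= 4
        assert pct == fraction_percent(inside, total)


class TestPocketMask:
    def test_cap_contains_its_center_cell(self):
        mask = PocketMask(center=cell_center(60, 30), radius_deg=15.0)
        assert mask.contains(60, 30)
        assert not mask.contains(0, 0)

    def test_explicit_cells(self):
        mask = PocketMask(cells={(1, 2), (3, 4)})
        assert mask.contains(1, 2) and not mask.contains(2, 1)

    @pytest.mark.parametrize("radius", [0, -5, 95])
    def test_invalid_cap_radius_raises(self, radius):
        with pytest.raises(InputError):
            PocketMask(center=GeoPosition(0, 0), radius_deg=radius)

    def test_empty_mask_raises(self):
        with pytest.raises(InputError):
            PocketMask()


class TestProbabilitySurface:
    def test_all_zero_counts_give_zero_surface(self):
        grid = GridMap()
        surf = probability_surface(grid)
        assert np.all(surf(np.array([[0.0, 0.0], [90.0, 45.0]])) == 0)

    def test_single_occupied_cell_peaks_there(self):
        grid = GridMap()
        grid.counts[30, 60] = 50
        surf = probability_surface(grid)
        c = cell_center(60, 30)
        probe = np.array(
            [[c.lon, c.lat], [c.lon + 30, c.lat], [c.lon, c.lat - 40]]
        )
        z = surf(probe)
        assert z[0] == max(z)

    def test_two_well_run_maxima_near_true_centers(self, small_run, two_well):
        pos, en = small_run.bound_geo_energy()
        grid = build_grid(pos, en, B=2, seed=0)
        surf = probability_surface(grid, lam=0.0)
        for center, _, _ in two_well.wells:
            # probe the cap around the true center on cell centers
            best, best_z = None, -np.inf
            for i_lon in range(120):
                for i_lat in range(20, 40):
                    c = cell_center(i_lon, i_lat)
                    d = np.degrees(
                        np.arccos(
                            np.clip(
                                np.dot(geo_to_unit(c), geo_to_unit(center)),
                                -1, 1,
                            )
                        )
                    )
                    if d < 15:
                        z = float(surf(np.array([[c.lon, c.lat]]))[0])
                        if z > best_z:
                            best, best_z = (i_lon, i_lat), z
            true_cell = assign_cell(center)
            assert abs(best[0] - true_cell[0]) <= 1
            assert abs(best[1] - true_cell[1]) <= 1


class TestSummary:
    def _inputs(self, small_run):
        pos, en = small_run.bound_geo_energy()
        grid = build_grid(pos, en, B=10, seed=3)
        wells = segment_wells(grid)
        mask = PocketMask.cap_at_minimum(grid, radius_deg=15.0)
        return grid, wells, mask

    def test_row_matches_simulator_ground_truth(self, small_run):
        grid, wells, mask = self._inputs(small_run)
        row = summarize_system("sim", grid, wells, mask, seed=3)
        assert row["dw_cells_total"] >= row["dw_cells_inside_pocket"] > 0
        # the deep well minimum sits at the true deep-well center cell
        dw = [w for w in wells if w.category == "DW"]
        assert dw, "deep well must be recovered"
        true_cell = assign_cell(small_run.potential.wells[0][0])
        deepest = min(dw, key=lambda w: w.min_dG)
        assert abs(deepest.min_cell[0] - true_cell[0]) <= 1
        assert abs(deepest.min_cell[1] - true_cell[1]) <= 1
        assert row["landscape_sd_max"] > 0

    def test_identical_seeds_give_identical_rows(self, small_run):
        grid, wells, mask = self._inputs(small_run)
        r1 = summarize_system("sim", grid, wells, mask, seed=9)
        r2 = summarize_system("sim", grid, wells, mask, seed=9)
        assert r1 == r2

    def test_zero_bound_run_yields_empty_row(self):
        grid = GridMap()
        row = summarize_system("empty", grid, [], PocketMask(cells={(0, 0)}))
        assert row["dw_cells_total"] == 0
        assert row["high_bp_cells_total"] == 0
        assert row["effective_binding_pct"] == 0.00

    def test_table_assembly(self, small_run):
        grid, wells, mask = self._inputs(small_run)
        df = summary_table([summarize_system("a", grid, wells, mask)])
        assert list(df["system"]) == ["a"]
        assert "dw_inside_pct" in df.columns
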