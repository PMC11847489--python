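import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from shapely.geometry import box

from nichecast.changes import (BinaryMap, binarize, centroid, change_map,
                               change_summary, mpa_overlap, mtss_threshold,
                               shift, summary_from_areas, LOST, GAINED,
                               MAINTAINED)
from nichecast.raster import (CellAreaLayer, Grid, RasterLayer, RegionPolygons,
                              cell_areas)


def layer(values, origin=(140.0, -34.0), cell=0.05, mask=None):
    values = np.asarray(values, dtype=float)
    grid = Grid(origin[0], origin[1], cell, *values.shape)
    if mask is None:
        mask = np.zeros(values.shape, bool)
    return RasterLayer(grid, values, mask, "suit")


def exhaustive_mtss(sp, sb):
    """Oracle: scan every pooled candidate threshold."""
    cand = np.unique(np.concatenate([sp, sb]))
    best_t, best_sum = None, -1.0
    for t in cand:  # ascending: first maximizer is the smallest
        sens = np.mean(sp >= t)
        spec = np.mean(sb < t)
        if sens + spec > best_sum + 1e-12:
            best_sum, best_t = sens + spec, t
    return best_t


class TestMTSS:
    def test_separated_scores(self):
        res = mtss_threshold([0.8, 0.9], [0.1, 0.2])
        assert res.threshold == 0.8
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_no_signal_returns_smallest_maximizer(self):
        scores = [0.2, 0.5, 0.8]
        res = mtss_threshold(scores, scores)
        assert res.threshold == exhaustive_mtss(np.array(scores), np.array(scores))
        assert res.sensitivity + res.specificity == pytest.approx(1.0)

    def test_overlapping_toy_matches_exhaustive_scan(self):
        sp = np.array([0.9, 0.8, 0.4])
        sb = np.array([0.1, 0.2, 0.6])
        res = mtss_threshold(sp, sb)
        assert res.threshold == exhaustive_mtss(sp, sb)
        assert res.sensitivity + res.specificity == pytest.approx(5 / 3)

    def test_degenerate_identical_scores_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = mtss_threshold([0.5, 0.5], [0.5])
        assert res.threshold == 0.5 and res.degenerate

    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_exhaustive_scan_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        sp = rng.choice(np.linspace(0, 1, 21), size=rng.integers(2, 20))
        sb = rng.choice(np.linspace(0, 1, 21), size=rng.integers(2, 20))
        assert mtss_threshold(sp, sb).threshold == exhaustive_mtss(sp, sb)


class TestBinarize:
    def test_zero_threshold_all_suitable(self):
        b = binarize(layer(np.random.default_rng(0).random((3, 3))), 0.0)
        assert b.suitable.sum() == 9

    def test_threshold_above_max_none_suitable(self):
        b = binarize(layer(np.full((3, 3), 0.4)), 0.9)
        assert b.suitable.sum() == 0

    def test_toy_grid_counts_with_equality_suitable(self):
        vals = np.arange(0.1, 1.0, 0.1).reshape(3, 3)
        b = binarize(layer(vals), 0.5)
        assert b.suitable.sum() == 5  # 0.5 counts as suitable

    def test_nodata_preserved(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = True
        b = binarize(layer(np.full((3, 3), 0.9), mask=mask), 0.5)
        assert not b.suitable[0, 0]
        assert b.layer.nodata_mask[0, 0]


class TestChangeAccounting:
    def test_identical_maps_all_maintained(self):
        vals = (np.random.default_rng(1).random((4, 4)) > 0.5).astype(float)
        cur = binarize(layer(vals), 0.5)
        cm = change_map(cur, cur)
        s = change_summary(cm, cell_areas(cur.layer.grid))
        assert s.lost_km2 == 0 and s.gained_km2 == 0
        assert s.maintained_km2 == pytest.approx(s.total_current_km2)
        assert s.total_change_pct == 0

    def test_hand_counted_ten_cell_toy(self):
        cur = np.zeros((2, 5))
        fut = np.zeros((2, 5))
        cur[0, :5] = 1
        cur[1, 0] = 1           # 6 currently suitable
        fut[0, 1:5] = 1         # 4 persist
        fut[1, 3:5] = 1         # 2 newly gained
        cur_b = binarize(layer(cur, origin=(0.0, 0.1)), 0.5)
        fut_b = binarize(layer(fut, origin=(0.0, 0.1)), 0.5)
        cm = change_map(cur_b, fut_b)
        codes = cm.layer.values
        assert (codes == MAINTAINED).sum() == 4
        assert (codes == LOST).sum() == 2
        assert (codes == GAINED).sum() == 2
        # equal-area cells at this scale: percentages from cell counts
        s = change_summary(cm, cell_areas(cur_b.layer.grid))
        assert s.pct_lost == pytest.approx(100 * 2 / 6, rel=1e-4)

    def test_grid_mismatch_rejected(self):
        a = binarize(layer(np.ones((2, 2))), 0.5)
        b = binarize(layer(np.ones((3, 3))), 0.5)
        with pytest.raises(ValueError):
            change_map(a, b)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_conservation_identities_exact(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(2, 8), rng.integers(2, 8))
        cur = binarize(layer(rng.random(shape)), 0.5)
        fut = binarize(layer(rng.random(shape)), 0.5)
        cm = change_map(cur, fut)
        codes = cm.layer.values
        assert ((codes == MAINTAINED) | (codes == LOST)).sum() == cur.suitable.sum()
        assert ((codes == MAINTAINED) | (codes == GAINED)).sum() == fut.suitable.sum()
        s = change_summary(cm, cell_areas(cur.layer.grid))
        assert s.maintained_km2 + s.lost_km2 == pytest.approx(s.total_current_km2, abs=1e-6)
        assert s.maintained_km2 + s.gained_km2 == pytest.approx(s.total_future_km2, abs=1e-6)


class TestPublishedTableIdentities:
    """Percentage formulas reproduce the published table values exactly
    (at printed precision) from the printed km² inputs."""

    def test_high_emission_end_of_century_row(self):
        s = summary_from_areas(322114, 90178, 45990, 44188, 276123)
        assert round(s.total_change_pct, 1) == -72.0
        assert round(s.pct_maintained, 1) == 14.3
        assert round(s.pct_gained, 1) == 13.7
        assert round(s.pct_lost, 1) == 85.7

    def test_sustainability_end_of_century_row(self):
        s = summary_from_areas(322114, 327945, 301943, 26003, 20174)
        assert round(s.total_change_pct, 1) == 1.8
        assert round(s.pct_maintained, 1) == 93.7

    TABLE1 = [
        # current, future, maintained, gained, lost, (pct_m, pct_g, pct_l, total)
        (322114, 319415, 294540, 24880, 27565, 91.4, 7.7, 8.6, -0.8),
        (322114, 300242, 262589, 37664, 59528, 81.5, 11.7, 18.5, -6.8),
        (322114, 280954, 234545, 46419, 87574, 72.8, 14.4, 27.2, -12.8),
        (322114, 281461, 228057, 53413, 94068, 70.8, 16.6, 29.2, -12.6),
        (322114, 289283, 243277, 46017, 78844, 75.5, 14.3, 24.5, -10.2),
        (322114, 257018, 201000, 56027, 121118, 62.4, 17.4, 37.6, -20.2),
        (322114, 327945, 301943, 26003, 20174, 93.7, 8.1, 6.3, 1.8),
        (322114, 272900, 217734, 55177, 104388, 67.6, 17.1, 32.4, -15.3),
        (322114, 246481, 128565, 117926, 193550, 39.9, 36.6, 60.1, -23.5),
        (322114, 166682, 73406, 93276, 248714, 22.8, 29.0, 77.2, -48.3),
        (322114, 242219, 100040, 142187, 222077, 31.1, 44.1, 68.9, -24.8),
        (322114, 90178, 45990, 44188, 276123, 14.3, 13.7, 85.7, -72.0),
    ]

    @pytest.mark.parametrize("row", TABLE1)
    def test_full_table_percentage_sweep(self, row):
        cur, fut, m, g, l, pm, pg, pl, tc = row
        s = summary_from_areas(cur, fut, m, g, l)
        assert round(s.pct_maintained, 1) == pm
        assert round(s.pct_gained, 1) == pg
        assert round(s.pct_lost, 1) == pl
        assert round(s.total_change_pct, 1) == tc


class TestCentroid:
    def test_single_cell_center(self):
        vals = np.zeros((3, 3))
        vals[1, 2] = 1.0
        b = binarize(layer(vals), 0.5)
        lon, lat = centroid(b, cell_areas(b.layer.grid))
        assert (lon, lat) == b.layer.grid.cell_center(1, 2)

    def test_two_equal_area_cells_midpoint(self):
        vals = np.zeros((1, 41))
        vals[0, 0] = vals[0, 40] = 1.0   # centers at 140.025 and 142.025
        b = binarize(layer(vals, origin=(140.0, -35.0)), 0.5)
        lon, lat = centroid(b, CellAreaLayer(b.layer.grid, np.ones((1, 41))))
        assert lon == pytest.approx(141.025)
        assert lat == pytest.approx(-35.025)

    def test_matches_manual_weighted_mean(self):
        rng = np.random.default_rng(7)
        vals = (rng.random((6, 4)) > 0.5).astype(float)
        b = binarize(layer(vals), 0.5)
        areas = cell_areas(b.layer.grid)
        lon, lat = centroid(b, areas)
        rows, cols = np.nonzero(vals)
        w = areas.area_km2[rows, cols]
        assert lon == pytest.approx(np.sum(w * b.layer.grid.lon_centers()[cols]) / w.sum())
        assert lat == pytest.approx(np.sum(w * b.layer.grid.lat_centers()[rows]) / w.sum())

    def test_empty_map_rejected(self):
        b = binarize(layer(np.zeros((2, 2))), 0.5)
        with pytest.raises(ValueError):
            centroid(b, cell_areas(b.layer.grid))


class TestShift:
    def test_coincident_points(self):
        s = shift((140.0, -35.0), (140.0, -35.0))
        assert s.distance_km == 0.0 and s.bearing_deg == 0.0

    def test_one_degree_equatorial_east(self):
        s = shift((0.0, 0.0), (1.0, 0.0))
        assert s.distance_km == pytest.approx(111.32, abs=0.01)
        assert s.bearing_deg == pytest.approx(90.0, abs=1e-9)

    def test_due_south_meridian_pair(self):
        s = shift((145.0, -35.0), (145.0, -36.0))
        assert s.bearing_deg == pytest.approx(180.0, abs=1e-9)

    def test_near_antipodal_falls_back_to_sphere(self):
        with pytest.warns(UserWarning, match="antipodal"):
            s = shift((0.0, 0.0), (179.7, 0.3))
        assert s.distance_km > 19000

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            shift((200.0, 0.0), (0.0, 0.0))


class TestMPAOverlap:
    def grid_map(self):
        vals = np.ones((4, 4))
        return binarize(layer(vals, origin=(0.0, 0.2)), 0.5)

    def test_full_cover_polygons(self):
        b = self.grid_map()
        areas = cell_areas(b.layer.grid)
        region = RegionPolygons([box(-1, -1, 1, 1)])
        total = float(areas.area_km2.sum())
        ov = mpa_overlap(b, region, areas, total)
        assert ov.outside_km2 == 0.0
        assert ov.inside_km2 == pytest.approx(total)

    def test_rectangle_matches_point_in_polygon_oracle(self):
        b = self.grid_map()
        areas = cell_areas(b.layer.grid)
        rect = box(0.0, 0.05, 0.12, 0.2)
        region = RegionPolygons([rect])
        ov = mpa_overlap(b, region, areas, 100.0)
        grid = b.layer.grid
        inside = np.zeros((4, 4), bool)
        for r in range(4):
            for c in range(4):
                lon, lat = grid.cell_center(r, c)
                inside[r, c] = rect.intersects(
                    __import__("shapely").geometry.Point(lon, lat))
        assert ov.inside_km2 == pytest.approx(float(areas.area_km2[inside].sum()))

    def test_empty_polygon_set_flagged(self):
        b = self.grid_map()
        areas = cell_areas(b.layer.grid)
        with pytest.warns(UserWarning, match="empty"):
            ov = mpa_overlap(b, RegionPolygons([]), areas, 50.0)
        assert ov.inside_km2 == 0.0

    def test_published_current_row_identity(self):
        # inside 76,379 of current 322,114 km² -> 23.7 %
        assert round(100 * 76379 / 322114, 1) == 23.7

    TABLE2 = [
        # total, outside, inside, pct_out, pct_in, change_km2, change_pct
        (319415, 243525, 75903, 75.6, 23.6, -476, -0.6),
        (300242, 230739, 69509, 71.6, 21.6, -6870, -9.0),
        (280954, 220206, 60758, 68.4, 18.9, -15621, -20.5),
        (281461, 221937, 59525, 68.9, 18.5, -16854, -22.1),
        (289283, 225796, 63492, 70.1, 19.7, -12887, -16.9),
        (257018, 207032, 49991, 64.3, 15.5, -26388, -34.5),
        (327945, 247956, 79992, 77.0, 24.8, 3613, 4.7),
        (272900, 215828, 57078, 67.0, 17.7, -19301, -25.3),
        (246481, 212578, 33921, 66.0, 10.5, -42458, -55.6),
        (166682, 152297, 14379, 47.3, 4.5, -62000, -81.2),
        (242219, 215741, 26490, 67.0, 8.2, -49889, -65.3),
        (90178, 82275, 7904, 25.5, 2.5, -68475, -89.7),
    ]

    @pytest.mark.parametrize("row", TABLE2)
    def test_full_overlap_table_percentage_sweep(self, row):
        total, outside, inside, pct_out, pct_in, chg_km2, chg_pct = row
        current_total, current_inside = 322114, 76379
        from nichecast.changes import OverlapSummary
        ov = OverlapSummary(inside, outside, current_total,
                            inside - current_inside,
                            100.0 * (inside - current_inside) / current_inside)
        assert round(ov.pct_inside, 1) == pct_in
        assert round(ov.pct_outside, 1) == pct_out
        assert round(ov.change_inside_km2) == chg_km2
        assert round(ov.change_inside_pct, 1) == chg_pct
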