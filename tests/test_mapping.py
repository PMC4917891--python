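"""Grid geometry, per-branch maps, cohort averaging, Chauvenet exclusion."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hotspotmap import (
    GridMap,
    average_maps,
    chauvenet_exclude,
    grid_geometry,
    nuclei_count_map,
    spot_area_map,
    spot_count_map,
    uptake_maps,
)
from hotspotmap.imaging import PatchImage
from hotspotmap.mapping import ostium_squares, read_grid_csv, write_grid_csv
from hotspotmap.segmentation import Spot

from oracles import normal_two_tail_quadrature


def _spot(row, col, area=100):
    return Spot(spot_id=1, area_px=area, area_um2=float(area), integrated_intensity=1.0,
                centroid_row=row, centroid_col=col)


def _no_ostium(side=100):
    return np.zeros((side, side), dtype=bool)


class TestGridGeometry:
    def test_exact_division_750(self):
        g = grid_geometry(750)
        assert np.array_equal(np.diff(g.row_edges), [75] * 10)

    def test_remainder_goes_to_last_square(self):
        g = grid_geometry(753)
        widths = np.diff(g.row_edges)
        assert list(widths[:-1]) == [75] * 9 and widths[-1] == 78

    @given(st.integers(100, 1000))
    def test_every_pixel_in_exactly_one_square(self, side):
        g = grid_geometry(side)
        rows = np.arange(side)
        i, _ = g.square_of(rows, rows)
        assert i.min() == 0 and i.max() == 9
        counts = np.bincount(i, minlength=10)
        assert counts.sum() == side
        base = side // 10
        assert list(counts[:-1]) == [base] * 9


class TestPointMaps:
    def test_zero_spots_all_zero_valid(self):
        g = grid_geometry(100)
        m = spot_count_map([], g, _no_ostium())
        assert np.nansum(m.values) == 0 and m.valid.all()

    def test_three_spots_in_one_square(self):
        g = grid_geometry(100)
        spots = [_spot(15, 15), _spot(12, 18), _spot(19, 11)]
        m = spot_count_map(spots, g, _no_ostium())
        assert m.values[1, 1] == 3 and np.nansum(m.values) == 3

    def test_counting_oracle_random_instances(self, rng):
        g = grid_geometry(100)
        mask = _no_ostium()
        mask[40:60, 40:60] = True  # central ostium
        invalid = ostium_squares(mask, g)
        for _ in range(10):
            pts = rng.uniform(0, 100, size=(50, 2))
            spots = [_spot(r, c) for r, c in pts]
            m = spot_count_map(spots, g, mask)
            i, j = g.square_of(pts[:, 0], pts[:, 1])
            outside = sum(1 for a, b in zip(i, j) if not invalid[a, b])
            assert np.nansum(m.values) == outside

    def test_nuclei_map_counts_and_total(self, rng):
        g = grid_geometry(100)
        pts = np.repeat([[5.0, 5.0]], 5, axis=0)
        m = nuclei_count_map(pts, g, _no_ostium())
        assert m.values[0, 0] == 5
        pts = rng.uniform(0, 100, (200, 2))
        m = nuclei_count_map(pts, g, _no_ostium())
        assert np.nansum(m.values) == 200

    def test_point_outside_image_rejected(self):
        g = grid_geometry(100)
        with pytest.raises(ValueError, match="inside"):
            nuclei_count_map(np.array([[100.0, 5.0]]), g, _no_ostium())


class TestSpotAreaMap:
    def test_single_spot_defines_only_its_square(self):
        g = grid_geometry(100)
        m = spot_area_map([_spot(5, 5, area=100)], g, _no_ostium())
        assert m.values[0, 0] == 100
        assert m.valid.sum() == 1  # all other squares undefined

    def test_mean_of_two_spots(self):
        g = grid_geometry(100)
        m = spot_area_map([_spot(5, 5, 50), _spot(6, 6, 150)], g, _no_ostium())
        assert m.values[0, 0] == 100.0

    def test_cohort_mean_uses_only_defined_branches(self):
        g = grid_geometry(100)
        with_spot = spot_area_map([_spot(5, 5, 120)], g, _no_ostium())
        without = spot_area_map([], g, _no_ostium())
        cohort = average_maps([with_spot, without, without])
        assert cohort.mean_values[0, 0] == 120.0  # not diluted by empty branches
        assert cohort.n_per_square[0, 0] == 1


class TestUptakeMaps:
    def _image(self, side=100):
        rng = np.random.default_rng(5)
        # ostium aligned to whole grid squares, so no uptake is lost to
        # partially-covered invalid squares
        mask = _no_ostium(side)
        mask[40:60, 40:60] = True
        return PatchImage(rng.random((side, side)) * 100, 1.0, mask)

    def test_uniform_image_no_spots(self):
        img = PatchImage(np.ones((100, 100)), 1.0, _no_ostium())
        s, n, t = uptake_maps(img, np.zeros((100, 100), dtype=int), grid_geometry(100))
        assert np.nansum(s.values) == 0
        assert np.allclose(n.values, 100.0)

    def test_single_spot_in_one_square(self):
        img = PatchImage(np.ones((100, 100)), 1.0, _no_ostium())
        lbl = np.zeros((100, 100), dtype=int)
        lbl[12:18, 12:18] = 1
        s, n, t = uptake_maps(img, lbl, grid_geometry(100))
        assert s.values[1, 1] == 36.0
        assert np.nansum(s.values) == 36.0

    def test_per_square_sums_match_whole_image_compartments(self):
        img = self._image()
        lbl = (img.intensity > 80).astype(int)
        s, n, t = uptake_maps(img, lbl, grid_geometry(100))
        unmasked = ~img.ostium_mask
        assert np.nansum(t.values) == pytest.approx(img.intensity[unmasked].sum(), rel=1e-12)
        assert np.nansum(s.values) == pytest.approx(
            img.intensity[(lbl > 0) & unmasked].sum(), rel=1e-12
        )
        spot_plus_non = np.nan_to_num(s.values) + np.nan_to_num(n.values)
        assert np.allclose(spot_plus_non, np.nan_to_num(t.values), rtol=1e-9)

    def test_shape_mismatch_rejected(self):
        img = self._image()
        with pytest.raises(ValueError, match="shape"):
            uptake_maps(img, np.zeros((10, 10), dtype=int), grid_geometry(100))


class TestAverageMaps:
    def _map(self, value, ostium=None):
        vals = np.full((10, 10), float(value))
        inv = np.zeros((10, 10), dtype=bool) if ostium is None else ostium
        return GridMap(vals, ~inv, "total_uptake", ostium=inv)

    def test_single_branch_identity(self):
        m = self._map(4.2)
        cohort = average_maps([m])
        assert np.allclose(cohort.mean_values, 4.2)
        assert cohort.n_branches == 1

    def test_two_branch_mean(self):
        cohort = average_maps([self._map(2), self._map(4)])
        assert np.allclose(cohort.mean_values[cohort.valid], 3.0)

    def test_union_ostium_masks_square_masked_anywhere(self):
        inv = np.zeros((10, 10), dtype=bool)
        inv[4, 4] = True
        cohort = average_maps([self._map(1), self._map(3, ostium=inv)])
        assert cohort.union_ostium[4, 4]
        assert np.isnan(cohort.mean_values[4, 4])
        assert cohort.n_per_square[4, 4] == 0

    def test_permutation_invariance(self, rng):
        maps = [self._map(v) for v in rng.random(6)]
        a = average_maps(maps)
        b = average_maps(maps[::-1])
        assert np.allclose(a.mean_values, b.mean_values, rtol=1e-12, equal_nan=True)

    def test_mixed_metric_rejected(self):
        bad = GridMap(np.ones((10, 10)), np.ones((10, 10), dtype=bool), "spot_count")
        with pytest.raises(ValueError, match="metric"):
            average_maps([self._map(1), bad])


class TestChauvenet:
    def test_degenerate_all_equal_excludes_nothing(self):
        kept, excl = chauvenet_exclude([7, 7, 7, 7])
        assert list(kept) == [0, 1, 2, 3] and len(excl) == 0

    def test_worked_example_excludes_the_outlier(self):
        values = [10, 9, 11, 10, 50]
        kept, excl = chauvenet_exclude(values)
        assert list(excl) == [4]
        # independent check by quadrature of the normal density
        x = np.asarray(values, float)
        z = abs(50 - x.mean()) / x.std(ddof=1)
        n_p = len(values) * normal_two_tail_quadrature(z)
        assert n_p == pytest.approx(0.37, abs=0.02)
        assert n_p < 0.5

    def test_no_exclusion_when_all_tail_products_exceed_half(self):
        values = [10, 9, 11, 10, 12]
        kept, excl = chauvenet_exclude(values)
        assert len(excl) == 0
        x = np.asarray(values, float)
        z = np.abs(x - x.mean()) / x.std(ddof=1)
        assert all(len(values) * normal_two_tail_quadrature(zi) > 0.5 for zi in z)

    def test_symmetric_three_values_with_small_z_kept(self):
        kept, excl = chauvenet_exclude([1.0, 2.0, 3.0])
        assert len(excl) == 0

    def test_needs_three_values(self):
        with pytest.raises(ValueError):
            chauvenet_exclude([1.0, 2.0])


class TestGridIO:
    def test_round_trip_with_sidecar(self, tmp_path):
        inv = np.zeros((10, 10), dtype=bool)
        inv[5, 5] = True
        gm = GridMap(np.arange(100, dtype=float).reshape(10, 10), ~inv, "spot_count",
                     units="spots/square", ostium=inv)
        write_grid_csv(gm, tmp_path / "m.csv")
        back = read_grid_csv(tmp_path / "m.csv")
        assert back.metric == "spot_count"
        assert np.array_equal(back.values, gm.values, equal_nan=True)
        assert np.array_equal(back.ostium, inv)

    def test_reads_plain_lesion_csv_without_sidecar(self, tmp_path):
        vals = np.random.default_rng(0).random((10, 10))
        np.savetxt(tmp_path / "lesion.csv", vals, delimiter=",")
        gm = read_grid_csv(tmp_path / "lesion.csv")
        assert gm.metric == "lesion_prevalence"
        assert gm.valid.all()
        assert np.allclose(gm.values, vals)
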