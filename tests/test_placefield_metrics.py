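"""Field detection, Skaggs information, specificity and inclusion rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placecell import (classify_place_cell, detect_fields,
                       field_size_normalized, spatial_information,
                       specificity_ratio)
from placecell.placefield_metrics import CellSessionMetrics, PlaceField

from conftest import square_occupancy, square_ratemap


def _metrics(n_fields):
    return CellSessionMetrics(n_fields=n_fields, field_areas_bins=(),
                              field_areas_cm2=(), active_bins_normalized=0,
                              spatial_info=0.0, specificity_ratio=np.nan,
                              mean_rate=1.0, max_rate=1.0)


def skaggs_oracle(rates, occ):
    """Independent term-by-term summation of the information integral."""
    total = occ.sum()
    lam_bar = sum(o / total * r for o, r in zip(occ.ravel(), rates.ravel()))
    info = 0.0
    for o, r in zip(occ.ravel(), rates.ravel()):
        if r > 0:
            info += (o / total) * (r / lam_bar) * np.log2(r / lam_bar)
    return info


class TestDetectFields:
    def test_uniform_map_single_field_of_all_bins(self):
        rm = square_ratemap(np.full((20, 20), 3.0))
        fields = detect_fields(rm)
        assert len(fields) == 1
        assert fields[0].area_bins == 400

    @pytest.mark.parametrize("n_bins,expected", [(10, 0), (11, 1)])
    def test_ten_adjacent_bins_rejected_eleven_accepted(self, n_bins,
                                                        expected):
        grid = np.zeros((20, 20))
        grid[5, 3:3 + n_bins] = 10.0
        fields = detect_fields(square_ratemap(grid))
        assert len(fields) == expected
        if expected:
            assert fields[0].area_bins == n_bins

    def test_gaussian_bump_area_matches_contour_count(self):
        yy, xx = np.mgrid[0:30, 0:30]
        grid = 10.0 * np.exp(-((xx - 15) ** 2 + (yy - 15) ** 2) / (2 * 3.0 ** 2))
        rm = square_ratemap(grid)
        fields = detect_fields(rm)
        brute = int(np.sum(grid > 0.3 * grid.max()))
        assert len(fields) == 1
        assert fields[0].area_bins == brute

    def test_silent_map_no_fields(self):
        assert detect_fields(square_ratemap(np.zeros((10, 10)))) == []

    def test_fields_disjoint_and_subset_of_suprathreshold(self):
        rng = np.random.default_rng(8)
        grid = rng.uniform(0, 1, (30, 30)) ** 4 * 10
        rm = square_ratemap(grid)
        fields = detect_fields(rm)
        supra = {(r, c) for r, c in zip(*np.nonzero(grid > 0.3 * grid.max()))}
        seen = set()
        for f in fields:
            assert not (f.member_bins & seen)
            seen |= f.member_bins
            assert f.member_bins <= supra

    def test_sorted_by_peak_descending(self):
        grid = np.zeros((30, 30))
        grid[2:6, 2:6] = 5.0
        grid[20:24, 20:24] = 10.0
        fields = detect_fields(square_ratemap(grid))
        peaks = [f.peak_rate for f in fields]
        assert peaks == sorted(peaks, reverse=True)

    def test_diagonal_not_adjacent_under_4_connectivity(self):
        grid = np.zeros((20, 20))
        grid[4, 4:10] = 10.0   # 6 bins
        grid[5, 10:16] = 10.0  # 6 bins, touching only diagonally
        assert detect_fields(square_ratemap(grid), adjacency=4) == []
        eight = detect_fields(square_ratemap(grid), adjacency=8)
        assert len(eight) == 1 and eight[0].area_bins == 12


class TestSpatialInformation:
    def test_uniform_rate_zero_information(self):
        rm = square_ratemap(np.full((8, 8), 2.5), smoothed=False)
        occ = square_occupancy(np.ones((8, 8)))
        assert spatial_information(rm, occ) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 8])
    def test_single_active_bin_gives_log2_n(self, n):
        grid = np.zeros((n, n))
        grid[0, 0] = 7.0
        rm = square_ratemap(grid, smoothed=False)
        occ = square_occupancy(np.ones((n, n)))
        assert spatial_information(rm, occ) == pytest.approx(
            np.log2(n * n), abs=1e-12)

    def test_matches_termwise_oracle_on_random_maps(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = rng.integers(4, 9)
            rates = rng.uniform(0, 10, (n, n))
            rates[rng.uniform(size=(n, n)) < 0.3] = 0.0
            occ_t = rng.uniform(0.2, 5.0, (n, n))
            rm = square_ratemap(rates, smoothed=False)
            occ = square_occupancy(occ_t)
            assert spatial_information(rm, occ) == pytest.approx(
                skaggs_oracle(rates, occ_t), abs=1e-12)

    def test_silent_cell_undefined(self):
        rm = square_ratemap(np.zeros((6, 6)), smoothed=False)
        occ = square_occupancy(np.ones((6, 6)))
        assert np.isnan(spatial_information(rm, occ))

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_invariant_to_rate_scaling_and_nonnegative(self, scale):
        rng = np.random.default_rng(23)
        rates = rng.uniform(0, 5, (6, 6))
        occ = square_occupancy(rng.uniform(0.2, 3, (6, 6)))
        base = spatial_information(square_ratemap(rates, smoothed=False), occ)
        scaled = spatial_information(
            square_ratemap(scale * rates, smoothed=False), occ)
        assert base >= -1e-12
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)


def _field_from_mask(mask, rates):
    rows, cols = np.nonzero(mask)
    k = np.argmax(rates[rows, cols])
    return PlaceField(member_bins=frozenset(zip(rows.tolist(), cols.tolist())),
                      area_bins=len(rows), area_cm2=4.0 * len(rows),
                      peak_rate=float(rates[rows, cols][k]),
                      peak_bin=(int(rows[k]), int(cols[k])),
                      centroid=(0.0, 0.0))


class TestSpecificityRatio:
    def test_in_4_out_1_uniform_occupancy_gives_4(self):
        grid = np.ones((10, 10))
        mask = np.zeros((10, 10), bool)
        mask[3:6, 3:7] = True
        grid[mask] = 4.0
        rm = square_ratemap(grid)
        occ = square_occupancy(np.ones((10, 10)))
        f = _field_from_mask(mask, grid)
        assert specificity_ratio(rm, [f], occ) == pytest.approx(4.0)

    def test_identical_rates_ratio_one(self):
        grid = np.full((10, 10), 2.0)
        mask = np.zeros((10, 10), bool)
        mask[0:3, 0:5] = True
        rm = square_ratemap(grid)
        occ = square_occupancy(np.ones((10, 10)))
        assert specificity_ratio(rm, [_field_from_mask(mask, grid)],
                                 occ) == pytest.approx(1.0)

    def test_no_fields_missing(self):
        rm = square_ratemap(np.ones((5, 5)))
        occ = square_occupancy(np.ones((5, 5)))
        assert np.isnan(specificity_ratio(rm, [], occ))

    def test_occupancy_weighting_matters(self):
        # out-field: 1 Hz in a heavily occupied bin, 3 Hz in a light one
        grid = np.ones((4, 4))
        grid[0, 0] = 10.0
        grid[3, 3] = 3.0
        occ_t = np.ones((4, 4))
        occ_t[3, 3] = 0.25
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        rm = square_ratemap(grid)
        occ = square_occupancy(occ_t)
        out_bins = ~mask
        expected_out = (np.sum(occ_t[out_bins] * grid[out_bins])
                        / np.sum(occ_t[out_bins]))
        got = specificity_ratio(rm, [_field_from_mask(mask, grid)], occ)
        assert got == pytest.approx(10.0 / expected_out)


class TestFieldSizeNormalized:
    def test_all_zero_map(self):
        assert field_size_normalized(
            square_ratemap(np.zeros((8, 8)), smoothed=False)) == 0

    def test_uniform_map_counts_all_valid(self):
        valid = np.ones((8, 8), bool)
        valid[0, :] = False
        rm = square_ratemap(np.ones((8, 8)), valid=valid, smoothed=False)
        assert field_size_normalized(rm) == int(valid.sum())

    def test_gaussian_bump_equals_brute_force(self):
        yy, xx = np.mgrid[0:20, 0:20]
        grid = 8.0 * np.exp(-((xx - 9) ** 2 + (yy - 11) ** 2) / (2 * 2.5 ** 2))
        rm = square_ratemap(grid, smoothed=False)
        assert field_size_normalized(rm) == int(np.sum(grid > 0.3 * grid.max()))


class TestClassifyPlaceCell:
    def test_fields_in_any_session_included(self):
        assert classify_place_cell([_metrics(0), _metrics(2), _metrics(0)])

    def test_no_fields_excluded(self):
        assert not classify_place_cell([_metrics(0), _metrics(0)])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify_place_cell([])
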