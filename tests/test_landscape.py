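"""Patch, edge, adjacency, and edge-effect statistics.

Edge detection is validated against a brute-force oracle that measures the
centre-to-centre distance from every patch cell to every cell of a
different class (treating off-raster space as nodata).
"""

import numpy as np
import pytest

from ugci.landscape import (
    ADJACENCY_GREEN,
    ADJACENCY_IMPERVIOUS,
    ADJACENCY_MIXED,
    classify_adjacency,
    compare_edge_interior,
    detect_edges,
    label_patches,
    patch_size_correlation,
    zonal_stats,
)

from conftest import make_categorical, make_continuous


def brute_force_edges(landcover, distance_m):
    """All-pairs centre-distance edge oracle (off-raster = nodata)."""
    values = landcover.values
    valid = landcover.mask
    rows, cols = values.shape
    pad = int(np.floor(distance_m / landcover.cell_size)) + 1
    edge = np.zeros_like(valid)
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c]:
                continue
            found = False
            for rr in range(r - pad, r + pad + 1):
                for cc in range(c - pad, c + pad + 1):
                    inside = 0 <= rr < rows and 0 <= cc < cols
                    foreign = (not inside or not valid[rr, cc]
                               or values[rr, cc] != values[r, c])
                    if foreign:
                        d = np.hypot(rr - r, cc - c) * landcover.cell_size
                        if d <= distance_m:
                            found = True
                            break
                if found:
                    break
            edge[r, c] = found
    return edge


class TestLabelPatches:
    def test_diagonal_cells_depend_on_connectivity(self):
        lc = make_categorical([[1, 0], [0, 1]], nodata=0)
        assert label_patches(lc, connectivity=8).n_patches == 1
        assert label_patches(lc, connectivity=4).n_patches == 2

    def test_uniform_block_is_one_patch(self):
        lc = make_categorical(np.ones((5, 5), dtype=int))
        patches = label_patches(lc)
        assert patches.n_patches == 1
        areas = patches.patch_areas()
        assert areas.loc[0, "cells"] == 25
        assert areas.loc[0, "area_m2"] == 25 * 900.0

    def test_checkerboard_connectivity4_isolates_cells(self):
        lc = make_categorical(np.indices((4, 4)).sum(axis=0) % 2 + 1)
        assert label_patches(lc, connectivity=4).n_patches == 16

    def test_continuous_raster_rejected(self):
        with pytest.raises(ValueError, match="categorical"):
            label_patches(make_continuous(np.ones((3, 3))))

    def test_patch_areas_sum_to_class_cells(self, small_landcover):
        lc, spec = small_landcover
        patches = label_patches(lc)
        areas = patches.patch_areas()
        for code in np.unique(lc.values):
            class_cells = int((lc.values == code).sum())
            assert areas.loc[areas.landcover_code == code, "cells"].sum() == class_cells


class TestDetectEdges:
    def test_5x5_single_patch_ring(self):
        lc = make_categorical(np.ones((5, 5), dtype=int))
        patches = detect_edges(label_patches(lc), distance_m=30.0)
        assert patches.edge.sum() == 16
        assert patches.interior().sum() == 9

    def test_two_cell_strip_all_edge(self):
        lc = make_categorical(np.ones((2, 7), dtype=int))
        patches = detect_edges(label_patches(lc))
        assert patches.edge.all()
        assert patches.interior().sum() == 0

    def test_single_cell_patch_is_edge(self):
        values = np.full((5, 5), 2, dtype=int)
        values[2, 2] = 1
        patches = detect_edges(label_patches(make_categorical(values)))
        assert patches.edge[2, 2]

    def test_matches_brute_force_on_random_rasters(self, rng):
        for _ in range(50):
            shape = tuple(rng.integers(4, 21, size=2))
            values = rng.integers(0, 4, size=shape)
            lc = make_categorical(values, nodata=0)
            patches = detect_edges(label_patches(lc), distance_m=30.0)
            oracle = brute_force_edges(lc, 30.0)
            np.testing.assert_array_equal(patches.edge, oracle & (patches.labels > 0))

    def test_larger_distance_two_rings(self):
        lc = make_categorical(np.ones((7, 7), dtype=int))
        patches = detect_edges(label_patches(lc), distance_m=60.0)
        oracle = brute_force_edges(lc, 60.0)
        np.testing.assert_array_equal(patches.edge, oracle)
        assert patches.interior().sum() == 9  # central 3x3 survives

    def test_subcell_distance_warns(self):
        lc = make_categorical(np.ones((4, 4), dtype=int))
        with pytest.warns(UserWarning, match="below the cell size"):
            detect_edges(label_patches(lc), distance_m=10.0)

    def test_edge_interior_partition(self, small_landcover):
        lc, _ = small_landcover
        patches = detect_edges(label_patches(lc))
        in_patch = patches.labels > 0
        assert not (patches.edge & patches.interior()).any()
        np.testing.assert_array_equal(patches.edge | patches.interior(), in_patch)


class TestAdjacency:
    def _patchmap(self, values, nodata=None):
        lc = make_categorical(values, nodata=nodata)
        return detect_edges(label_patches(lc))

    def test_impervious_only_neighbours(self):
        patches = self._patchmap([[6, 6, 6], [6, 1, 6], [6, 6, 6]])
        classify_adjacency(patches, impervious_classes={6}, green_classes={1, 2})
        assert patches.adjacency[1, 1] == ADJACENCY_IMPERVIOUS

    def test_green_only_neighbours(self):
        patches = self._patchmap([[2, 2, 2], [2, 1, 2], [2, 2, 2]])
        classify_adjacency(patches, impervious_classes={6}, green_classes={1, 2})
        assert patches.adjacency[1, 1] == ADJACENCY_GREEN

    def test_both_kinds_is_mixed(self):
        patches = self._patchmap([[2, 2, 2], [6, 1, 2], [6, 6, 2]])
        classify_adjacency(patches, impervious_classes={6}, green_classes={1, 2})
        assert patches.adjacency[1, 1] == ADJACENCY_MIXED

    def test_empty_impervious_set_rejected(self):
        patches = self._patchmap(np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError, match="impervious"):
            classify_adjacency(patches, impervious_classes=set(), green_classes={1})

    def test_only_flags_edge_cells(self):
        patches = self._patchmap(np.pad(np.ones((3, 3), dtype=int), 2,
                                        constant_values=6))
        classify_adjacency(patches, impervious_classes={6}, green_classes={1})
        assert (patches.adjacency[patches.interior()] == 0).all()


class TestZonalStats:
    def test_basic_stats(self):
        values = make_continuous([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        zones = make_categorical([[1, 1, 1], [2, 2, 2]])
        out = zonal_stats(values, zones).set_index("zone")
        assert out.loc[1, "mean"] == 2.0
        assert out.loc[1, "sd"] == pytest.approx(1.0)
        assert out.loc[1, "n"] == 3

    def test_nodata_zone_omitted(self):
        values = make_continuous([[1.0, -9.0]], nodata=-9.0)
        zones = make_categorical([[1, 2]])
        out = zonal_stats(values, zones)
        assert set(out["zone"]) == {1}

    def test_single_cell_zone_sd_flagged(self):
        values = make_continuous([[4.0, 1.0]])
        zones = make_categorical([[1, 2]])
        out = zonal_stats(values, zones).set_index("zone")
        assert out.loc[1, "sd"] == 0.0
        assert not out.loc[1, "sd_defined"]

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            zonal_stats(make_continuous(np.ones((2, 2))),
                        make_categorical(np.ones((3, 3), dtype=int)))


class TestCompareEdgeInterior:
    def _constructed(self, interior_value, edge_value):
        values = np.full((7, 7), 1, dtype=int)
        lc = make_categorical(np.pad(values, 1, constant_values=6))
        patches = detect_edges(label_patches(lc))
        surface = np.full(lc.shape, np.nan)
        surface[patches.interior() & (lc.values == 1)] = interior_value
        surface[patches.edge & (lc.values == 1)] = edge_value
        return surface, patches

    def test_percent_difference_arithmetic(self):
        surface, patches = self._constructed(0.50, 0.35)
        out = compare_edge_interior(surface, patches, by_class=[1])
        assert out.loc[0, "pct_lower"] == pytest.approx(30.0)

    def test_null_case(self, rng):
        lc = make_categorical(np.pad(np.ones((10, 10), dtype=int), 1,
                                     constant_values=6))
        patches = detect_edges(label_patches(lc))
        surface = rng.normal(0.5, 0.05, size=lc.shape)
        out = compare_edge_interior(surface, patches, by_class=[1])
        assert abs(out.loc[0, "pct_lower"]) < 10
        assert out.loc[0, "p"] > 0.001

    def test_insufficient_cells_skipped_with_notice(self):
        lc = make_categorical([[1, 6], [6, 6]])
        patches = detect_edges(label_patches(lc))
        with pytest.warns(UserWarning, match="skipped"):
            out = compare_edge_interior(np.ones(lc.shape), patches, by_class=[1])
        assert out.loc[0, "skipped"]

    def test_recovers_injected_deficit(self, deficit_landscape):
        from ugci.index import compute_ugci, entropy_weights, normalize_minmax

        lc, stack, spec = deficit_landscape
        norm = normalize_minmax(stack)
        scores = compute_ugci(norm, entropy_weights(norm))
        surface = np.full(stack.shape, np.nan)
        surface[stack.mask] = scores
        patches = detect_edges(label_patches(lc))
        out = compare_edge_interior(surface, patches, by_class=[1])
        assert out.loc[0, "pct_lower"] == pytest.approx(30.0, abs=5.0)
        assert out.loc[0, "p"] < 0.001


class TestPatchSizeCorrelation:
    def _patchy_landscape(self, rng, n_patches=8):
        """Disjoint square patches of class 1 with growing sizes."""
        lc = np.full((60, 40), 6, dtype=int)
        sizes = np.arange(1, n_patches + 1)
        r = 1
        for k, s in enumerate(sizes):
            lc[r:r + s, 1:1 + s] = 1
            r += s + 2
        return make_categorical(lc)

    def test_perfect_log_linear_correlation(self, rng):
        lc = self._patchy_landscape(rng, n_patches=6)
        patches = detect_edges(label_patches(lc, connectivity=4))
        areas = patches.patch_areas()
        surface = np.zeros(lc.shape)
        for pid, area in zip(areas["patch"], areas["area_ha"]):
            if patches.patch_class[pid] == 1:
                surface[patches.labels == pid] = np.log(area)
        r, p = patch_size_correlation(surface, patches, landcover_code=1)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_shuffled_values_near_zero(self, rng):
        lc = self._patchy_landscape(rng, n_patches=8)
        patches = detect_edges(label_patches(lc, connectivity=4))
        ids = [pid for pid, code in patches.patch_class.items() if code == 1]
        means = rng.permutation(len(ids)).astype(float)
        surface = np.zeros(lc.shape)
        for pid, m in zip(ids, means):
            surface[patches.labels == pid] = m
        r, p = patch_size_correlation(surface, patches, landcover_code=1)
        assert abs(r) < 0.8  # decorrelated by construction

    def test_constant_means_undefined(self):
        lc = self._patchy_landscape(np.random.default_rng(0), n_patches=5)
        patches = label_patches(lc, connectivity=4)
        r, p = patch_size_correlation(np.ones(lc.shape), patches, landcover_code=1)
        assert np.isnan(r)

    def test_too_few_patches_rejected(self):
        lc = make_categorical(np.ones((4, 4), dtype=int))
        patches = label_patches(lc)
        with pytest.raises(ValueError, match=">= 3"):
            patch_size_correlation(np.ones(lc.shape), patches, landcover_code=1)
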