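"""Natural-breaks classification (against a brute-force partition oracle),
binarization, richness stacking, hotspot coding, windowed density, and
group-uniqueness labelling."""

import itertools

import numpy as np
import pytest

from flywaysdm.raster import Grid, RasterLayer
from flywaysdm.stacking import (
    binarize_species,
    classify_hotspots,
    jenks_breaks,
    jenks_classify,
    neighborhood_density,
    stack_richness,
    unique_group_cells,
)


def brute_force_jenks_cost(values, k):
    """Minimum within-class SSD over all ordered partitions (tiny n only)."""
    v = np.sort(np.asarray(values, float))
    n = len(v)

    def ssd(seg):
        return ((seg - seg.mean()) ** 2).sum()

    best = np.inf
    best_breaks = None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        cost = sum(ssd(v[bounds[i]:bounds[i + 1]]) for i in range(k))
        if cost < best - 1e-12:
            best = cost
            best_breaks = [v[c - 1] for c in cuts]
    return best, best_breaks


def partition_cost(values, breaks, k):
    v = np.asarray(values, float)
    cls = jenks_classify(v, np.asarray(breaks))
    return sum(
        ((v[cls == c] - v[cls == c].mean()) ** 2).sum() for c in range(k) if (cls == c).any()
    )


class TestJenksBreaks:
    def test_single_class_has_no_breaks(self):
        assert jenks_breaks([1, 2, 3], 1).size == 0

    def test_two_cluster_example(self):
        breaks = jenks_breaks([1, 2, 10, 11], 2)
        assert breaks.tolist() == [2]

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_exhaustive_partition_oracle(self, k):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(k, 13)
            values = np.round(rng.uniform(0, 100, n), 3)
            if np.unique(values).size < k:
                continue
            breaks = jenks_breaks(values, k)
            oracle_cost, _ = brute_force_jenks_cost(values, k)
            assert partition_cost(values, breaks, k) == pytest.approx(oracle_cost, abs=1e-8)

    def test_weighted_equals_unweighted_on_duplicates(self):
        values = [1, 1, 1, 2, 8, 8, 9, 9, 9, 9]
        b1 = jenks_breaks(values, 2)
        oracle_cost, _ = brute_force_jenks_cost(values, 2)
        assert partition_cost(values, b1, 2) == pytest.approx(oracle_cost, abs=1e-10)

    def test_too_few_distinct_values_errors(self):
        with pytest.raises(ValueError):
            jenks_breaks([1.0, 1.0, 1.0], 2)
        with pytest.raises(ValueError):
            jenks_breaks([1.0, 2.0], 0)


class TestBinarize:
    def _layer(self, vals):
        vals = np.asarray(vals, float)
        return RasterLayer(Grid(*vals.shape, 1.0), "m", vals)

    def test_fixed_threshold_is_ge_rule(self):
        out = binarize_species(self._layer([[0.2, 0.7], [0.5, 0.49]]),
                               "fixed_threshold", threshold=0.5)
        np.testing.assert_array_equal(out.values, [[0, 1], [1, 0]])

    def test_trimodal_map_marks_top_cluster_only(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([
            rng.normal(0.1, 0.01, 40), rng.normal(0.5, 0.01, 40), rng.normal(0.9, 0.01, 20)
        ])
        rng.shuffle(vals)
        layer = self._layer(vals.reshape(10, 10))
        out = binarize_species(layer, "jenks3_top")
        np.testing.assert_array_equal(out.values == 1, layer.values > 0.7)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            binarize_species(self._layer(np.full((4, 4), 0.3)), "jenks3_top")

    def test_nodata_stays_nodata(self):
        vals = np.array([[0.2, np.nan], [0.8, 0.9]])
        out = binarize_species(self._layer(vals), "fixed_threshold", threshold=0.5)
        assert np.isnan(out.values[0, 1])


class TestRichnessAndHotspots:
    def test_stack_sum_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        grid = Grid(12, 12, 1.0)
        maps = [RasterLayer(grid, f"m{i}", rng.integers(0, 2, grid.shape).astype(float))
                for i in range(5)]
        out = stack_richness(maps)
        expected = np.zeros(grid.shape)
        for m in maps:
            for r in range(12):
                for c in range(12):
                    expected[r, c] += m.values[r, c]
        np.testing.assert_array_equal(out.values, expected)

    def test_single_map_is_identity_and_grid_mismatch_errors(self):
        grid = Grid(4, 4, 1.0)
        m = RasterLayer(grid, "m", np.eye(4))
        np.testing.assert_array_equal(stack_richness([m]).values, np.eye(4))
        other = RasterLayer(Grid(4, 4, 2.0), "o", np.eye(4))
        with pytest.raises(ValueError, match="grid"):
            stack_richness([m, other])

    def test_hotspot_classes_follow_jenks_oracle(self):
        vals = np.array([0, 0, 0, 0, 0, 0, 1, 1, 5, 6, 0, 0], float).reshape(3, 4)
        layer = RasterLayer(Grid(3, 4, 1.0), "r", vals)
        out = classify_hotspots(layer)
        np.testing.assert_array_equal(out.values == 2, vals >= 5)
        np.testing.assert_array_equal(out.values == 1, vals == 1)

    def test_constant_richness_warns_all_nonsuitable(self):
        layer = RasterLayer(Grid(3, 3, 1.0), "r", np.zeros((3, 3)))
        with pytest.warns(UserWarning, match="constant"):
            out = classify_hotspots(layer)
        assert np.all(out.values == 0)

    def test_invariant_to_monotone_scaling(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 8, (10, 10)).astype(float)
        layer = RasterLayer(Grid(10, 10, 1.0), "r", vals)
        doubled = RasterLayer(Grid(10, 10, 1.0), "r2", 2 * vals)
        np.testing.assert_array_equal(
            classify_hotspots(layer).values, classify_hotspots(doubled).values
        )

    def test_class_counts_account_for_every_finite_cell(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(0, 6, (9, 9)).astype(float)
        vals[0, 0] = np.nan
        out = classify_hotspots(RasterLayer(Grid(9, 9, 1.0), "r", vals))
        finite = np.isfinite(vals)
        counts = [np.sum(out.values[finite] == c) for c in (0, 1, 2)]
        assert sum(counts) == finite.sum()


class TestNeighborhoodDensity:
    def test_all_ones_everywhere_one(self):
        grid = Grid(6, 6, 300.0)
        out = neighborhood_density(RasterLayer(grid, "b", np.ones(grid.shape)), 900.0)
        np.testing.assert_allclose(out.values, 1.0)

    def test_single_one_in_3x3_window(self):
        grid = Grid(5, 5, 300.0)
        vals = np.zeros(grid.shape)
        vals[2, 2] = 1.0
        out = neighborhood_density(RasterLayer(grid, "b", vals), 900.0)
        assert out.values[2, 2] == pytest.approx(1 / 9)

    def test_matches_double_loop_oracle_with_shrinking_edges(self):
        rng = np.random.default_rng(5)
        grid = Grid(9, 11, 300.0)
        vals = rng.integers(0, 2, grid.shape).astype(float)
        out = neighborhood_density(RasterLayer(grid, "b", vals), 900.0)
        for r in range(9):
            for c in range(11):
                window = vals[max(0, r - 1):r + 2, max(0, c - 1):c + 2]
                assert out.values[r, c] == pytest.approx(window.mean())


class TestUniqueGroupCells:
    def _mask(self, grid, ones):
        vals = np.zeros(grid.shape)
        for r, c in ones:
            vals[r, c] = 1.0
        return RasterLayer(grid, "m", vals, "categorical")

    def test_disjoint_masks_label_their_union(self):
        grid = Grid(4, 4, 1.0)
        out, codes = unique_group_cells(
            {"a": self._mask(grid, [(0, 0)]), "b": self._mask(grid, [(1, 1)])}
        )
        assert out.values[0, 0] == 1 and out.values[1, 1] == 2
        assert codes == {1: "a", 2: "b"}

    def test_shared_cells_are_zero(self):
        grid = Grid(4, 4, 1.0)
        out, _ = unique_group_cells(
            {"a": self._mask(grid, [(2, 2)]), "b": self._mask(grid, [(2, 2)])}
        )
        assert out.values[2, 2] == 0

    def test_matches_per_cell_count_oracle(self):
        rng = np.random.default_rng(6)
        grid = Grid(8, 8, 1.0)
        masks = {
            g: RasterLayer(grid, g, rng.integers(0, 2, grid.shape).astype(float), "categorical")
            for g in ("a", "b", "c")
        }
        out, codes = unique_group_cells(masks)
        for r in range(8):
            for c in range(8):
                on = [g for g in masks if masks[g].values[r, c] > 0]
                if len(on) == 1:
                    assert codes[int(out.values[r, c])] == on[0]
                else:
                    assert out.values[r, c] == 0
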