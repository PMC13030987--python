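import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubicell import (
    CubeGrid,
    cluster_regions,
    density_clusters,
    holm_bonferroni,
    morans_i,
    neighbor_graph,
    permutation_test,
    presence_glm,
    quartile_neighborhoods,
)
from cubicell.spatial_stats import ClusterRegion, DensityClustering

from _oracles import mark_and_flood_fill, moran_brute_force


def line_counts(n, hot, value=10):
    counts = np.zeros((n, 1, 1), dtype=int)
    counts[list(hot)] = value
    return counts


class TestMoransI:
    def test_two_cube_contrast_gives_minus_one(self, grid_and_graph):
        grid, graph = grid_and_graph(line_counts(2, [1], value=2))
        assert morans_i(grid, graph, "cells").I == pytest.approx(-1.0)

    def test_half_and_half_line_gives_one_third(self, grid_and_graph):
        counts = np.array([5, 5, 0, 0]).reshape(4, 1, 1)
        grid, graph = grid_and_graph(counts)
        result = morans_i(grid, graph, "cells")
        assert result.I == pytest.approx(1 / 3)
        assert result.n == 4 and result.sum_weights == 6

    def test_constant_counts_raise_zero_variance_error(self, grid_and_graph):
        grid, graph = grid_and_graph(np.full((3, 3, 1), 7))
        with pytest.raises(ValueError, match="zero variance"):
            morans_i(grid, graph, "cells")

    def test_disconnected_graph_raises(self, grid_and_graph):
        mask = np.array([True, False, True]).reshape(3, 1, 1)
        grid, graph = grid_and_graph(line_counts(3, [0]), mask=mask)
        with pytest.raises(ValueError, match="no edges"):
            morans_i(grid, graph, "cells")

    def test_matches_double_loop_oracle_on_random_grids(self, grid_and_graph):
        rng = np.random.default_rng(42)
        for _ in range(20):
            counts = rng.poisson(3.0, size=(4, 4, 4))
            if counts.std() == 0:
                continue
            mask = rng.random((4, 4, 4)) > 0.2
            mask[counts.argmax() // 16 % 4, 0, 0] = True  # keep some nodes
            grid, graph = grid_and_graph(counts, mask=mask)
            if graph.sum_weights == 0 or grid.counts_in_mask("cells").std() == 0:
                continue
            expected = moran_brute_force(counts, mask=mask, cube_size=grid.spec.cube_size)
            got = morans_i(grid, graph, "cells").I
            assert got == pytest.approx(expected, rel=1e-12)

    def test_permutation_null_mean_is_minus_one_over_n_minus_one(self, grid_and_graph):
        rng = np.random.default_rng(0)
        base = rng.poisson(4.0, size=(4, 4, 4))
        grid, graph = grid_and_graph(base)
        n = base.size
        draws = []
        for _ in range(400):
            perm = rng.permutation(base.ravel()).reshape(base.shape)
            g, _ = CubeGrid.from_counts(perm, cube_size=45.0), None
            draws.append(morans_i(g, graph, "cells").I)
        draws = np.array(draws)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - (-1 / (n - 1))) < 3 * se


class TestDensityClusters:
    def test_all_zero_counts_give_no_clusters(self, grid_and_graph):
        grid, graph = grid_and_graph(np.zeros((4, 4, 4), dtype=int))
        clustering = density_clusters(grid, graph, "cells")
        assert clustering.n_clusters == 0
        assert not clustering.high_density.any()

    def test_line_with_hot_ends_marks_two_step_halos_as_two_clusters(self, grid_and_graph):
        # 17 cubes, counts 10 at 1-based positions 1,2,16,17: 76% zeros, so the
        # third quartile is 0 and each hot pair plus its two-step halo is marked.
        grid, graph = grid_and_graph(line_counts(17, [0, 1, 15, 16]))
        clustering = density_clusters(grid, graph, "cells")
        assert clustering.q3_threshold == 0.0
        assert clustering.n_clusters == 2
        marked = np.flatnonzero(clustering.high_density.ravel())
        assert marked.tolist() == [0, 1, 2, 3, 13, 14, 15, 16]

    def test_quartile_includes_zero_cubes_and_can_silence_a_sparse_line(self, grid_and_graph):
        # With only 69% zeros the 0.75 quantile falls among the hot values
        # (type-7 gives 10), so no neighborhood mean exceeds it: no clusters.
        grid, graph = grid_and_graph(line_counts(13, [0, 1, 11, 12]))
        clustering = density_clusters(grid, graph, "cells")
        assert clustering.q3_threshold == pytest.approx(10.0)
        assert clustering.n_clusters == 0

    def test_block_cluster_includes_two_step_halo(self, grid_and_graph):
        counts = np.zeros((5, 5, 1), dtype=int)
        counts[1:3, 1:3, 0] = 10
        grid, graph = grid_and_graph(counts)
        clustering = density_clusters(grid, graph, "cells")
        assert clustering.q3_threshold == 0.0
        assert clustering.n_clusters == 1
        # marked set = cubes within two face-steps of the block
        from collections import deque

        dist = np.full((5, 5), -1)
        queue = deque([(i, j) for i in (1, 2) for j in (1, 2)])
        for i, j in queue:
            dist[i, j] = 0
        while queue:
            i, j = queue.popleft()
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                a, b = i + di, j + dj
                if 0 <= a < 5 and 0 <= b < 5 and dist[a, b] < 0:
                    dist[a, b] = dist[i, j] + 1
                    queue.append((a, b))
        np.testing.assert_array_equal(
            clustering.high_density[:, :, 0], (dist >= 0) & (dist <= 2)
        )

    def test_labels_sorted_by_descending_cell_content(self, grid_and_graph):
        grid, graph = grid_and_graph(line_counts(17, [0, 1, 15, 16]) + line_counts(17, [16], 5))
        clustering = density_clusters(grid, graph, "cells")
        totals = clustering.cluster_cell_counts(grid)
        assert list(totals) == sorted(totals, reverse=True)
        assert clustering.cluster_label[16, 0, 0] == 1  # the heavier end is cluster 1

    def test_matches_mark_then_flood_fill_oracle_on_fuzzed_grids(self, grid_and_graph):
        rng = np.random.default_rng(123)
        for trial in range(25):
            dims = tuple(rng.integers(2, 6, size=3))
            counts = rng.poisson(rng.uniform(0.2, 3.0), size=dims)
            mask = rng.random(dims) > 0.15
            if not mask.any():
                continue
            grid, graph = grid_and_graph(counts, mask=mask)
            clustering = density_clusters(grid, graph, "cells")
            _, marked, oracle_clusters = mark_and_flood_fill(counts, mask=mask)
            np.testing.assert_array_equal(clustering.high_density, marked, err_msg=f"trial {trial}")
            got = {
                frozenset(map(tuple, np.argwhere(clustering.cluster_label == lab)))
                for lab in range(1, clustering.n_clusters + 1)
            }
            assert got == set(oracle_clusters), f"trial {trial}"


def manual_clustering(label_array, cell_class="AML", threshold=0.0):
    label_array = np.asarray(label_array)
    return DensityClustering(
        cell_class=cell_class,
        quantile=0.75,
        q3_threshold=threshold,
        high_density=label_array > 0,
        cluster_label=label_array.astype(np.int64),
        n_clusters=int(label_array.max()),
    )


class TestClusterRegions:
    def test_interior_singleton_has_six_surround_cubes(self, grid_and_graph):
        grid, graph = grid_and_graph(np.zeros((3, 3, 3), dtype=int))
        labels = np.zeros((3, 3, 3), dtype=int)
        labels[1, 1, 1] = 1
        (region,) = cluster_regions(manual_clustering(labels), graph)
        assert region.sizes == (1, 6)

    def test_corner_singleton_has_three_surround_cubes(self, grid_and_graph):
        grid, graph = grid_and_graph(np.zeros((3, 3, 3), dtype=int))
        labels = np.zeros((3, 3, 3), dtype=int)
        labels[0, 0, 0] = 1
        (region,) = cluster_regions(manual_clustering(labels), graph)
        assert region.sizes == (1, 3)

    def test_surround_excludes_other_clusters_by_default(self, grid_and_graph):
        grid, graph = grid_and_graph(np.zeros((5, 1, 1), dtype=int))
        labels = np.zeros((5, 1, 1), dtype=int)
        labels[0] = 1
        labels[2] = 2
        regions = cluster_regions(manual_clustering(labels), graph)
        # cube 1 separates the clusters; it is the only candidate surround
        assert regions[0].adjacent.tolist() == [1]
        assert regions[1].adjacent.tolist() == [1, 3]

    def test_touching_clusters_violate_contiguity(self, grid_and_graph):
        grid, graph = grid_and_graph(np.zeros((4, 1, 1), dtype=int))
        labels = np.array([1, 2, 0, 0]).reshape(4, 1, 1)
        with pytest.raises(ValueError, match="contiguity"):
            cluster_regions(manual_clustering(labels), graph)

    def test_fully_covered_grid_yields_untestable_region(self, grid_and_graph):
        grid, graph = grid_and_graph(np.zeros((2, 1, 1), dtype=int))
        labels = np.ones((2, 1, 1), dtype=int)
        (region,) = cluster_regions(manual_clustering(labels), graph)
        assert not region.testable and region.sizes == (2, 0)


class TestPermutationTest:
    def grid_with(self, cluster_counts, surround_counts):
        n1, n2 = len(cluster_counts), len(surround_counts)
        counts = np.array(cluster_counts + surround_counts).reshape(n1 + n2, 1, 1)
        grid = CubeGrid.from_counts(counts, cube_size=45.0, cell_class="CTL")
        region = ClusterRegion(
            cluster_id=1,
            members=np.arange(n1),
            adjacent=np.arange(n1, n1 + n2),
        )
        return grid, region

    def test_tied_counts_give_p_one(self):
        grid, region = self.grid_with([3, 3], [3, 3])
        result = permutation_test(grid, region, "CTL", mode="exhaustive")
        assert result.observed_M == 0.0 and result.p_raw == 1.0

    def test_pure_split_exhaustive_p_is_two_sixths(self):
        grid, region = self.grid_with([10, 10], [0, 0])
        result = permutation_test(grid, region, "CTL", mode="exhaustive")
        assert result.observed_M == pytest.approx(10.0)
        assert result.p_raw == pytest.approx(2 / 6)
        assert result.n_permutations == 6

    def test_monte_carlo_converges_to_exhaustive(self):
        rng = np.random.default_rng(17)
        cluster = list(rng.poisson(3, 4))
        surround = list(rng.poisson(1, 5))
        grid, region = self.grid_with(cluster, surround)
        exact = permutation_test(grid, region, "CTL", mode="exhaustive").p_raw
        approx = permutation_test(grid, region, "CTL", m=20000, seed=1).p_raw
        assert abs(approx - exact) < 0.02

    def test_seeded_runs_are_bit_reproducible(self):
        grid, region = self.grid_with([5, 1, 4], [0, 2, 1, 3])
        a = permutation_test(grid, region, "CTL", m=5000, seed=99)
        b = permutation_test(grid, region, "CTL", m=5000, seed=99)
        assert a.p_raw == b.p_raw

    def test_untestable_region_is_skipped_not_p_one(self):
        grid, _ = self.grid_with([1, 2], [3])
        region = ClusterRegion(cluster_id=1, members=np.array([0, 1]), adjacent=np.array([], dtype=int))
        result = permutation_test(grid, region, "CTL")
        assert not result.testable and result.p_raw is None

    def test_exhaustive_bound_is_enforced(self):
        grid, region = self.grid_with(list(range(12)), list(range(12)))
        with pytest.raises(ValueError, match="exceeds the bound"):
            permutation_test(grid, region, "CTL", mode="exhaustive", exhaustive_bound=100)


class TestHolmBonferroni:
    def test_single_p_value_unchanged(self):
        assert holm_bonferroni([0.04]) == pytest.approx([0.04])

    def test_two_p_values_step_down(self):
        assert holm_bonferroni([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_capped_at_one(self):
        assert holm_bonferroni([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_dominates_raw_and_is_below_bonferroni(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.001, 1.0, size=12)
        adj = holm_bonferroni(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= np.minimum(1.0, p * len(p)) + 1e-15).all()

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.001, 1.0, size=9)
        perm = rng.permutation(len(p))
        adj = holm_bonferroni(p)
        adj_perm = holm_bonferroni(p[perm])
        assert adj_perm == pytest.approx(adj[perm])

    def test_rejects_values_outside_unit_interval(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.0, 0.5])
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])

    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=25,
        )
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_step_down_bounds_hold_for_arbitrary_inputs(self, p):
        p = np.asarray(p)
        adj = holm_bonferroni(p)
        assert ((adj >= p - 1e-12) & (adj <= 1.0 + 1e-12)).all()
        assert (adj <= np.minimum(1.0, p * len(p)) + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()  # monotone in the p ordering


def composition_grid(inside_with, inside_without, outside_with, outside_without):
    """1D grid: first block in-cluster; 'with' cubes contain one CTL, never MK."""
    n = inside_with + inside_without + outside_with + outside_without
    ctl = np.zeros((n, 1, 1), dtype=int)
    ctl[:inside_with] = 1
    start = inside_with + inside_without
    ctl[start : start + outside_with] = 1
    counts = {
        "AML": np.zeros((n, 1, 1), dtype=int),
        "CTL": ctl,
        "MK": np.zeros((n, 1, 1), dtype=int),
    }
    grid = CubeGrid.from_counts(counts, cube_size=45.0)
    labels = np.zeros((n, 1, 1), dtype=int)
    labels[: inside_with + inside_without] = 1
    return grid, manual_clustering(labels)


class TestPresenceGlm:
    def test_matches_closed_form_odds_ratio(self):
        grid, clustering = composition_grid(20, 80, 200, 200)
        result = presence_glm(grid, clustering, "first-only", ("CTL", "MK"))
        assert result.odds_ratio == pytest.approx(0.25, abs=1e-8)
        assert result.coefficient == pytest.approx(np.log(0.25), abs=1e-8)
        assert not result.separation_flag

    def test_identical_split_gives_odds_ratio_one(self):
        grid, clustering = composition_grid(30, 70, 30, 70)
        result = presence_glm(grid, clustering, "first-only", ("CTL", "MK"))
        assert result.odds_ratio == pytest.approx(1.0, abs=1e-8)
        assert result.coefficient == pytest.approx(0.0, abs=1e-8)

    def test_zero_cell_flags_separation(self):
        grid, clustering = composition_grid(0, 100, 200, 200)
        with pytest.warns(UserWarning, match="separation"):
            result = presence_glm(grid, clustering, "first-only", ("CTL", "MK"))
        assert result.separation_flag
        assert not np.isfinite(result.coefficient) or np.isnan(result.std_error)

    def test_single_level_response_is_rejected(self):
        grid, clustering = composition_grid(20, 80, 200, 200)
        clustering.cluster_label[:] = 0
        clustering.high_density[:] = False
        with pytest.raises(ValueError, match="response levels"):
            presence_glm(grid, clustering, "first-only", ("CTL", "MK"))

    def test_wald_p_value_detects_strong_depletion(self):
        grid, clustering = composition_grid(20, 380, 200, 200)
        result = presence_glm(grid, clustering, "first-only", ("CTL", "MK"))
        assert result.odds_ratio < 0.2
        assert result.p_value < 1e-6


class TestQuartileNeighborhoods:
    def make_grid(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        counts = {
            "AML": rng.poisson(4, size=(n, 1, 1)),
            "CTL": rng.poisson(0.3, size=(n, 1, 1)),
            "MK": rng.poisson(0.1, size=(n, 1, 1)),
        }
        return CubeGrid.from_counts(counts, cube_size=45.0)

    def test_sixteen_categories_partition_the_cubes(self):
        grid = self.make_grid()
        nb = quartile_neighborhoods(grid, "AML", ("CTL", "MK"))
        assert len(nb.categories) == 16
        assert len(set(nb.categories)) == 16
        assert nb.category_counts.sum() == grid.n_nodes
        assert set(nb.table["category"]) <= set(nb.categories)

    def test_low_density_empty_cube_lands_in_q1_absent_absent(self):
        counts = {
            "AML": np.arange(8).reshape(8, 1, 1),
            "CTL": np.zeros((8, 1, 1), dtype=int),
            "MK": np.zeros((8, 1, 1), dtype=int),
        }
        grid = CubeGrid.from_counts(counts, cube_size=45.0)
        nb = quartile_neighborhoods(grid, "AML", ("CTL", "MK"))
        first = nb.table.iloc[0]
        assert first["quartile"] == 1
        assert first["category"] == "Q1|CTL-|MK-"

    def test_ties_go_to_the_lowest_qualifying_bin(self):
        counts = {
            "AML": np.full((8, 1, 1), 5, dtype=int),
            "CTL": np.zeros((8, 1, 1), dtype=int),
            "MK": np.zeros((8, 1, 1), dtype=int),
        }
        grid = CubeGrid.from_counts(counts, cube_size=45.0)
        nb = quartile_neighborhoods(grid, "AML", ("CTL", "MK"))
        assert (nb.table["quartile"] == 1).all()

    def test_quartile_bins_are_balanced_for_continuousish_counts(self):
        grid = self.make_grid(seed=5, n=400)
        nb = quartile_neighborhoods(grid, "AML", ("CTL", "MK"))
        shares = nb.table["quartile"].value_counts(normalize=True)
        assert shares.max() < 0.45  # no bin swallows the grid
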