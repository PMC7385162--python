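import itertools

import numpy as np
import pytest

from cytopool.cluster import (
    assign_cells,
    cluster_sample,
    derive_seed,
    metacluster,
    pool_centers,
    repeated_metacluster,
)
from cytopool.io import CellMatrix


def cm(values, sample_id="s1"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and values.shape[1] > 1:
        values = values.T
    return CellMatrix(sample_id, values, [f"c{i}" for i in range(values.shape[1])])


def wcss(values, labels):
    total = 0.0
    for lab in np.unique(labels):
        members = values[labels == lab]
        total += ((members - members.mean(axis=0)) ** 2).sum()
    return total


def best_partition_wcss(values, k):
    """Exhaustive minimum within-cluster sum of squares over all k-partitions."""
    n = values.shape[0]
    best = np.inf
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) != k:
            continue
        best = min(best, wcss(values, np.array(assignment)))
    return best


class TestClusterSample:
    def test_two_well_separated_groups_found_exactly(self):
        cells = cm([0.0, 0.1, 10.0, 10.1])
        sc = cluster_sample(cells, 2, seed=0)
        centers = np.sort(sc.centers.ravel())
        np.testing.assert_allclose(centers, [0.05, 10.05])
        assert sorted(sc.sizes.tolist()) == [2, 2]

    def test_k_equals_n_gives_singletons(self):
        cells = cm([0.0, 1.0, 2.0, 3.0])
        sc = cluster_sample(cells, 4, seed=0)
        assert sc.n_clusters == 4
        np.testing.assert_allclose(np.sort(sc.centers.ravel()), [0, 1, 2, 3])

    def test_identical_cells_single_cluster(self):
        cells = cm([2.5, 2.5, 2.5])
        sc = cluster_sample(cells, 1, seed=0)
        assert sc.n_clusters == 1
        assert sc.centers[0, 0] == pytest.approx(2.5)

    def test_k_above_n_cells_rejected(self):
        with pytest.raises(ValueError, match="lower k"):
            cluster_sample(cm([1.0, 2.0]), 3, seed=0)
        with pytest.raises(ValueError, match=">= 1"):
            cluster_sample(cm([1.0, 2.0]), 0, seed=0)

    def test_centers_equal_member_means_and_sizes_sum(self, rng):
        cells = cm(rng.normal(size=(60, 3)).tolist())
        sc = cluster_sample(cells, 5, seed=3)
        assert sc.sizes.sum() == cells.n_cells
        for j in range(sc.n_clusters):
            np.testing.assert_allclose(
                sc.centers[j], cells.values[sc.assignments == j].mean(axis=0)
            )

    @pytest.mark.parametrize("n,k", [(8, 2), (9, 3), (12, 3)])
    def test_wcss_matches_exhaustive_partition_minimum(self, rng, n, k):
        # restarts across seeds are allowed: k-means is a local optimizer
        values = rng.normal(size=(n, 2))
        achieved = min(
            wcss(values, cluster_sample(cm(values.tolist()), k, seed=s).assignments)
            for s in range(10)
        )
        optimal = best_partition_wcss(values, k)
        assert achieved == pytest.approx(optimal, rel=1e-9)


class TestPoolCenters:
    def test_concatenation_with_provenance(self):
        a = cluster_sample(cm([0, 1, 10, 11, 20, 21], "a"), 3, seed=0)
        b = cluster_sample(cm([5, 6, 15, 16, 25, 26], "b"), 3, seed=0)
        pooled, provenance, weights = pool_centers([a, b])
        assert pooled.shape == (6, 1)
        assert provenance == [("a", 0), ("a", 1), ("a", 2), ("b", 0), ("b", 1), ("b", 2)]
        assert weights.sum() == 12

    def test_single_sample_identity(self):
        a = cluster_sample(cm([0, 1, 10, 11], "a"), 2, seed=0)
        pooled, _, _ = pool_centers([a])
        np.testing.assert_array_equal(pooled, a.centers)

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError, match="no clusterings"):
            pool_centers([])
        a = cluster_sample(cm([0.0, 1.0], "a"), 1, seed=0)
        b = cluster_sample(
            CellMatrix("b", np.zeros((2, 2)), ["c0", "c1"]), 1, seed=0
        )
        with pytest.raises(ValueError, match="mismatch"):
            pool_centers([a, b])


class TestMetacluster:
    def test_separates_low_and_high_centers(self):
        pooled = np.array([[0.0], [0.1], [10.0], [10.1]])
        provenance = [("s1", 0), ("s1", 1), ("s2", 0), ("s2", 1)]
        sol = metacluster(pooled, provenance, 2, seed=0)
        assert sol.cluster_to_meta[("s1", 0)] == sol.cluster_to_meta[("s1", 1)]
        assert sol.cluster_to_meta[("s2", 0)] == sol.cluster_to_meta[("s2", 1)]
        assert sol.cluster_to_meta[("s1", 0)] != sol.cluster_to_meta[("s2", 0)]

    def test_k_prime_equals_k_identity_up_to_labeling(self, rng):
        pooled = rng.normal(size=(6, 2)) * 10
        provenance = [("s", j) for j in range(6)]
        sol = metacluster(pooled, provenance, 6, seed=0)
        assert sol.n_meta == 6
        assert sorted(sol.cluster_to_meta.values()) == list(range(6))

    def test_identical_centers_collapse(self):
        pooled = np.ones((4, 2))
        provenance = [("s", j) for j in range(4)]
        sol = metacluster(pooled, provenance, 1, seed=0)
        assert sol.n_meta == 1

    def test_k_prime_above_k_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            metacluster(np.ones((2, 1)), [("s", 0), ("s", 1)], 3, seed=0)


class TestRepeatedMetaclustering:
    def test_total_feature_count_scales_with_solutions(self, tiny_run):
        _, _, meta, _ = tiny_run
        assert meta.n_solutions == 3
        assert meta.total_metaclusters == sum(s.n_meta for s in meta.solutions)
        assert all(s.n_meta == 5 for s in meta.solutions)

    def test_same_master_seed_reproduces_solutions(self, tiny_run):
        cohort, _, meta, _ = tiny_run
        again = repeated_metacluster(
            cohort.cells, k_per_sample=20, k_prime=5, n_solutions=3, master_seed=11
        )
        for a, b in zip(meta.solutions, again.solutions):
            np.testing.assert_array_equal(a.meta_centers, b.meta_centers)
            assert a.cluster_to_meta == b.cluster_to_meta

    def test_sample_stage_shared_across_solutions(self, tiny_run):
        _, _, meta, _ = tiny_run
        assert meta.shared_sample_stage
        first = meta.clusterings[1]
        assert all(meta.clusterings[it] is first for it in meta.clusterings)

    def test_every_cell_labeled_once_per_solution(self, tiny_run):
        cohort, _, meta, _ = tiny_run
        for sol in meta.solutions:
            for sc, cells in zip(meta.clusterings_for(sol), cohort.cells):
                labels = assign_cells(sc, sol)
                assert labels.shape == (cells.n_cells,)
                counts = np.bincount(labels, minlength=sol.n_meta)
                assert counts.sum() == cells.n_cells

    def test_pluggable_clusterer_used_in_both_stages(self):
        calls = []

        def halves(values, k, seed):
            calls.append(values.shape[0])
            return (np.arange(values.shape[0]) * k // values.shape[0]).astype(int)

        cells = [cm(np.linspace(0, 1, 10).tolist(), f"s{i}") for i in range(2)]
        meta = repeated_metacluster(
            cells, k_per_sample=2, k_prime=2, n_solutions=2,
            master_seed=0, clusterer=halves,
        )
        assert len(calls) == 2 + 2  # two samples, then two metacluster runs
        for sol in meta.solutions:
            for sc in meta.clusterings_for(sol):
                labels = assign_cells(sc, sol)
                assert np.bincount(labels).sum() == 10

    def test_small_sample_caps_k_at_cell_count(self):
        cells = [cm([0.0, 1.0, 2.0], "small"), cm(np.linspace(0, 9, 40).tolist(), "big")]
        meta = repeated_metacluster(
            cells, k_per_sample=10, k_prime=4, n_solutions=1, master_seed=0
        )
        small_sc = meta.clusterings[1][0]
        assert small_sc.n_clusters <= 3


class TestAssignCells:
    def test_mapping_composition(self):
        sc = cluster_sample(cm([0, 0, 10, 10], "s"), 2, seed=0)
        lo = int(sc.centers.argmin())
        sol_map = {("s", lo): 7, ("s", 1 - lo): 3}
        from cytopool.cluster import MetaclusterSolution

        sol = MetaclusterSolution(1, np.zeros((8, 1)), sol_map)
        labels = assign_cells(sc, sol)
        np.testing.assert_array_equal(labels, [7, 7, 3, 3])

    def test_unmapped_cluster_raises(self):
        sc = cluster_sample(cm([0.0, 10.0], "s"), 2, seed=0)
        from cytopool.cluster import MetaclusterSolution

        sol = MetaclusterSolution(1, np.zeros((1, 1)), {("s", 0): 0})
        with pytest.raises(RuntimeError, match="does not cover"):
            assign_cells(sc, sol)


def test_derive_seed_is_path_dependent_not_order_dependent():
    a = derive_seed(42, 1, 0)
    assert a == derive_seed(42, 1, 0)
    assert a != derive_seed(42, 1, 1)
    assert a != derive_seed(43, 1, 0)
    assert 0 <= a < 2**31
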