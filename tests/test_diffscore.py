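import itertools
import math

import numpy as np
import pytest
from scipy.stats import rankdata

from cytopool.cluster import MetaclusterSolution
from cytopool.diffscore import (
    ClusterSignificance,
    build_differentiation_map,
    cell_similarity,
    cluster_significance,
    differentiation_scores,
    embed_2d,
    rank_sum_p,
    render_map,
    subsample_cells,
)
from cytopool.features import FrequencyMatrix
from cytopool.io import CellMatrix


def enumeration_rank_sum_p(x_a, x_b):
    """Exact two-sided p by enumerating every rank assignment."""
    pooled = np.concatenate([x_a, x_b])
    ranks = rankdata(pooled)
    n = len(x_a)
    obs = ranks[:n].sum()
    stats = np.array([sum(c) for c in itertools.combinations(ranks, n)])
    p = 2 * min((stats <= obs).mean(), (stats >= obs).mean())
    return min(1.0, p)


class TestRankSum:
    def test_fully_separated_small_groups(self):
        assert rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        assert rank_sum_p([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_group_swap_symmetry(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=5), rng.normal(size=7)
            assert rank_sum_p(a, b) == pytest.approx(rank_sum_p(b, a))

    def test_matches_enumeration_for_small_groups(self, rng):
        for _ in range(40):
            n, m = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            a, b = rng.normal(size=n), rng.normal(size=m)
            assert rank_sum_p(a, b) == pytest.approx(
                enumeration_rank_sum_p(a, b), abs=1e-12
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_sum_p([], [1.0])


def small_F():
    values = np.array(
        [[0.8, 0.2], [0.7, 0.3], [0.6, 0.4], [0.3, 0.7], [0.2, 0.8], [0.1, 0.9]]
    )
    return FrequencyMatrix(
        values=values,
        column_meta=[(1, 0), (1, 1)],
        sample_ids=[f"s{i}" for i in range(6)],
    )


class TestClusterSignificance:
    def test_shifted_frequencies_detected(self):
        sig = cluster_significance(small_F(), [0, 0, 0, 1, 1, 1])
        assert sig.p_values[(1, 0)] == pytest.approx(0.1)
        assert sig.direction[(1, 0)] == -1  # class 1 has lower mc0 frequency
        assert sig.direction[(1, 1)] == 1

    def test_comparison_subset_restricts_the_test(self):
        sig = cluster_significance(
            small_F(), [0, 0, 0, 1, 1, 1], comparison_samples=["s0", "s1", "s4", "s5"]
        )
        assert sig.comparison_samples == ["s0", "s1", "s4", "s5"]
        assert sig.p_values[(1, 0)] == pytest.approx(
            rank_sum_p([0.8, 0.7], [0.2, 0.1])
        )

    def test_empty_group_in_subset_rejected(self):
        with pytest.raises(ValueError, match="class-1"):
            cluster_significance(
                small_F(), [0, 0, 0, 1, 1, 1], comparison_samples=["s0", "s1"]
            )


class TestSubsample:
    def cells(self):
        return [
            CellMatrix("a", np.full((30, 2), 0.0), ["x", "y"]),
            CellMatrix("b", np.full((20, 2), 1.0), ["x", "y"]),
        ]

    def test_requesting_everything_returns_identity(self):
        sub, prov = subsample_cells(self.cells(), n_cells=50, seed=0)
        assert sub.shape == (50, 2)
        assert len(prov) == 50

    def test_exclusion_mask_removes_sample(self):
        sub, prov = subsample_cells(
            self.cells(),
            n_cells=25,
            exclusion_mask=lambda cm: np.full(cm.n_cells, cm.sample_id == "a"),
            seed=0,
        )
        assert all(sid == "b" for sid, _ in prov)

    def test_same_seed_same_subset(self):
        s1, p1 = subsample_cells(self.cells(), n_cells=10, seed=5)
        s2, p2 = subsample_cells(self.cells(), n_cells=10, seed=5)
        np.testing.assert_array_equal(s1, s2)
        assert p1 == p2


class TestEmbedding:
    def test_pca2_preserves_collinearity(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        coords = embed_2d(pts, method="pca2", seed=0)
        # second principal direction carries no variance for collinear input
        assert np.allclose(coords[:, 1], coords[0, 1], atol=1e-9)

    def test_two_cells_embed_distinctly(self):
        coords = embed_2d(np.array([[0.0, 0.0], [5.0, 5.0]]), method="pca2", seed=0)
        assert not np.allclose(coords[0], coords[1])

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(40, 3))
        a = embed_2d(X, method="tsne", seed=4)
        b = embed_2d(X, method="tsne", seed=4)
        np.testing.assert_array_equal(a, b)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            embed_2d(np.zeros((3, 2)), method="isomapX")


class TestSimilarity:
    def test_coincident_cell_scores_one(self):
        assert cell_similarity([1.0, 2.0], [1.0, 2.0], alpha=3.0) == 1.0

    def test_closed_form(self):
        assert cell_similarity([0.0], [2.0], alpha=0.5) == pytest.approx(
            math.exp(-1.0)
        )

    def test_strictly_decreasing_in_distance(self):
        sims = [cell_similarity([0.0], [d], alpha=1.0) for d in (1, 2, 5, 20)]
        assert all(a > b for a, b in zip(sims, sims[1:]))
        assert sims[-1] > 0

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            cell_similarity([0.0], [1.0], alpha=0.0)


def two_cluster_solution():
    centers = np.array([[0.0], [2.0]])
    return MetaclusterSolution(1, centers, {("s", 0): 0, ("s", 1): 1})


def sig_for(w0, w1):
    return ClusterSignificance(
        p_values={(1, 0): w0, (1, 1): w1},
        direction={(1, 0): 0, (1, 1): 0},
        comparison_samples=[],
    )


class TestDifferentiationScores:
    def test_constant_weights_give_constant_scores(self, rng):
        cells = rng.normal(size=(20, 1))
        scores = differentiation_scores(
            cells, [two_cluster_solution()], sig_for(0.4, 0.4)
        )
        np.testing.assert_allclose(scores, 0.4)

    def test_equidistant_cell_averages_the_weights(self):
        cells = np.array([[1.0]])  # midway between centers 0 and 2
        scores = differentiation_scores(
            cells, [two_cluster_solution()], sig_for(0.01, 1.0), standardize=False
        )
        assert scores[0] == pytest.approx(0.505)

    def test_large_alpha_converges_to_nearest_center_weight(self):
        cells = np.array([[0.05]])
        scores = differentiation_scores(
            cells,
            [two_cluster_solution()],
            sig_for(0.01, 1.0),
            alpha=200.0,
            standardize=False,
        )
        assert scores[0] == pytest.approx(0.01, abs=1e-6)

    def test_scores_bounded_by_weight_range(self, rng):
        cells = rng.normal(size=(50, 1), scale=3)
        sols = [two_cluster_solution()]
        sig = sig_for(0.02, 0.9)
        scores = differentiation_scores(cells, sols, sig)
        assert (scores >= 0.02 - 1e-12).all() and (scores <= 0.9 + 1e-12).all()

    def test_final_score_averages_solutions(self):
        cells = np.array([[1.0]])
        sol2 = MetaclusterSolution(2, np.array([[0.0], [2.0]]), {("s", 0): 0, ("s", 1): 1})
        sig = ClusterSignificance(
            p_values={(1, 0): 0.2, (1, 1): 0.2, (2, 0): 0.6, (2, 1): 0.6},
            direction={k: 0 for k in [(1, 0), (1, 1), (2, 0), (2, 1)]},
            comparison_samples=[],
        )
        scores = differentiation_scores(
            cells, [two_cluster_solution(), sol2], sig, standardize=False
        )
        assert scores[0] == pytest.approx(0.4)


class TestRenderMap:
    def test_outputs_written_and_rows_match(self, tmp_path, rng):
        from cytopool.diffscore import DifferentiationMap

        n = 10
        dmap = DifferentiationMap(
            cells=rng.normal(size=(n, 2)),
            coords=rng.normal(size=(n, 2)),
            scores=np.full(n, 0.5),  # constant scores: degenerate colorbar path
            provenance=[("s", i) for i in range(n)],
            alpha=1.0,
            channels=["x", "y"],
        )
        paths = render_map(dmap, tmp_path / "new_dir", marker_panels=True)
        assert paths["figure"].exists()
        assert paths["marker_figure"].exists()
        import pandas as pd

        table = pd.read_csv(paths["table"])
        assert len(table) == n
        assert list(table.columns) == ["sample_id", "cell_index", "x", "y", "score"]


def test_full_map_assembly(tiny_run):
    cohort, _, meta, F = tiny_run
    sig = cluster_significance(F, cohort.manifest.labels)
    dmap = build_differentiation_map(
        cohort.cells, meta.solutions, sig, n_cells=300, method="pca2", seed=0
    )
    assert dmap.coords.shape == (300, 2)
    w = np.array(list(sig.p_values.values()))
    assert dmap.scores.min() >= w.min() - 1e-12
    assert dmap.scores.max() <= w.max() + 1e-12
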