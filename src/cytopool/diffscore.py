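"""Per-cell differentiation scores over a 2-D embedding.

Cluster-level case-control statistics are mapped back onto single cells:
each metacluster *j* gets a two-sided Wilcoxon rank-sum p-value ``w_j``
comparing its frequency feature between the two groups (optionally restricted
to a comparison subset of samples, e.g. one timepoint), and each cell *i*
gets, per solution *m*, the similarity-weighted average

    p_i^m = sum_j s_ji w_j / sum_j s_ji,   s_ji = exp(-alpha ||c_j - x_i||_2)

over that solution's metacluster centers. The final score is the mean of
``p_i^m`` over the ``I`` solutions. Low scores flag cells in populations
whose abundance separates the groups. The p-values order populations for
visualization only — no multiple-testing correction is applied and no
classical inferential claim is attached to them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu

from .cluster import MetaclusterSolution, derive_seed
from .features import FrequencyMatrix
from .io import CellMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ClusterSignificance",
    "DifferentiationMap",
    "rank_sum_p",
    "cluster_significance",
    "subsample_cells",
    "build_differentiation_map",
    "embed_2d",
    "cell_similarity",
    "differentiation_scores",
    "render_map",
]

EXACT_GROUP_LIMIT = 25  # exact rank-sum null up to this per-group size


def rank_sum_p(x_a: np.ndarray, x_b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when both groups have <= 25 observations and the
    data carry no ties; the tie-corrected normal approximation otherwise.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.size == 0 or x_b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x_a, x_b])
    has_ties = np.unique(pooled).size < pooled.size
    small = max(x_a.size, x_b.size) <= EXACT_GROUP_LIMIT
    method = "exact" if (small and not has_ties) else "asymptotic"
    return float(
        mannwhitneyu(x_a, x_b, alternative="two-sided", method=method).pvalue
    )


@dataclass
class ClusterSignificance:
    """Per-(iteration, metacluster) rank-sum p-value and direction of change."""

    p_values: dict[tuple[int, int], float]
    direction: dict[tuple[int, int], int]  # sign of median(freq_1) - median(freq_0)
    comparison_samples: list[str]

    def weights_for(self, sol: MetaclusterSolution) -> np.ndarray:
        try:
            return np.array(
                [self.p_values[(sol.iteration_id, j)] for j in range(sol.n_meta)]
            )
        except KeyError as exc:
            raise ValueError(
                f"significance table does not cover metacluster {exc} of "
                f"solution {sol.iteration_id}"
            ) from exc

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(self.p_values)
        return pd.DataFrame(
            {
                "iteration": [k[0] for k in keys],
                "metacluster": [k[1] for k in keys],
                "p_value": [self.p_values[k] for k in keys],
                "direction": [self.direction[k] for k in keys],
            }
        )


def cluster_significance(
    F: FrequencyMatrix,
    labels: Sequence[int],
    comparison_samples: Sequence[str] | None = None,
) -> ClusterSignificance:
    """Rank-sum significance of every metacluster's frequency feature.

    ``comparison_samples`` restricts the test to a subset of sample ids (the
    classification task and the visualized contrast need not coincide — e.g.
    a single timepoint out of a longitudinal cohort); default is all samples.
    """
    labels = np.asarray(labels, dtype=int)
    if comparison_samples is None:
        keep = np.arange(F.n_samples)
    else:
        wanted = set(comparison_samples)
        keep = np.array(
            [i for i, sid in enumerate(F.sample_ids) if sid in wanted], dtype=int
        )
    sub_labels = labels[keep]
    for cls in (0, 1):
        if not (sub_labels == cls).any():
            raise ValueError(
                f"comparison subset has no class-{cls} samples "
                f"({len(keep)} samples selected)"
            )
    p_values: dict[tuple[int, int], float] = {}
    direction: dict[tuple[int, int], int] = {}
    for col, key in enumerate(F.column_meta):
        freq = F.values[keep, col]
        x_a = freq[sub_labels == 0]
        x_b = freq[sub_labels == 1]
        p_values[key] = rank_sum_p(x_a, x_b)
        direction[key] = int(np.sign(np.median(x_b) - np.median(x_a)))
    return ClusterSignificance(
        p_values=p_values,
        direction=direction,
        comparison_samples=[F.sample_ids[i] for i in keep],
    )


def subsample_cells(
    cells: Sequence[CellMatrix],
    n_cells: int = 30_000,
    exclusion_mask: Callable[[CellMatrix], np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Uniform subsample of pooled, non-excluded cells across all samples.

    ``exclusion_mask(sample) -> bool per cell`` removes cells (e.g. an
    abundant population such as granulocytes that would dominate the
    embedding) from the visualization universe only — modeling always uses
    every cell. Returns the stacked matrix and ``(sample_id, cell index)``
    provenance. If fewer eligible cells exist than requested, all are taken.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    pools: list[np.ndarray] = []
    provenance: list[tuple[str, int]] = []
    for cm in cells:
        if exclusion_mask is not None:
            mask = np.asarray(exclusion_mask(cm), dtype=bool)
            if mask.shape != (cm.n_cells,):
                raise ValueError("exclusion mask length does not match sample")
            idx = np.flatnonzero(~mask)
        else:
            idx = np.arange(cm.n_cells)
        pools.append(cm.values[idx])
        provenance.extend((cm.sample_id, int(i)) for i in idx)
    stacked = np.vstack(pools)
    total = stacked.shape[0]
    if total <= n_cells:
        if total < n_cells:
            log.warning("only %d eligible cells for a %d-cell subsample", total, n_cells)
        return stacked, provenance
    rng = np.random.default_rng(derive_seed(seed, 31))
    pick = np.sort(rng.choice(total, size=n_cells, replace=False))
    return stacked[pick], [provenance[i] for i in pick]


def embed_2d(cells: np.ndarray, method: str = "tsne", seed: int = 0) -> np.ndarray:
    """2-D embedding of the subsampled cells; the method is pluggable.

    ``tsne`` (default), ``pca2``, or ``umap``; any callable
    ``(matrix, seed) -> n x 2`` is also accepted.
    """
    X = np.asarray(cells, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells to embed")
    if callable(method):
        return np.asarray(method(X, seed), dtype=float)
    if method == "pca2":
        from sklearn.decomposition import PCA

        n_comp = min(2, X.shape[1])
        coords = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
        if n_comp == 1:
            coords = np.column_stack([coords[:, 0], np.zeros(X.shape[0])])
        return coords
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(2.0, (X.shape[0] - 1) / 3.0))
        return TSNE(
            n_components=2, perplexity=perplexity, random_state=seed, init="pca"
        ).fit_transform(X)
    if method == "umap":
        import umap

        return umap.UMAP(n_components=2, random_state=seed).fit_transform(X)
    raise ValueError(f"unknown embedding method {method!r}")


def cell_similarity(cell: np.ndarray, center: np.ndarray, alpha: float) -> float:
    """``exp(-alpha * ||center - cell||_2)``; 1 iff coincident."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    cell = np.asarray(cell, dtype=float)
    center = np.asarray(center, dtype=float)
    if cell.shape != center.shape:
        raise ValueError("cell and center must have equal length")
    return float(np.exp(-alpha * np.linalg.norm(center - cell)))


def differentiation_scores(
    cells: np.ndarray,
    solutions: Sequence[MetaclusterSolution],
    significance: ClusterSignificance,
    alpha: float = 1.0,
    standardize: bool = True,
) -> np.ndarray:
    """Similarity-weighted average of cluster p-values, averaged over solutions.

    With ``standardize`` (default) cells and centers are z-scored per channel
    — using the subsample's statistics — before distances are taken, so
    ``alpha`` has a channel-scale-free meaning. If a cell's similarities to
    every center of a solution underflow to zero, the nearest center's
    p-value is used instead.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    X = np.asarray(cells, dtype=float)
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
    else:
        mu = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    Xs = (X - mu) / sd

    per_solution = np.empty((len(solutions), X.shape[0]))
    for s_idx, sol in enumerate(solutions):
        w = significance.weights_for(sol)
        centers = (sol.meta_centers - mu) / sd
        dist = cdist(Xs, centers)
        sim = np.exp(-alpha * dist)
        denom = sim.sum(axis=1)
        scores = np.where(denom > 0, (sim @ w) / np.where(denom > 0, denom, 1.0), 0.0)
        dead = denom <= 0
        if dead.any():
            log.warning(
                "%d cell(s) underflowed all similarities in solution %d; "
                "using nearest-center p-value",
                int(dead.sum()),
                sol.iteration_id,
            )
            scores[dead] = w[dist[dead].argmin(axis=1)]
        per_solution[s_idx] = scores
    return per_solution.mean(axis=0)


@dataclass
class DifferentiationMap:
    """Subsampled cells, 2-D coordinates, and per-cell scores."""

    cells: np.ndarray
    coords: np.ndarray
    scores: np.ndarray
    provenance: list[tuple[str, int]]
    alpha: float
    method: str = "tsne"
    seed: int = 0
    channels: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [p[0] for p in self.provenance],
                "cell_index": [p[1] for p in self.provenance],
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "score": self.scores,
            }
        )


def build_differentiation_map(
    cells: Sequence[CellMatrix],
    solutions: Sequence[MetaclusterSolution],
    significance: ClusterSignificance,
    n_cells: int = 30_000,
    alpha: float = 1.0,
    method: str = "tsne",
    exclusion_mask: Callable[[CellMatrix], np.ndarray] | None = None,
    seed: int = 0,
) -> DifferentiationMap:
    """Subsample, embed, and score in one call."""
    sub, provenance = subsample_cells(
        cells, n_cells=n_cells, exclusion_mask=exclusion_mask, seed=seed
    )
    coords = embed_2d(sub, method=method, seed=derive_seed(seed, 32))
    scores = differentiation_scores(sub, solutions, significance, alpha=alpha)
    return DifferentiationMap(
        cells=sub,
        coords=coords,
        scores=scores,
        provenance=provenance,
        alpha=alpha,
        method=method if isinstance(method, str) else "custom",
        seed=seed,
        channels=list(cells[0].channels) if cells else None,
    )


def render_map(
    dmap: DifferentiationMap,
    out_dir: str | Path,
    stem: str = "differentiation_map",
    marker_panels: bool = False,
) -> dict[str, Path]:
    """Write the scatter figure, per-cell CSV, and a parameter JSON.

    Cells are colored by ``-log10(score)`` so outcome-associated populations
    light up. Returns the written paths. With ``marker_panels`` an extra grid
    figure colors the embedding by each channel's expression.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    color = -np.log10(np.clip(dmap.scores, 1e-300, None))
    fig, ax = plt.subplots(figsize=(7, 6))
    sc = ax.scatter(
        dmap.coords[:, 0], dmap.coords[:, 1], c=color, s=3, cmap="viridis", lw=0
    )
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_title("differentiation score ( -log10 p )")
    if np.ptp(color) == 0:  # constant scores: colorbar still renders
        sc.set_clim(color[0] - 0.5, color[0] + 0.5)
    fig.colorbar(sc, ax=ax, label="-log10(score)")
    fig.tight_layout()
    paths["figure"] = out_dir / f"{stem}.png"
    fig.savefig(paths["figure"], dpi=150)
    plt.close(fig)

    if marker_panels and dmap.channels:
        n = len(dmap.channels)
        ncol = min(4, n)
        nrow = int(np.ceil(n / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.8 * nrow), squeeze=False)
        for k, name in enumerate(dmap.channels):
            ax = axes[k // ncol][k % ncol]
            ax.scatter(
                dmap.coords[:, 0],
                dmap.coords[:, 1],
                c=dmap.cells[:, k],
                s=2,
                cmap="magma",
                lw=0,
            )
            ax.set_title(name, fontsize=8)
            ax.set_xticks([])
            ax.set_yticks([])
        for k in range(n, nrow * ncol):
            axes[k // ncol][k % ncol].axis("off")
        fig.tight_layout()
        paths["marker_figure"] = out_dir / f"{stem}_markers.png"
        fig.savefig(paths["marker_figure"], dpi=150)
        plt.close(fig)

    paths["table"] = out_dir / f"{stem}.csv"
    dmap.to_frame().to_csv(paths["table"], index=False)
    paths["params"] = out_dir / f"{stem}.json"
    with open(paths["params"], "w") as fh:
        json.dump(
            {
                "alpha": dmap.alpha,
                "method": dmap.method,
                "seed": dmap.seed,
                "n_cells": int(dmap.cells.shape[0]),
            },
            fh,
            indent=2,
        )
    return paths
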