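"""Unsupervised Laplacian-score feature selection on the sample graph.

Repeated metaclustering makes the frequency features highly redundant:
different solutions rediscover the same populations. To thin them without
touching class labels, each solution's feature block is scored with the
Laplacian score of He, Cai & Niyogi (locality-preserving feature selection):
build a k-nearest-neighbor similarity graph over the S samples from the
block, then score each feature by how well it respects the graph's local
structure. Lower scores are better; the top ``top_m`` features of each block
are retained and the retained blocks concatenated for classification.

Selection never sees class labels, so it introduces no selection bias into
downstream cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .features import FrequencyMatrix

log = logging.getLogger(__name__)

__all__ = ["SampleGraph", "SelectionResult", "build_sample_graph", "laplacian_score", "select_features"]


@dataclass
class SampleGraph:
    """Symmetric kNN similarity graph over samples (zero diagonal)."""

    weights: np.ndarray  # S x S, nonnegative, symmetric
    k_nn: int
    bandwidth: float

    @property
    def n_samples(self) -> int:
        return self.weights.shape[0]

    def degree(self) -> np.ndarray:
        return self.weights.sum(axis=1)


@dataclass
class SelectionResult:
    scores: np.ndarray  # per-column Laplacian score over the full F
    retained: dict[int, np.ndarray]  # iteration_id -> kept column indices (into F)
    top_m: int

    @property
    def retained_columns(self) -> np.ndarray:
        """All kept columns across iterations, ascending."""
        if not self.retained:
            return np.array([], dtype=int)
        return np.sort(np.concatenate(list(self.retained.values())))

    def to_frame(self, F: FrequencyMatrix) -> pd.DataFrame:
        kept = set(self.retained_columns.tolist())
        return pd.DataFrame(
            {
                "iteration": [it for it, _ in F.column_meta],
                "metacluster": [mc for _, mc in F.column_meta],
                "score": self.scores,
                "retained": [i in kept for i in range(F.n_features)],
            }
        )

    def to_csv(self, F: FrequencyMatrix, path: str | Path) -> None:
        self.to_frame(F).to_csv(path, index=False)


def build_sample_graph(
    block: np.ndarray,
    k_nn: int = 5,
    bandwidth: float | None = None,
    kernel: str = "heat",
) -> SampleGraph:
    """kNN similarity graph between samples in one feature block.

    An edge links i and j when either is among the other's ``k_nn`` Euclidean
    neighbors (union rule). Heat-kernel weights
    ``W_ij = exp(-||x_i - x_j||^2 / bandwidth)``; ``bandwidth`` defaults to
    the squared median pairwise distance of the block (scale-free). A
    ``binary`` kernel (0/1 adjacency) is available as an alternative.
    """
    block = np.asarray(block, dtype=float)
    n = block.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 samples to build a graph, got {n}")
    if not 1 <= k_nn < n:
        raise ValueError(f"k_nn must be in [1, {n - 1}], got {k_nn}")
    if kernel not in ("heat", "binary"):
        raise ValueError(f"unknown kernel {kernel!r}")

    dist = squareform(pdist(block))
    if bandwidth is None:
        med = float(np.median(dist[np.triu_indices(n, k=1)]))
        bandwidth = med**2
        if bandwidth <= 0:  # all samples identical in this block
            log.warning("degenerate block (all pairwise distances 0); bandwidth set to 1")
            bandwidth = 1.0
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    adjacency = np.zeros((n, n), dtype=bool)
    order = np.argsort(dist, axis=1, kind="stable")
    for i in range(n):
        neighbors = [j for j in order[i] if j != i][:k_nn]
        adjacency[i, neighbors] = True
    adjacency |= adjacency.T  # union of directed neighborhoods

    if kernel == "heat":
        weights = np.where(adjacency, np.exp(-(dist**2) / bandwidth), 0.0)
    else:
        weights = adjacency.astype(float)
    np.fill_diagonal(weights, 0.0)
    return SampleGraph(weights=weights, k_nn=k_nn, bandwidth=float(bandwidth))


def laplacian_score(feature: np.ndarray, graph: SampleGraph) -> float:
    """Laplacian score of one feature on the sample graph (lower = better).

    With ``D = diag(W 1)``, ``L = D - W`` and the degree-weighted centering
    ``f~ = f - (f' D 1 / 1' D 1) 1``, the score is
    ``(f~' L f~) / (f~' D f~)``. A feature constant across samples has no
    locality information; it scores ``+inf`` (worst) by convention.
    """
    f = np.asarray(feature, dtype=float)
    if f.shape != (graph.n_samples,):
        raise ValueError("feature length does not match graph size")
    d = graph.degree()
    total = d.sum()
    if total <= 0:
        raise ValueError("graph has no edges")
    f_tilde = f - (f @ d) / total
    denom = f_tilde @ (d * f_tilde)
    # relative threshold: a numerically constant feature leaves only rounding
    # residue after degree-weighted centering
    scale = float((f * f) @ d) + 1.0
    if denom <= 1e-24 * scale:
        log.debug("constant feature scored +inf")
        return float("inf")
    numer = f_tilde @ (d * f_tilde) - f_tilde @ (graph.weights @ f_tilde)  # f'Lf
    return float(numer / denom)


def select_features(
    F: FrequencyMatrix,
    k_nn: int = 5,
    bandwidth: float | None = None,
    top_m: int = 40,
    kernel: str = "heat",
) -> SelectionResult:
    """Score and select features independently within each solution's block.

    For each metaclustering iteration, a sample graph is built from that
    iteration's block alone and the ``top_m`` lowest-scoring columns are
    retained (all columns when ``top_m >= `` block width). Ties break by
    ascending column index, so selection is deterministic.
    """
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    scores = np.full(F.n_features, np.nan)
    retained: dict[int, np.ndarray] = {}
    for it in F.iteration_ids:
        cols = F.block_columns(it)
        block = F.values[:, cols]
        graph = build_sample_graph(block, k_nn=k_nn, bandwidth=bandwidth, kernel=kernel)
        block_scores = np.array([laplacian_score(block[:, j], graph) for j in range(block.shape[1])])
        scores[cols] = block_scores
        keep = min(top_m, cols.size)
        # stable argsort: equal scores keep ascending column order
        order = np.argsort(block_scores, kind="stable")[:keep]
        retained[it] = np.sort(cols[order])
    return SelectionResult(scores=scores, retained=retained, top_m=top_m)
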