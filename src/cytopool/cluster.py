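"""Per-sample clustering, center pooling, and repeated metaclustering.

The population-discovery strategy avoids downsampling: every sample is
coarsely over-clustered on all analysis channels (phenotypic + functional),
the resulting cluster centers from all samples are pooled, and the pooled
centers are re-clustered into ``K'`` metaclusters. Because the metaclustering
stage is stochastic, it is repeated ``I`` times with independent seeds,
yielding ``I`` distinct cell-to-metacluster solutions whose union defines
``P = I * K'`` overlapping cell populations. The per-sample stage is computed
once and shared across repetitions; stochastic diversity enters at the
metaclustering stage (a flag re-randomizes both stages).

Any clusterer with the signature ``(matrix, k, seed) -> labels`` can replace
the default k-means in either stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .io import CellMatrix

Clusterer = Callable[[np.ndarray, int, int], np.ndarray]

__all__ = [
    "SampleClustering",
    "MetaclusterSolution",
    "RepeatedMetaclustering",
    "kmeans_clusterer",
    "cluster_sample",
    "pool_centers",
    "metacluster",
    "repeated_metacluster",
    "assign_cells",
    "derive_seed",
]

# stream tags for deterministic, schedule-independent child seeds
_STREAM_SAMPLE = 1
_STREAM_META = 2
_STREAM_OTHER = 3


def derive_seed(master_seed: int, *path: int) -> int:
    """Derive a child seed from a master seed and an integer stream path.

    Counter-based (hash of the full path), so the result does not depend on
    how many seeds were drawn before it — parallel schedules see identical
    streams.
    """
    ss = np.random.SeedSequence([int(master_seed), *map(int, path)])
    return int(ss.generate_state(1)[0] % (2**31))


def kmeans_clusterer(values: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Default clusterer: k-means++ with 10 restarts, tol 1e-4."""
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, tol=1e-4, random_state=seed)
    return km.fit_predict(values)


@dataclass
class SampleClustering:
    """One sample's coarse partition: assignments, empirical centers, sizes."""

    sample_id: str
    assignments: np.ndarray  # per-cell cluster index in [0, n_clusters)
    centers: np.ndarray  # n_clusters x m
    sizes: np.ndarray  # per-cluster cell counts

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


@dataclass
class MetaclusterSolution:
    """One stochastic metaclustering: centers plus the pooled-cluster map."""

    iteration_id: int
    meta_centers: np.ndarray  # n_meta x m
    cluster_to_meta: dict[tuple[str, int], int] = field(repr=False)

    @property
    def n_meta(self) -> int:
        return self.meta_centers.shape[0]


def cluster_sample(
    cells: CellMatrix, k: int, seed: int, clusterer: Clusterer | None = None
) -> SampleClustering:
    """Cluster one sample's cells into at most ``k`` clusters.

    Empty clusters are dropped and indices compacted, so ``k`` is an upper
    bound. Centers are recomputed as member means so they satisfy the
    center-equals-mean invariant exactly regardless of the clusterer's own
    convergence tolerance.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > cells.n_cells:
        raise ValueError(
            f"sample {cells.sample_id!r}: k={k} exceeds n_cells={cells.n_cells}; "
            "lower k (or rely on the automatic cap in repeated_metacluster)"
        )
    clusterer = clusterer or kmeans_clusterer
    labels = np.asarray(clusterer(cells.values, k, seed))
    used, assignments = np.unique(labels, return_inverse=True)
    n_clusters = used.size
    centers = np.empty((n_clusters, cells.values.shape[1]))
    sizes = np.empty(n_clusters, dtype=int)
    for j in range(n_clusters):
        members = assignments == j
        sizes[j] = int(members.sum())
        centers[j] = cells.values[members].mean(axis=0)
    return SampleClustering(
        sample_id=cells.sample_id, assignments=assignments, centers=centers, sizes=sizes
    )


def pool_centers(
    clusterings: Sequence[SampleClustering],
) -> tuple[np.ndarray, list[tuple[str, int]], np.ndarray]:
    """Stack all samples' cluster centers into one ``K x m`` matrix.

    Returns the pooled matrix, row-aligned provenance ``(sample_id, cluster)``
    pairs, and row-aligned cluster sizes (kept for diagnostics; the
    metaclustering stage treats centers as unweighted points).
    """
    if not clusterings:
        raise ValueError("no clusterings to pool")
    width = clusterings[0].centers.shape[1]
    for sc in clusterings:
        if sc.centers.shape[1] != width:
            raise ValueError(
                f"channel-order mismatch: sample {sc.sample_id!r} has "
                f"{sc.centers.shape[1]} channels, expected {width}"
            )
    pooled = np.vstack([sc.centers for sc in clusterings])
    provenance = [
        (sc.sample_id, j) for sc in clusterings for j in range(sc.n_clusters)
    ]
    weights = np.concatenate([sc.sizes for sc in clusterings])
    return pooled, provenance, weights


def metacluster(
    pooled: np.ndarray,
    provenance: Sequence[tuple[str, int]],
    k_prime: int,
    seed: int,
    clusterer: Clusterer | None = None,
    iteration_id: int = 1,
) -> MetaclusterSolution:
    """Cluster pooled centers into at most ``k_prime`` metaclusters."""
    pooled = np.asarray(pooled, dtype=float)
    if k_prime > pooled.shape[0]:
        raise ValueError(
            f"k_prime={k_prime} exceeds the number of pooled centers {pooled.shape[0]}"
        )
    if k_prime < 1:
        raise ValueError(f"k_prime must be >= 1, got {k_prime}")
    clusterer = clusterer or kmeans_clusterer
    labels = np.asarray(clusterer(pooled, k_prime, seed))
    used, compact = np.unique(labels, return_inverse=True)
    centers = np.empty((used.size, pooled.shape[1]))
    for j in range(used.size):
        centers[j] = pooled[compact == j].mean(axis=0)
    mapping = {tuple(p): int(m) for p, m in zip(provenance, compact)}
    return MetaclusterSolution(
        iteration_id=iteration_id, meta_centers=centers, cluster_to_meta=mapping
    )


@dataclass
class RepeatedMetaclustering:
    """``I`` metaclustering solutions plus the clusterings behind each one."""

    solutions: list[MetaclusterSolution]
    clusterings: dict[int, list[SampleClustering]]  # iteration_id -> per-sample
    shared_sample_stage: bool

    def clusterings_for(self, sol: MetaclusterSolution) -> list[SampleClustering]:
        return self.clusterings[sol.iteration_id]

    @property
    def n_solutions(self) -> int:
        return len(self.solutions)

    @property
    def total_metaclusters(self) -> int:
        """P, the pooled feature count across all solutions."""
        return sum(s.n_meta for s in self.solutions)


def repeated_metacluster(
    cells: Sequence[CellMatrix],
    k_per_sample: int,
    k_prime: int,
    n_solutions: int,
    master_seed: int,
    clusterer: Clusterer | None = None,
    recluster_samples: bool = False,
) -> RepeatedMetaclustering:
    """Produce ``n_solutions`` independent metaclustering solutions.

    Per-sample clustering is computed once and reused across solutions by
    default; set ``recluster_samples`` to re-randomize both stages per
    solution. ``k_per_sample`` is capped at each sample's cell count. Child
    seeds are derived per (stage, sample/iteration) so results are
    independent of execution order.
    """
    if n_solutions < 1:
        raise ValueError("n_solutions must be >= 1")

    def run_sample_stage(stream: int) -> list[SampleClustering]:
        out = []
        for idx, cm in enumerate(cells):
            seed = derive_seed(master_seed, _STREAM_SAMPLE, stream, idx)
            out.append(
                cluster_sample(cm, min(k_per_sample, cm.n_cells), seed, clusterer)
            )
        return out

    shared = None if recluster_samples else run_sample_stage(0)
    solutions: list[MetaclusterSolution] = []
    by_iteration: dict[int, list[SampleClustering]] = {}
    for m in range(1, n_solutions + 1):
        clusterings = shared if shared is not None else run_sample_stage(m)
        by_iteration[m] = clusterings
        pooled, provenance, _ = pool_centers(clusterings)
        seed = derive_seed(master_seed, _STREAM_META, m)
        solutions.append(
            metacluster(
                pooled,
                provenance,
                min(k_prime, pooled.shape[0]),
                seed,
                clusterer,
                iteration_id=m,
            )
        )
    return RepeatedMetaclustering(
        solutions=solutions,
        clusterings=by_iteration,
        shared_sample_stage=shared is not None,
    )


def assign_cells(sc: SampleClustering, sol: MetaclusterSolution) -> np.ndarray:
    """Compose within-sample assignments with the cluster -> metacluster map."""
    try:
        lut = np.array(
            [sol.cluster_to_meta[(sc.sample_id, j)] for j in range(sc.n_clusters)],
            dtype=int,
        )
    except KeyError as exc:
        raise RuntimeError(
            f"solution {sol.iteration_id} does not cover cluster {exc} of "
            f"sample {sc.sample_id!r}"
        ) from exc
    return lut[sc.assignments]
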