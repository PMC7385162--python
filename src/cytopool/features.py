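"""Frequency and functional-marker feature matrices over metaclusters.

The primary feature set is the ``S x P`` frequency matrix ``F``: entry
``F[i, j]`` is the proportion of sample *i*'s cells assigned to pooled
metacluster *j* (column *j* belongs to exactly one metaclustering solution).
Because clustering uses functional as well as phenotypic channels, cell
frequencies already carry signaling information; functional mean-expression
features (``X* = [X^1 | ... | X^f]``) are available but opt-in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import (
    MetaclusterSolution,
    RepeatedMetaclustering,
    SampleClustering,
    assign_cells,
)
from .io import CellMatrix

__all__ = ["FrequencyMatrix", "FunctionalMatrix", "frequency_features", "functional_features"]


@dataclass
class FrequencyMatrix:
    """Samples x pooled-metacluster proportions with column provenance."""

    values: np.ndarray  # S x P, entries in [0, 1]
    column_meta: list[tuple[int, int]]  # (iteration_id, metacluster index)
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def iteration_ids(self) -> list[int]:
        seen: list[int] = []
        for it, _ in self.column_meta:
            if it not in seen:
                seen.append(it)
        return seen

    def block_columns(self, iteration_id: int) -> np.ndarray:
        """Column indices belonging to one metaclustering solution."""
        return np.array(
            [i for i, (it, _) in enumerate(self.column_meta) if it == iteration_id],
            dtype=int,
        )

    def column_names(self) -> list[str]:
        return [f"iter{it}_mc{mc}" for it, mc in self.column_meta]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names())
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrequencyMatrix":
        df = pd.read_csv(path, dtype={"sample_id": str})
        meta = []
        for col in df.columns[1:]:
            it, mc = col.split("_mc")
            meta.append((int(it.removeprefix("iter")), int(mc)))
        return cls(
            values=df.iloc[:, 1:].to_numpy(dtype=float),
            column_meta=meta,
            sample_ids=df["sample_id"].tolist(),
        )


@dataclass
class FunctionalMatrix:
    """Per-(metacluster, functional marker) mean expression, ``S x (P*f)``.

    Missing entries (a sample contributed no cells to a metacluster) are NaN
    in ``values``; ``values_imputed`` fills them with the metacluster's
    cross-sample mean for use in classifiers that reject missing data.
    """

    values: np.ndarray
    column_meta: list[tuple[int, int, str]]  # (iteration_id, metacluster, marker)
    sample_ids: list[str]

    def column_names(self) -> list[str]:
        return [f"iter{it}_mc{mc}_marker{mk}" for it, mc, mk in self.column_meta]

    def values_imputed(self) -> np.ndarray:
        out = self.values.copy()
        for j in range(out.shape[1]):
            col = out[:, j]
            mask = np.isnan(col)
            if mask.all():
                out[mask, j] = 0.0
            elif mask.any():
                out[mask, j] = col[~mask].mean()
        return out

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.column_names())
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)


def _counts_from_sizes(
    sc: SampleClustering, sol: MetaclusterSolution
) -> np.ndarray:
    """Per-metacluster cell counts for one sample, via cluster sizes."""
    counts = np.zeros(sol.n_meta, dtype=float)
    for j in range(sc.n_clusters):
        try:
            meta = sol.cluster_to_meta[(sc.sample_id, j)]
        except KeyError as exc:
            raise RuntimeError(
                f"solution {sol.iteration_id} does not map cluster {j} of "
                f"sample {sc.sample_id!r}"
            ) from exc
        counts[meta] += sc.sizes[j]
    return counts


def frequency_features(
    meta: RepeatedMetaclustering, sample_ids: Sequence[str] | None = None
) -> FrequencyMatrix:
    """Build ``F`` from the repeated-metaclustering result.

    Rows follow ``sample_ids`` order (default: the order samples were
    clustered in). Within each solution's column block, every row sums to 1;
    metaclusters receiving no cells from a sample get 0.
    """
    first = next(iter(meta.clusterings.values()))
    default_order = [sc.sample_id for sc in first]
    sample_ids = list(sample_ids) if sample_ids is not None else default_order

    blocks: list[np.ndarray] = []
    column_meta: list[tuple[int, int]] = []
    for sol in meta.solutions:
        clusterings = {sc.sample_id: sc for sc in meta.clusterings_for(sol)}
        block = np.zeros((len(sample_ids), sol.n_meta))
        for i, sid in enumerate(sample_ids):
            sc = clusterings[sid]
            counts = _counts_from_sizes(sc, sol)
            block[i] = counts / counts.sum()
        blocks.append(block)
        column_meta.extend((sol.iteration_id, j) for j in range(sol.n_meta))
    return FrequencyMatrix(
        values=np.hstack(blocks), column_meta=column_meta, sample_ids=sample_ids
    )


def functional_features(
    cells: Sequence[CellMatrix],
    meta: RepeatedMetaclustering,
    functional_indices: Sequence[int],
    functional_names: Sequence[str] | None = None,
) -> FunctionalMatrix:
    """Mean functional-marker expression per (sample, metacluster).

    ``functional_indices`` are column positions of functional channels within
    the analysis-channel order; empty (sample, metacluster) combinations are
    recorded as NaN.
    """
    functional_indices = list(functional_indices)
    if not functional_indices:
        raise ValueError("no functional channels given")
    if functional_names is None:
        functional_names = [str(i) for i in functional_indices]
    by_id = {cm.sample_id: cm for cm in cells}
    sample_ids = [cm.sample_id for cm in cells]

    marker_blocks: dict[str, list[np.ndarray]] = {m: [] for m in functional_names}
    per_marker_meta: dict[str, list[tuple[int, int, str]]] = {
        m: [] for m in functional_names
    }
    for sol in meta.solutions:
        clusterings = {sc.sample_id: sc for sc in meta.clusterings_for(sol)}
        sums = np.zeros((len(sample_ids), sol.n_meta, len(functional_indices)))
        counts = np.zeros((len(sample_ids), sol.n_meta))
        for i, sid in enumerate(sample_ids):
            sc = clusterings[sid]
            labels = assign_cells(sc, sol)
            vals = by_id[sid].values[:, functional_indices]
            for mc in range(sol.n_meta):
                members = labels == mc
                counts[i, mc] = members.sum()
                if counts[i, mc]:
                    sums[i, mc] = vals[members].sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = sums / counts[:, :, None]  # NaN where count == 0
        for t, marker in enumerate(functional_names):
            marker_blocks[marker].append(means[:, :, t])
            per_marker_meta[marker].extend(
                (sol.iteration_id, j, marker) for j in range(sol.n_meta)
            )

    # X* = [X^1 | X^2 | ... | X^f]: one full S x P block per marker
    values = np.hstack([np.hstack(marker_blocks[m]) for m in functional_names])
    column_meta = [entry for m in functional_names for entry in per_marker_meta[m]]
    return FunctionalMatrix(
        values=values, column_meta=column_meta, sample_ids=sample_ids
    )
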