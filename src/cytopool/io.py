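"""Cohort ingestion: marker panels, per-sample expression matrices, manifests.

The pipeline operates on pre-gated live-cell matrices, one per biological
sample. Input files are FCS 3.0/3.1 or headered CSV (one cell per row,
channel names in the header). Channel values are transformed at load time —
by default ``arcsinh(x / 5)``, the standard variance-stabilizing transform
for mass cytometry — and channels marked ``excluded`` in the panel (DNA,
barcodes, viability dyes, event length) are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._fcs import read_fcs

log = logging.getLogger(__name__)

ROLES = ("phenotypic", "functional", "excluded")
TRANSFORMS = ("none", "arcsinh")

__all__ = [
    "ChannelSpec",
    "MarkerPanel",
    "CellMatrix",
    "SampleRecord",
    "CohortManifest",
    "Cohort",
    "ChannelMismatchError",
    "CohortValidationError",
    "read_sample",
    "load_cohort",
]


class ChannelMismatchError(ValueError):
    """A file does not provide a channel the panel requires."""


class CohortValidationError(ValueError):
    """Aggregated manifest/cohort validation failures."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "cohort validation failed:\n" + "\n".join(f"  - {p}" for p in problems)
        )


@dataclass(frozen=True)
class ChannelSpec:
    """One channel of the antibody panel.

    role
        ``phenotypic`` (lineage/surface identity), ``functional``
        (intracellular signaling readout), or ``excluded`` (dropped after
        loading).
    transform / cofactor
        ``arcsinh`` applies ``arcsinh(x / cofactor)``; ``none`` passes values
        through unchanged.
    """

    name: str
    role: str = "phenotypic"
    transform: str = "arcsinh"
    cofactor: float = 5.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"channel {self.name!r}: unknown role {self.role!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(
                f"channel {self.name!r}: unknown transform {self.transform!r}"
            )
        if self.transform == "arcsinh" and not self.cofactor > 0:
            raise ValueError(f"channel {self.name!r}: cofactor must be > 0")

    def apply(self, x: np.ndarray) -> np.ndarray:
        if self.transform == "arcsinh":
            return np.arcsinh(np.asarray(x, dtype=float) / self.cofactor)
        return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered channel list with roles and per-channel transforms."""

    channels: tuple[ChannelSpec, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names in panel")
        if not any(c.role == "phenotypic" for c in self.channels):
            raise ValueError("panel must contain at least one phenotypic channel")

    @property
    def used(self) -> tuple[ChannelSpec, ...]:
        """Channels retained for analysis (phenotypic + functional), in order."""
        return tuple(c for c in self.channels if c.role != "excluded")

    @property
    def used_names(self) -> list[str]:
        return [c.name for c in self.used]

    @property
    def phenotypic(self) -> list[str]:
        return [c.name for c in self.channels if c.role == "phenotypic"]

    @property
    def functional(self) -> list[str]:
        return [c.name for c in self.channels if c.role == "functional"]

    def functional_indices(self) -> list[int]:
        """Column indices of functional channels within the used-channel order."""
        return [i for i, c in enumerate(self.used) if c.role == "functional"]

    @classmethod
    def from_dict(cls, data: dict) -> "MarkerPanel":
        channels = []
        for entry in data["channels"]:
            channels.append(
                ChannelSpec(
                    name=entry["name"],
                    role=entry.get("role", "phenotypic"),
                    transform=entry.get("transform", "arcsinh"),
                    cofactor=float(entry.get("cofactor", 5.0)),
                )
            )
        return cls(channels=tuple(channels))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerPanel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "channels": [
                {
                    "name": c.name,
                    "role": c.role,
                    "transform": c.transform,
                    "cofactor": c.cofactor,
                }
                for c in self.channels
            ]
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class CellMatrix:
    """Transformed expression for one sample: cells x used channels."""

    sample_id: str
    values: np.ndarray
    channels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x channels)")
        if self.values.shape[1] != len(self.channels):
            raise ValueError("channel list does not match value columns")
        if self.values.shape[0] < 1:
            raise ValueError(f"sample {self.sample_id!r} has no cells")
        if not np.isfinite(self.values).all():
            raise ValueError(f"sample {self.sample_id!r} contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        # %.17g round-trips IEEE doubles exactly
        pd.DataFrame(self.values, columns=self.channels).to_csv(
            path, index=False, float_format="%.17g"
        )


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    patient_id: str
    class_label: int
    path: str

    def __post_init__(self) -> None:
        if self.class_label not in (0, 1):
            raise ValueError(
                f"sample {self.sample_id!r}: class label {self.class_label!r} not in {{0,1}}"
            )


@dataclass
class CohortManifest:
    """Sample -> patient -> class bookkeeping for one classification task."""

    records: list[SampleRecord]

    def __post_init__(self) -> None:
        problems = self.validation_problems()
        if problems:
            raise CohortValidationError(problems)

    def validation_problems(self) -> list[str]:
        problems: list[str] = []
        if not self.records:
            return ["no samples in manifest"]
        seen: set[str] = set()
        for r in self.records:
            if r.sample_id in seen:
                problems.append(f"duplicate sample_id {r.sample_id!r}")
            seen.add(r.sample_id)
        by_patient: dict[str, set[int]] = {}
        for r in self.records:
            by_patient.setdefault(r.patient_id, set()).add(r.class_label)
        for pid, labels in by_patient.items():
            if len(labels) > 1:
                problems.append(f"patient {pid!r} has samples in both classes")
        return problems

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.class_label for r in self.records], dtype=int)

    def patients_per_class(self) -> dict[int, int]:
        per_class: dict[int, set[str]] = {0: set(), 1: set()}
        for r in self.records:
            per_class[r.class_label].add(r.patient_id)
        return {k: len(v) for k, v in per_class.items()}

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortManifest":
        df = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str})
        required = {"sample_id", "patient_id", "class", "path"}
        missing = required - set(df.columns)
        if missing:
            raise CohortValidationError(
                [f"manifest missing column {c!r}" for c in sorted(missing)]
            )
        base = Path(path).parent
        records = []
        problems = []
        for _, row in df.iterrows():
            label = row["class"]
            try:
                label = int(label)
                if label not in (0, 1):
                    raise ValueError
            except (TypeError, ValueError):
                problems.append(
                    f"sample {row['sample_id']!r}: class {row['class']!r} not in {{0,1}}"
                )
                continue
            p = Path(str(row["path"]))
            if not p.is_absolute():
                p = base / p
            records.append(
                SampleRecord(
                    sample_id=str(row["sample_id"]),
                    patient_id=str(row["patient_id"]),
                    class_label=label,
                    path=str(p),
                )
            )
        if problems:
            raise CohortValidationError(problems)
        return cls(records=records)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "patient_id": self.patient_ids,
                "class": self.labels,
                "path": [r.path for r in self.records],
            }
        ).to_csv(path, index=False)


@dataclass
class Cohort:
    """Loaded cohort: per-sample matrices aligned with the manifest."""

    manifest: CohortManifest
    cells: list[CellMatrix]
    panel: MarkerPanel | None = field(default=None)

    @property
    def n_samples(self) -> int:
        return len(self.cells)

    @property
    def total_cells(self) -> int:
        return sum(c.n_cells for c in self.cells)


def _read_values(path: Path) -> tuple[np.ndarray, list[str]]:
    if path.suffix.lower() == ".fcs":
        return read_fcs(path)
    df = pd.read_csv(path, float_precision="round_trip")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def read_sample(
    path: str | Path, panel: MarkerPanel, sample_id: str | None = None
) -> CellMatrix:
    """Load one sample file, transform, and restrict to panel order.

    The returned matrix has the panel's non-excluded channels as columns, in
    panel order, regardless of the column order in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sample file not found: {path}")
    values, names = _read_values(path)
    index = {n: i for i, n in enumerate(names)}
    missing = [c.name for c in panel.used if c.name not in index]
    if missing:
        raise ChannelMismatchError(
            f"{path}: channel(s) {missing} required by the panel are absent"
        )
    cols = []
    for chan in panel.used:
        cols.append(chan.apply(values[:, index[chan.name]]))
    return CellMatrix(
        sample_id=sample_id if sample_id is not None else path.stem,
        values=np.column_stack(cols),
        channels=panel.used_names,
    )


def load_cohort(
    manifest: CohortManifest, panel: MarkerPanel, require_two_per_class: bool = True
) -> Cohort:
    """Load every manifest sample; aggregate all failures into one report."""
    problems = list(manifest.validation_problems())
    if require_two_per_class:
        for cls_label, n in manifest.patients_per_class().items():
            if n < 2:
                problems.append(
                    f"class {cls_label} has {n} patient(s); at least 2 required"
                )
    cells: list[CellMatrix] = []
    for rec in manifest.records:
        try:
            cells.append(read_sample(rec.path, panel, sample_id=rec.sample_id))
        except (OSError, ValueError) as exc:
            problems.append(f"sample {rec.sample_id!r}: {exc}")
    if problems:
        raise CohortValidationError(problems)
    cohort = Cohort(manifest=manifest, cells=cells, panel=panel)
    log.info(
        "loaded cohort: %d samples, %d cells, patients per class %s",
        cohort.n_samples,
        cohort.total_cells,
        manifest.patients_per_class(),
    )
    return cohort
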