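"""Synthetic multi-sample cytometry cohorts with known ground truth.

Each population is a diagonal Gaussian in *transformed* (post-arcsinh)
expression space — the pipeline clusters transformed data, so simulating
there sidesteps any raw-ion-count model. Per sample, population proportions
are drawn from a Dirichlet centered on the class-appropriate frequency
vector with concentration ``kappa`` (biological between-sample variability),
cell counts are multinomial, and cells are Gaussian draws. A class effect is
a multiplicative shift of one or more populations' base frequencies in class
1, renormalized to sum to one.

The default fixture emulates a small immunology case-control study: ten
channels (six lineage, four signaling), five leukocyte-like populations, one
population expanded 1.5-fold in class 1, ten patients per class with one
sample each, and 2,000 cells per sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import CellMatrix, ChannelSpec, Cohort, CohortManifest, MarkerPanel, SampleRecord

__all__ = [
    "PopulationSpec",
    "SyntheticTruth",
    "default_panel",
    "default_population_specs",
    "generate_cohort",
    "generate_null_cohort",
    "signal_cohort",
    "null_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One Gaussian cell population with an optional class-frequency effect."""

    name: str
    mean: tuple[float, ...]
    variance: tuple[float, ...]
    base_frequency: float
    effect: float = 1.0  # multiplicative frequency shift in class 1; 1.0 = null

    def __post_init__(self) -> None:
        if len(self.mean) != len(self.variance):
            raise ValueError(f"population {self.name!r}: mean/variance length mismatch")
        if any(v <= 0 for v in self.variance):
            raise ValueError(f"population {self.name!r}: variances must be > 0")
        if not 0 < self.base_frequency < 1:
            raise ValueError(f"population {self.name!r}: base_frequency must be in (0,1)")
        if self.effect <= 0:
            raise ValueError(f"population {self.name!r}: effect must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated cohort."""

    population_names: list[str]
    class_frequencies: dict[int, np.ndarray]  # class -> target proportion vector
    sample_frequencies: dict[str, np.ndarray]  # realized per-sample proportions
    cell_populations: dict[str, np.ndarray]  # per-sample per-cell population index
    effect_populations: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "population_names": self.population_names,
            "class_frequencies": {
                str(k): v.tolist() for k, v in self.class_frequencies.items()
            },
            "sample_frequencies": {
                k: v.tolist() for k, v in self.sample_frequencies.items()
            },
            "effect_populations": self.effect_populations,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def default_panel() -> MarkerPanel:
    """Ten channels: six phenotypic lineage markers, four signaling readouts.

    ``transform='none'`` throughout — synthetic values are generated directly
    on the transformed scale.
    """
    phenotypic = ["CD45", "CD3", "CD4", "CD19", "CD14", "CD56"]
    functional = ["pNFkB", "pMAPKAPK2", "pERK", "IkB"]
    channels = [ChannelSpec(name=n, role="phenotypic", transform="none") for n in phenotypic]
    channels += [ChannelSpec(name=n, role="functional", transform="none") for n in functional]
    return MarkerPanel(channels=tuple(channels))


# Population archetypes on the arcsinh scale: "high" ~ 3, "low" ~ 0.3.
# Columns follow default_panel order: CD45 CD3 CD4 CD19 CD14 CD56 | pNFkB pMK2 pERK IkB
_POP_MEANS = {
    "T_CD4": (3.0, 3.0, 3.0, 0.3, 0.3, 0.3, 1.0, 1.0, 1.0, 2.0),
    "T_CD8": (3.0, 3.0, 0.3, 0.3, 0.3, 0.5, 1.0, 1.0, 1.0, 2.0),
    "B": (3.0, 0.3, 0.3, 3.0, 0.3, 0.3, 1.0, 2.0, 1.0, 1.0),
    "Monocyte": (3.0, 0.3, 1.0, 0.3, 3.0, 0.3, 2.5, 2.0, 2.0, 1.5),
    "NK": (3.0, 0.3, 0.3, 0.3, 0.3, 3.0, 1.0, 1.0, 2.0, 1.0),
}
_POP_BASE_FREQ = {"T_CD4": 0.30, "T_CD8": 0.25, "Monocyte": 0.20, "B": 0.15, "NK": 0.10}
_POP_SD = 0.4

DEFAULT_EFFECT_POPULATION = "Monocyte"
DEFAULT_EFFECT = 1.5
# Dirichlet concentration: kappa=500 puts the between-sample frequency CV of
# a 0.20 population near 9%, the regime of a tightly batch-controlled,
# barcoded acquisition; it makes a 1.5-fold planted shift a strong effect at
# ten patients per class, which is what the fixture exists to provide.
DEFAULT_KAPPA = 500.0


def default_population_specs(
    effect: float = DEFAULT_EFFECT,
    effect_population: str = DEFAULT_EFFECT_POPULATION,
) -> list[PopulationSpec]:
    """The five-population fixture; ``effect=1.0`` yields a null design."""
    specs = []
    for name, mean in _POP_MEANS.items():
        specs.append(
            PopulationSpec(
                name=name,
                mean=mean,
                variance=(_POP_SD**2,) * len(mean),
                base_frequency=_POP_BASE_FREQ[name],
                effect=effect if name == effect_population else 1.0,
            )
        )
    return specs


def _class_frequencies(specs: Sequence[PopulationSpec]) -> dict[int, np.ndarray]:
    base = np.array([s.base_frequency for s in specs])
    if not np.isclose(base.sum(), 1.0, atol=1e-8):
        raise ValueError(f"base frequencies sum to {base.sum():.6f}, expected 1")
    shifted = base * np.array([s.effect for s in specs])
    return {0: base, 1: shifted / shifted.sum()}


def generate_cohort(
    specs: Sequence[PopulationSpec],
    n_patients_per_class: int = 10,
    samples_per_patient: int = 1,
    cells_per_sample: int = 2000,
    freq_noise_kappa: float = DEFAULT_KAPPA,
    seed: int = 0,
    panel: MarkerPanel | None = None,
) -> tuple[Cohort, SyntheticTruth]:
    """Generate a labeled two-class cohort with planted frequency effects.

    Per-sample population proportions are Dirichlet with parameter
    ``kappa * target``; the infinite-``kappa`` limit pins every sample to its
    class target vector. Deterministic given ``seed``.
    """
    specs = list(specs)
    if len(specs) < 2:
        raise ValueError("need at least 2 populations")
    if cells_per_sample < 50:
        raise ValueError("cells_per_sample must be >= 50")
    if freq_noise_kappa <= 0:
        raise ValueError("freq_noise_kappa must be > 0")
    targets = _class_frequencies(specs)
    panel = panel or default_panel()
    n_channels = len(panel.used)
    for s in specs:
        if len(s.mean) != n_channels:
            raise ValueError(
                f"population {s.name!r} has {len(s.mean)} channels, panel has {n_channels}"
            )

    rng = np.random.default_rng(seed)
    means = np.array([s.mean for s in specs])
    sds = np.sqrt(np.array([s.variance for s in specs]))

    cells: list[CellMatrix] = []
    records: list[SampleRecord] = []
    sample_freqs: dict[str, np.ndarray] = {}
    cell_pops: dict[str, np.ndarray] = {}
    for cls in (0, 1):
        for p in range(n_patients_per_class):
            patient_id = f"patient{cls}_{p:02d}"
            for s in range(samples_per_patient):
                sample_id = f"{patient_id}_s{s}"
                props = (
                    rng.dirichlet(freq_noise_kappa * targets[cls])
                    if np.isfinite(freq_noise_kappa)
                    else targets[cls].copy()
                )
                counts = rng.multinomial(cells_per_sample, props)
                pop_idx = np.repeat(np.arange(len(specs)), counts)
                values = rng.normal(means[pop_idx], sds[pop_idx])
                cells.append(
                    CellMatrix(
                        sample_id=sample_id, values=values, channels=panel.used_names
                    )
                )
                records.append(
                    SampleRecord(
                        sample_id=sample_id,
                        patient_id=patient_id,
                        class_label=cls,
                        path=f"{sample_id}.csv",
                    )
                )
                sample_freqs[sample_id] = counts / counts.sum()
                cell_pops[sample_id] = pop_idx
    manifest = CohortManifest(records=records)
    truth = SyntheticTruth(
        population_names=[s.name for s in specs],
        class_frequencies=targets,
        sample_frequencies=sample_freqs,
        cell_populations=cell_pops,
        effect_populations=[s.name for s in specs if s.effect != 1.0],
    )
    return Cohort(manifest=manifest, cells=cells, panel=panel), truth


def generate_null_cohort(
    specs: Sequence[PopulationSpec],
    n_patients_per_class: int = 20,
    samples_per_patient: int = 1,
    cells_per_sample: int = 1000,
    freq_noise_kappa: float = DEFAULT_KAPPA,
    seed: int = 0,
    panel: MarkerPanel | None = None,
) -> tuple[Cohort, SyntheticTruth]:
    """Null control: all effects forced to 1.0, labels independent of data."""
    nulled = [
        PopulationSpec(
            name=s.name,
            mean=s.mean,
            variance=s.variance,
            base_frequency=s.base_frequency,
            effect=1.0,
        )
        for s in specs
    ]
    return generate_cohort(
        nulled,
        n_patients_per_class=n_patients_per_class,
        samples_per_patient=samples_per_patient,
        cells_per_sample=cells_per_sample,
        freq_noise_kappa=freq_noise_kappa,
        seed=seed,
        panel=panel,
    )


def signal_cohort(seed: int = 0, **overrides) -> tuple[Cohort, SyntheticTruth]:
    """Default signal fixture: one population expanded 1.5-fold in class 1."""
    return generate_cohort(default_population_specs(), seed=seed, **overrides)


def null_cohort(seed: int = 0, **overrides) -> tuple[Cohort, SyntheticTruth]:
    """Default null fixture: no effects, labels carry no information."""
    return generate_null_cohort(default_population_specs(effect=1.0), seed=seed, **overrides)


def write_cohort(
    cohort: Cohort, truth: SyntheticTruth | None, out_dir: str | Path
) -> Path:
    """Persist a cohort as per-sample CSVs + manifest + panel (+ truth JSON).

    The written tree is valid pipeline input: the manifest paths point at the
    CSVs and the panel records ``transform: none`` so values round-trip.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for cm, rec in zip(cohort.cells, cohort.manifest.records):
        cm.to_csv(out_dir / f"{cm.sample_id}.csv")
        records.append(
            SampleRecord(
                sample_id=rec.sample_id,
                patient_id=rec.patient_id,
                class_label=rec.class_label,
                path=f"{cm.sample_id}.csv",
            )
        )
    CohortManifest(records=records).to_csv(out_dir / "manifest.csv")
    if cohort.panel is not None:
        cohort.panel.to_yaml(out_dir / "panel.yaml")
    if truth is not None:
        truth.to_json(out_dir / "truth.json")
    return out_dir

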