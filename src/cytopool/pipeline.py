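"""End-to-end orchestration: config, staged artifacts, provenance.

Stages run in order — load -> cluster -> featurize -> select -> classify ->
visualize — and every stage writes plain CSV/JSON artifacts plus a
``provenance.json`` carrying the config hash, master seed, and package
version, so a downstream stage (or a re-run) can verify it is consuming
artifacts from the same configuration. All randomness derives from the
single master seed; re-running a config reproduces every numeric artifact
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import CVConfig, run_cv
from .cluster import RepeatedMetaclustering, repeated_metacluster
from .diffscore import build_differentiation_map, cluster_significance, render_map
from .features import frequency_features
from .featselect import select_features
from .io import Cohort, CohortManifest, MarkerPanel, load_cohort

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries a machine-readable record."""

    def __init__(self, stage: str, cause: Exception):
        self.record = {"stage": stage, "error": type(cause).__name__, "message": str(cause)}
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Validated configuration for a full run (YAML-loadable).

    Defaults mirror a full-scale cytometry study: 1000 within-sample
    clusters, 50 metaclusters x 50 solutions, top-40 feature selection,
    500 CV iterations, 30,000-cell visualization subsample.
    """

    manifest: str = ""
    panel: str = ""
    out_dir: str = "cytopool_out"
    seed: int = 0
    k_per_sample: int = 1000
    k_prime: int = 50
    n_solutions: int = 50
    selection_enabled: bool = True
    k_nn: int = 5
    bandwidth: float | None = None
    top_m: int = 40
    cv_iterations: int = 500
    train_fraction: float = 0.5
    stratified: bool = False
    n_trials: int = 0  # >0 adds the ensemble-vs-single comparison
    viz_enabled: bool = True
    viz_n_cells: int = 30_000
    alpha: float = 1.0
    embedding: str = "tsne"
    comparison_samples: list[str] | None = None

    def __post_init__(self) -> None:
        for name, value, low in (
            ("k_per_sample", self.k_per_sample, 1),
            ("k_prime", self.k_prime, 1),
            ("n_solutions", self.n_solutions, 1),
            ("k_nn", self.k_nn, 1),
            ("top_m", self.top_m, 1),
            ("cv_iterations", self.cv_iterations, 1),
            ("viz_n_cells", self.viz_n_cells, 1),
        ):
            if value < low:
                raise ValueError(f"{name} must be >= {low}, got {value}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def clustering_hash(self) -> str:
        """Hash of only the fields that determine the clustering artifacts."""
        fields = ("manifest", "panel", "seed", "k_per_sample", "k_prime", "n_solutions")
        payload = json.dumps({f: getattr(self, f) for f in fields}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {
            "version": __version__,
            "seed": self.seed,
            "config_hash": self.config_hash(),
            "clustering_hash": self.clustering_hash(),
            "config": asdict(self),
        }


def _write_provenance(out_dir: Path, config: PipelineConfig) -> None:
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(config.provenance(), fh, indent=2)


def check_provenance(out_dir: Path, config: PipelineConfig) -> None:
    """Raise if existing artifacts come from a different configuration."""
    path = Path(out_dir) / "provenance.json"
    if not path.exists():
        raise FileNotFoundError(
            f"no provenance.json in {out_dir}; run the producing stage first"
        )
    with open(path) as fh:
        prov = json.load(fh)
    if prov.get("clustering_hash") != config.clustering_hash():
        raise ValueError(
            f"artifacts in {out_dir} were produced under clustering config "
            f"{prov.get('clustering_hash')}, current config is "
            f"{config.clustering_hash()}; re-run the cluster stage"
        )


def save_solutions(meta: RepeatedMetaclustering, out_dir: Path, channels: list[str]) -> None:
    sol_dir = out_dir / "solutions"
    sol_dir.mkdir(parents=True, exist_ok=True)
    for sol in meta.solutions:
        pd.DataFrame(sol.meta_centers, columns=channels).to_csv(
            sol_dir / f"meta_centers_iter{sol.iteration_id}.csv", index=False
        )
        rows = [
            {"sample_id": sid, "cluster": c, "metacluster": m}
            for (sid, c), m in sorted(sol.cluster_to_meta.items())
        ]
        pd.DataFrame(rows).to_csv(
            sol_dir / f"cluster_to_meta_iter{sol.iteration_id}.csv", index=False
        )


def _stage(name: str, timings: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.2fs", name, timings[name])
            return False

    return _Timer()


def run_pipeline(
    config: PipelineConfig, cohort: Cohort | None = None
) -> dict:
    """Execute every stage and persist all artifact families.

    ``cohort`` may be passed directly (e.g. a synthetic cohort held in
    memory); otherwise it is loaded from the configured manifest and panel.
    Returns the summary dict also written to ``results.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    with _stage("load", timings):
        if cohort is None:
            manifest = CohortManifest.from_csv(config.manifest)
            panel = MarkerPanel.from_yaml(config.panel)
            cohort = load_cohort(manifest, panel)
        log.info(
            "cohort: %d samples, %d cells", cohort.n_samples, cohort.total_cells
        )
    _write_provenance(out_dir, config)

    with _stage("cluster", timings):
        meta = repeated_metacluster(
            cohort.cells,
            k_per_sample=config.k_per_sample,
            k_prime=config.k_prime,
            n_solutions=config.n_solutions,
            master_seed=config.seed,
        )
        save_solutions(meta, out_dir, cohort.cells[0].channels)
        total_k = sum(sc.n_clusters for sc in next(iter(meta.clusterings.values())))
        log.info(
            "clustering: K=%d pooled clusters, P=%d metaclusters over %d solutions",
            total_k,
            meta.total_metaclusters,
            meta.n_solutions,
        )

    with _stage("featurize", timings):
        F = frequency_features(meta, sample_ids=cohort.manifest.sample_ids)
        F.to_csv(out_dir / "features.csv")

    with _stage("select", timings):
        if config.selection_enabled:
            selection = select_features(
                F, k_nn=config.k_nn, bandwidth=config.bandwidth, top_m=config.top_m
            )
            selection.to_csv(F, out_dir / "selection.csv")
            feature_cols = selection.retained_columns
        else:
            selection = None
            feature_cols = np.arange(F.n_features)

    with _stage("classify", timings):
        cv_config = CVConfig(
            n_iterations=config.cv_iterations,
            train_fraction=config.train_fraction,
            seed=config.seed,
            stratified=config.stratified,
        )
        cv = run_cv(
            F.values[:, feature_cols],
            cohort.manifest.labels,
            cohort.manifest.patient_ids,
            cv_config,
        )
        cv.to_csv(
            cohort.manifest.sample_ids, cohort.manifest.labels, out_dir / "cv_predictions.csv"
        )
        with open(out_dir / "cv_summary.json", "w") as fh:
            json.dump(
                {
                    "auroc": cv.auroc,
                    "B_requested": config.cv_iterations,
                    "B_effective": cv.n_effective_iterations,
                    "n_features": int(len(feature_cols)),
                    "seed": config.seed,
                },
                fh,
                indent=2,
            )

    comparison = None
    if config.n_trials > 0:
        with _stage("compare", timings):
            from .classify import compare_ensemble_vs_single

            comparison = compare_ensemble_vs_single(
                F,
                selection,
                cohort.manifest.labels,
                cohort.manifest.patient_ids,
                cv_config,
                n_trials=config.n_trials,
                seed=config.seed,
            )
            pd.DataFrame(
                {
                    "trial": np.arange(config.n_trials),
                    "ensemble_auc": comparison.ensemble_aucs,
                    "single_auc": comparison.single_aucs,
                }
            ).to_csv(out_dir / "ensemble_comparison.csv", index=False)

    if config.viz_enabled:
        with _stage("visualize", timings):
            sig = cluster_significance(
                F, cohort.manifest.labels, comparison_samples=config.comparison_samples
            )
            sig.to_frame().to_csv(out_dir / "cluster_significance.csv", index=False)
            dmap = build_differentiation_map(
                cohort.cells,
                meta.solutions,
                sig,
                n_cells=config.viz_n_cells,
                alpha=config.alpha,
                method=config.embedding,
                seed=config.seed,
            )
            render_map(dmap, out_dir)

    summary = {
        "auroc": cv.auroc,
        "B_effective": cv.n_effective_iterations,
        "n_samples": cohort.n_samples,
        "total_cells": cohort.total_cells,
        "P": meta.total_metaclusters,
        "n_features_used": int(len(feature_cols)),
        "runtime_s": timings,
        **config.provenance(),
    }
    if comparison is not None:
        summary["ensemble_comparison"] = comparison.summary()
    with open(out_dir / "results.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


# re-exported for CLI stage-by-stage use
__all__ += ["check_provenance", "save_solutions"]
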