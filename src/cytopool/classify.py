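"""Patient-level bootstrapped leave-group-out cross-validation.

Samples from the same patient must never straddle a train/test split, so the
unit of resampling is the patient: each of ``B`` iterations assigns a random
half of patients (and all their samples) to training, fits a classifier
(Random Forest by default), and stores class-1 probabilities for the held-out
samples. A sample's final prediction ``y*`` is the median of its stored
probabilities across all iterations in which it was held out, and AUROC of
``(y, y*)`` is the figure of merit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .cluster import derive_seed
from .featselect import SelectionResult
from .features import FrequencyMatrix

log = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "CVResult",
    "default_classifier_factory",
    "split_patients",
    "run_cv",
    "auroc",
    "EnsembleComparison",
    "compare_ensemble_vs_single",
]


def default_classifier_factory(seed: int):
    """Random Forest, 100 trees, sqrt(d) features per split."""
    return RandomForestClassifier(
        n_estimators=100, max_features="sqrt", random_state=seed, n_jobs=1
    )


@dataclass
class CVConfig:
    """Knobs for the bootstrapped cross-validation loop.

    ``classifier_factory(seed)`` must return an object with
    ``fit(X, y)`` and ``predict_proba(X)`` (class-1 probabilities in the
    second column); any probabilistic classifier satisfies the contract.
    ``stratified`` draws the training half per class (off by default: the
    splits are simple random halves of the patient list).
    """

    n_iterations: int = 500
    train_fraction: float = 0.5
    classifier_factory: Callable = field(default=default_classifier_factory)
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class CVResult:
    sample_index: np.ndarray  # indices of samples with >= 1 test appearance
    y_star: np.ndarray  # median held-out probability, aligned with sample_index
    n_test_appearances: np.ndarray  # per input sample
    auroc: float
    n_effective_iterations: int  # iterations not skipped for a one-class train set
    n_skipped_iterations: int
    # sparse record of test membership: iteration -> sample indices held out
    test_sets: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def to_frame(
        self, sample_ids: Sequence[str], labels: Sequence[int]
    ) -> pd.DataFrame:
        full_y_star = np.full(len(sample_ids), np.nan)
        full_y_star[self.sample_index] = self.y_star
        return pd.DataFrame(
            {
                "sample_id": list(sample_ids),
                "true_label": list(labels),
                "y_star": full_y_star,
                "n_test_appearances": self.n_test_appearances,
            }
        )

    def to_csv(self, sample_ids, labels, path: str | Path) -> None:
        self.to_frame(sample_ids, labels).to_csv(path, index=False)


def split_patients(
    patients: Sequence[str],
    train_fraction: float,
    rng: np.random.Generator,
    labels_by_patient: dict[str, int] | None = None,
    stratified: bool = False,
) -> tuple[set[str], set[str]]:
    """Random patient-level split; ``floor(train_fraction * n)`` to training.

    With ``stratified`` the floor rule applies within each class, which keeps
    both classes represented in imbalanced cohorts.
    """
    unique = list(dict.fromkeys(patients))
    if len(unique) < 2:
        raise ValueError("need at least 2 patients to split")
    if stratified:
        if labels_by_patient is None:
            raise ValueError("stratified split requires labels_by_patient")
        train: set[str] = set()
        for cls in sorted({labels_by_patient[p] for p in unique}):
            members = [p for p in unique if labels_by_patient[p] == cls]
            n_train = int(np.floor(train_fraction * len(members)))
            picked = rng.permutation(len(members))[:n_train]
            train.update(members[i] for i in picked)
    else:
        n_train = int(np.floor(train_fraction * len(unique)))
        picked = rng.permutation(len(unique))[:n_train]
        train = {unique[i] for i in picked}
    test = set(unique) - train
    return train, test


def auroc(y: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals P(score of a random positive > random negative) + 0.5 P(tie),
    computed from midranks so ties are handled exactly.
    """
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def run_cv(
    features: np.ndarray,
    labels: Sequence[int],
    patient_ids: Sequence[str],
    config: CVConfig,
) -> CVResult:
    """B iterations of patient-level split -> fit -> held-out prediction.

    Iterations whose training half lacks a class are skipped (and counted),
    not resampled, so ``n_iterations`` is an upper bound. Samples that never
    land in a test set are excluded from the AUROC with a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    patient_ids = list(patient_ids)
    if X.shape[0] != len(y) or len(y) != len(patient_ids):
        raise ValueError("features, labels and patient_ids must be row-aligned")
    if np.isnan(X).any():
        raise ValueError("features contain missing values")

    labels_by_patient: dict[str, int] = {}
    for pid, lab in zip(patient_ids, y):
        labels_by_patient[pid] = int(lab)

    rng = np.random.default_rng(derive_seed(config.seed, 11))
    stored: list[list[float]] = [[] for _ in range(X.shape[0])]
    test_sets: dict[int, np.ndarray] = {}
    n_skipped = 0
    for b in range(config.n_iterations):
        train_p, test_p = split_patients(
            patient_ids,
            config.train_fraction,
            rng,
            labels_by_patient=labels_by_patient,
            stratified=config.stratified,
        )
        train_mask = np.array([p in train_p for p in patient_ids])
        if len(set(y[train_mask].tolist())) < 2:
            n_skipped += 1
            continue
        clf = config.classifier_factory(derive_seed(config.seed, 12, b))
        clf.fit(X[train_mask], y[train_mask])
        test_idx = np.flatnonzero(~train_mask)
        test_sets[b] = test_idx
        probs = clf.predict_proba(X[test_idx])[:, 1]
        for i, p in zip(test_idx, probs):
            stored[i].append(float(p))
    if n_skipped:
        log.warning(
            "%d/%d CV iterations skipped: training half contained one class",
            n_skipped,
            config.n_iterations,
        )

    appearances = np.array([len(s) for s in stored], dtype=int)
    covered = np.flatnonzero(appearances > 0)
    if covered.size < len(stored):
        log.warning(
            "%d sample(s) never appeared in a test set; excluded from AUROC",
            len(stored) - covered.size,
        )
    if covered.size == 0:
        raise RuntimeError("no sample ever appeared in a test set")
    y_star = np.array([float(np.median(stored[i])) for i in covered])
    return CVResult(
        sample_index=covered,
        y_star=y_star,
        n_test_appearances=appearances,
        auroc=auroc(y[covered], y_star),
        n_effective_iterations=config.n_iterations - n_skipped,
        n_skipped_iterations=n_skipped,
        test_sets=test_sets,
    )


@dataclass
class EnsembleComparison:
    ensemble_aucs: np.ndarray
    single_aucs: np.ndarray

    def summary(self) -> dict:
        return {
            "ensemble_mean_auc": float(self.ensemble_aucs.mean()),
            "single_mean_auc": float(self.single_aucs.mean()),
            "ensemble_auc_variance": float(self.ensemble_aucs.var(ddof=1))
            if self.ensemble_aucs.size > 1
            else 0.0,
            "single_auc_variance": float(self.single_aucs.var(ddof=1))
            if self.single_aucs.size > 1
            else 0.0,
            "n_trials": int(self.ensemble_aucs.size),
        }


def compare_ensemble_vs_single(
    F: FrequencyMatrix,
    selection: SelectionResult | None,
    labels: Sequence[int],
    patient_ids: Sequence[str],
    config: CVConfig,
    n_trials: int,
    seed: int = 0,
) -> EnsembleComparison:
    """Paired AUC distributions: pooled-solution features vs single solutions.

    Per trial, the baseline arm draws one metaclustering solution at random
    and cross-validates on its (selected) feature block alone; the ensemble
    arm cross-validates on the retained features of all solutions. Both arms
    re-randomize only the CV splits between trials — the metaclustering
    solutions are fixed inputs.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    iteration_ids = F.iteration_ids
    if len(iteration_ids) < 2:
        log.warning("only one metaclustering solution; the two arms coincide")

    def cols_for(it: int) -> np.ndarray:
        if selection is None:
            return F.block_columns(it)
        return selection.retained[it]

    ensemble_cols = (
        np.sort(np.concatenate([cols_for(it) for it in iteration_ids]))
        if selection is None
        else selection.retained_columns
    )
    rng = np.random.default_rng(derive_seed(seed, 21))
    ensemble_aucs = np.empty(n_trials)
    single_aucs = np.empty(n_trials)
    for t in range(n_trials):
        trial_cfg = CVConfig(
            n_iterations=config.n_iterations,
            train_fraction=config.train_fraction,
            classifier_factory=config.classifier_factory,
            seed=derive_seed(seed, 22, t),
            stratified=config.stratified,
        )
        it = iteration_ids[int(rng.integers(len(iteration_ids)))]
        single_aucs[t] = run_cv(
            F.values[:, cols_for(it)], labels, patient_ids, trial_cfg
        ).auroc
        ensemble_aucs[t] = run_cv(
            F.values[:, ensemble_cols], labels, patient_ids, trial_cfg
        ).auroc
    return EnsembleComparison(ensemble_aucs=ensemble_aucs, single_aucs=single_aucs)
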