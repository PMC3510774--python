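"""Stratified 10-fold cross-validation and confusion-matrix metrics.

The evaluation protocol pools windows across participants, partitions
them into 10 stratified folds, holds each fold out once, and fits both
the range normalizer and the classifier on the training folds only.
Counts accumulate into a single 9×9 confusion matrix (rows = true
class, columns = predicted class, both in C1…C9 order), from which the
report derives:

* per-class recall, 100 × diagonal / row total;
* weighted average accuracy, 100 × trace / total (equivalently recall
  weighted by class prevalence);
* three confusion tallies that summarize where errors concentrate —
  among walking speeds (within C1–C3), between stair and level walking
  (C6–C9 vs C1–C3, both directions), and between brisk walking and
  jogging (C3↔C4).

A packaged reference confusion matrix — the published 9-class result of
a k-nearest-neighbor classifier on a 16-participant smartphone study,
with both accelerometer and gyroscope features — serves as the worked
example for all of these metrics, along with the published
accelerometer-only vs combined-sensor accuracy columns for the
ablation arithmetic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import gnb_fit, gnb_predict, knn_fit, knn_predict
from .features import LabeledDataset
from .io_data import CLASS_NAMES, CLASS_ORDER

logger = logging.getLogger("imuact")

__all__ = [
    "ConfusionMatrix",
    "CVConfig",
    "MetricsReport",
    "round_half_up",
    "stratified_kfold",
    "assign_folds",
    "cross_validate",
    "per_class_recall",
    "weighted_average_accuracy",
    "confusion_tallies",
    "ablation_delta",
    "load_reference_confusion",
    "load_reference_ablation",
]

_WALK_CLASSES = ("C1", "C2", "C3")
_STAIR_CLASSES = ("C6", "C7", "C8", "C9")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as printed report tables do."""
    factor = 10.0**ndigits
    return float(np.floor(abs(x) * factor + 0.5) / factor * np.sign(x)) if x else 0.0


@dataclass
class ConfusionMatrix:
    """9×9 integer counts; rows = true class, columns = predicted."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_labels(
        cls,
        true: Sequence[str],
        predicted: Sequence[str],
        classes: Sequence[str] = CLASS_ORDER,
    ) -> "ConfusionMatrix":
        classes = tuple(classes)
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(true, predicted, strict=True):
            counts[index[str(t)], index[str(p)]] += 1
        return cls(counts=counts, classes=classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("class orders differ")
        return ConfusionMatrix(self.counts + other.counts, self.classes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.classes), columns=list(self.classes)
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        frame = self.to_frame()
        frame.insert(0, "true_class", frame.index)
        frame.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        frame = pd.read_csv(path)
        classes = tuple(frame["true_class"])
        return cls(
            counts=frame[list(classes)].to_numpy(dtype=int), classes=classes
        )


def load_reference_confusion() -> ConfusionMatrix:
    """The packaged published confusion matrix (kNN, both sensors)."""
    with resources.as_file(
        resources.files("imuact.data") / "reference_confusion.csv"
    ) as path:
        return ConfusionMatrix.from_csv(path)


def load_reference_ablation() -> pd.DataFrame:
    """Published per-class accuracies: accelerometer-only vs both sensors.

    Columns ``accel_only`` and ``accel_gyro`` in percent, indexed by
    class plus a ``weighted_average`` row.
    """
    with resources.as_file(
        resources.files("imuact.data") / "reference_ablation.csv"
    ) as path:
        return pd.read_csv(path, index_col="class")


def per_class_recall(matrix: ConfusionMatrix) -> dict[str, float]:
    """100 × diagonal / row total, per class (unrounded)."""
    totals = matrix.counts.sum(axis=1)
    if np.any(totals == 0):
        empty = [c for c, t in zip(matrix.classes, totals) if t == 0]
        raise ValueError(f"empty true-class row(s): {empty}")
    diag = np.diag(matrix.counts)
    return {
        c: 100.0 * d / t for c, d, t in zip(matrix.classes, diag, totals)
    }


def weighted_average_accuracy(matrix: ConfusionMatrix) -> float:
    """100 × trace / total (unrounded)."""
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(matrix.counts)) / matrix.total


def confusion_tallies(matrix: ConfusionMatrix) -> dict[str, int]:
    """Where the errors live: walking speeds, stairs vs level, brisk vs jog."""
    if matrix.classes != CLASS_ORDER:
        raise ValueError("tallies are defined on the canonical C1..C9 matrix")
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}
    counts = matrix.counts
    walk = sum(
        counts[idx[a], idx[b]]
        for a in _WALK_CLASSES
        for b in _WALK_CLASSES
        if a != b
    )
    stair = sum(
        counts[idx[a], idx[b]] + counts[idx[b], idx[a]]
        for a in _STAIR_CLASSES
        for b in _WALK_CLASSES
    )
    brisk_jog = counts[idx["C3"], idx["C4"]] + counts[idx["C4"], idx["C3"]]
    return {
        "walking_speed": int(walk),
        "stair_vs_level": int(stair),
        "brisk_walk_vs_jog": int(brisk_jog),
    }


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol: fold count, stratification, grouping."""

    n_folds: int = 10
    stratified: bool = True
    seed: int = 0
    grouping: str = "pooled"  # or "by_participant"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.grouping not in ("pooled", "by_participant"):
            raise ValueError("grouping must be 'pooled' or 'by_participant'")


def stratified_kfold(
    labels: Sequence[str], n_folds: int = 10, seed: int = 0
) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Within each class, indices are shuffled with the seeded generator
    and dealt round-robin across folds, so per-class fold counts differ
    by at most one.
    """
    labels = np.asarray(labels, dtype=object)
    folds = np.full(len(labels), -1, dtype=int)
    rng = np.random.default_rng(seed)
    for c in sorted(set(labels.astype(str))):
        idx = np.flatnonzero(labels.astype(str) == c)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {c} has {len(idx)} rows, fewer than {n_folds} folds"
            )
        idx = rng.permutation(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def assign_folds(
    labels: Sequence[str],
    groups: Sequence[str] | None = None,
    config: CVConfig = CVConfig(),
) -> np.ndarray:
    """Fold assignment per row under the configured protocol."""
    labels = np.asarray(labels, dtype=object)
    if config.grouping == "by_participant":
        if groups is None:
            raise ValueError("by_participant grouping needs group ids")
        groups = np.asarray(groups, dtype=object)
        uniq = sorted(set(groups.astype(str)))
        if len(uniq) < config.n_folds:
            raise ValueError(
                f"{len(uniq)} participants cannot fill {config.n_folds} folds"
            )
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(len(uniq))
        group_fold = {uniq[j]: i % config.n_folds for i, j in enumerate(order)}
        return np.array([group_fold[str(g)] for g in groups], dtype=int)
    if config.stratified:
        return stratified_kfold(labels, config.n_folds, config.seed)
    rng = np.random.default_rng(config.seed)
    return rng.permutation(np.arange(len(labels)) % config.n_folds)


def cross_validate(
    dataset: LabeledDataset,
    classifier: str = "knn",
    k: int = 1,
    config: CVConfig = CVConfig(),
    folds: np.ndarray | None = None,
    normalizer_scope: str = "fold",
) -> ConfusionMatrix:
    """Hold each fold out once and accumulate one confusion matrix.

    ``normalizer_scope='fold'`` (the only sound choice) fits the range
    normalizer on the training folds only; ``'global'`` fits it once on
    the full dataset and exists solely as a leakage diagnostic.
    """
    if classifier not in ("knn", "gnb"):
        raise ValueError("classifier must be 'knn' or 'gnb'")
    if normalizer_scope not in ("fold", "global"):
        raise ValueError("normalizer_scope must be 'fold' or 'global'")
    if folds is None:
        folds = assign_folds(dataset.y, dataset.groups, config)
    folds = np.asarray(folds, dtype=int)
    if len(folds) != len(dataset):
        raise ValueError("fold assignment does not match the dataset")

    X = dataset.X
    if normalizer_scope == "global":
        from .classify import fit_normalizer, normalize

        X = normalize(X, fit_normalizer(X))

    matrix = ConfusionMatrix(np.zeros((9, 9), dtype=int))
    for f in sorted(set(folds.tolist())):
        test = folds == f
        train = ~test
        if classifier == "knn":
            if normalizer_scope == "global":
                # already normalized; an identity re-fit would rescale, so
                # run the neighbor search on the pre-normalized matrix
                from .classify import KnnModel, NormalizationParams

                params = NormalizationParams(
                    mins=np.zeros(X.shape[1]), maxs=np.ones(X.shape[1])
                )
                model = KnnModel(X=X[train], y=dataset.y[train], k=k, normalization=params)
            else:
                model = knn_fit(X[train], dataset.y[train], k=k)
            pred = knn_predict(model, X[test])
        else:
            model = gnb_fit(X[train], dataset.y[train])
            pred = gnb_predict(model, X[test])
        matrix = matrix + ConfusionMatrix.from_labels(dataset.y[test], pred)
    logger.info(
        "cross-validation (%s, %d folds): %d windows, accuracy %.1f%%",
        classifier, config.n_folds, matrix.total, weighted_average_accuracy(matrix),
    )
    return matrix


@dataclass
class MetricsReport:
    """Per-class recall, weighted accuracy, tallies, and provenance echo."""

    matrix: ConfusionMatrix
    recalls: dict[str, float]
    weighted_average: float
    tallies: dict[str, int]
    config: dict = field(default_factory=dict)

    @classmethod
    def from_matrix(
        cls, matrix: ConfusionMatrix, config: Mapping | None = None
    ) -> "MetricsReport":
        return cls(
            matrix=matrix,
            recalls=per_class_recall(matrix),
            weighted_average=weighted_average_accuracy(matrix),
            tallies=confusion_tallies(matrix),
            config=dict(config or {}),
        )

    def accuracy_table(self) -> dict[str, float]:
        """Per-class recalls plus the weighted average, rounded to 0.1."""
        table = {c: round_half_up(r) for c, r in self.recalls.items()}
        table["weighted_average"] = round_half_up(self.weighted_average)
        return table

    def to_dict(self) -> dict:
        return {
            "recalls_pct": {c: round_half_up(r) for c, r in self.recalls.items()},
            "weighted_average_pct": round_half_up(self.weighted_average),
            "tallies": self.tallies,
            "confusion_matrix": self.matrix.counts.tolist(),
            "classes": list(self.matrix.classes),
            "config": self.config,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_text(self) -> str:
        lines = ["Activity                  Accuracy"]
        for c in self.matrix.classes:
            name = f"{c}. {CLASS_NAMES.get(c, '')}"
            lines.append(f"{name:<26}{round_half_up(self.recalls[c]):.1f}%")
        lines.append(f"{'Weighted average':<26}{round_half_up(self.weighted_average):.1f}%")
        lines.append("")
        lines.append("Confusion tallies: " + ", ".join(
            f"{k}={v}" for k, v in self.tallies.items()
        ))
        return "\n".join(lines)


def ablation_delta(
    accuracies_a: Mapping[str, float], accuracies_b: Mapping[str, float]
) -> dict[str, float]:
    """Per-class (and weighted) accuracy difference b − a, to one decimal.

    ``a`` is the reduced configuration (accelerometer only), ``b`` the
    full one (accelerometer + gyroscope); positive deltas mean the
    removed component helps.
    """
    if hasattr(accuracies_a, "to_dict"):
        accuracies_a = accuracies_a.to_dict()
    if hasattr(accuracies_b, "to_dict"):
        accuracies_b = accuracies_b.to_dict()
    if set(accuracies_a) != set(accuracies_b):
        raise ValueError("mismatched class sets")
    return {
        c: round_half_up(accuracies_b[c] - accuracies_a[c]) for c in accuracies_a
    }
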