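"""Classifier evaluation: confusion counts, the five summary metrics,
ROC/AUC, and the k-fold cross-validation driver.

Metrics reported (as fractions; tables print them as percentages):

    sensitivity  TP / (TP + FN)
    specificity  TN / (TN + FP)
    F1           2 TP / (2 TP + FP + FN)
    MCC          (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TN+FN)(TP+FP))
    accuracy     (TP + TN) / n

A prediction is called positive when its score is strictly greater than
the threshold (default 0.5).  Any metric whose denominator vanishes is
reported as 0 and flagged in ``MetricsReport.warnings``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import cnn_model
from .chimera_builder import encode_batch, kfold_split
from .exceptions import ValidationError
from .sequence_io import DatasetTable

METRIC_NAMES = ("sensitivity", "specificity", "f1", "mcc", "accuracy")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    accuracy: float
    warnings: list[str] = field(default_factory=list)

    def as_percent(self, decimals: int = 2) -> dict[str, float]:
        return {
            name: round(getattr(self, name) * 100, decimals)
            for name in METRIC_NAMES
        }

    def values(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(
    labels, scores, threshold: float = 0.5
) -> ConfusionCounts:
    """Confusion counts under the strictly-greater-than decision rule."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if labels.shape != scores.shape:
        raise ValidationError(
            f"labels {labels.shape} and scores {scores.shape} differ in length"
        )
    pred = scores > threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    warnings: list[str] = []

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.append(f"{name}: zero denominator, reported as 0")
            return 0.0
        return num / den

    sen = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    spe = _ratio(c.tn, c.tn + c.fp, "specificity")
    f1 = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1")
    mcc_den = (
        (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn) * (c.tp + c.fp)
    )
    mcc = _ratio(c.tp * c.tn - c.fp * c.fn, math.sqrt(mcc_den), "mcc")
    acc = _ratio(c.tp + c.tn, c.total, "accuracy")
    return MetricsReport(sen, spe, f1, mcc, acc, warnings)


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(labels, scores) -> RocCurve:
    """ROC curve (thresholds descending, trapezoidal AUC).

    Raises if only one class is present — the curve is undefined then.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if len(np.unique(labels)) < 2:
        raise ValidationError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CvSummary:
    per_fold: list[MetricsReport]
    mean: dict[str, float]
    se: dict[str, float]  # sample standard deviation / sqrt(k)

    @property
    def k(self) -> int:
        return len(self.per_fold)


def summarize_folds(per_fold: list[MetricsReport]) -> CvSummary:
    k = len(per_fold)
    mean, se = {}, {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(r, name) for r in per_fold])
        mean[name] = float(vals.mean())
        sd = float(vals.std(ddof=1)) if k > 1 else 0.0
        se[name] = sd / math.sqrt(k)
    return CvSummary(per_fold, mean, se)


def evaluate_model(
    model: cnn_model.TrainedModel,
    table: DatasetTable,
    threshold: float = 0.5,
) -> tuple[MetricsReport, RocCurve]:
    batch = encode_batch(table)
    scores = cnn_model.predict(model, batch)
    report = metrics_from_counts(confusion(batch.labels, scores, threshold))
    roc = roc_auc(batch.labels, scores)
    return report, roc


def cross_validate(
    table: DatasetTable,
    k: int = 10,
    arch: cnn_model.ArchitectureSpec | None = None,
    config: cnn_model.TrainingConfig | None = None,
    *,
    stratify: bool = True,
    validation_fraction: float = 0.1,
    threshold: float = 0.5,
    rng: np.random.Generator | None = None,
) -> CvSummary:
    """k rounds of train-on-(k-1)-folds / test-on-held-out-fold.

    Folds are stratified by label by default so each round sees both
    classes.  A ``validation_fraction`` slice of each round's training
    portion drives early stopping.  Summary is mean +/- SE (sd/sqrt(k))
    per metric.
    """
    if arch is None:
        arch = cnn_model.build_architecture()
    if config is None:
        config = cnn_model.TrainingConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    folds = kfold_split(table, k, rng, stratify=stratify)
    for j, fold in enumerate(folds):
        if len(set(fold.labels)) < 2:
            raise ValidationError(f"fold {j} contains a single class")
    reports = []
    for j, heldout in enumerate(folds):
        train_seqs, train_labels = [], []
        for i, fold in enumerate(folds):
            if i != j:
                train_seqs.extend(fold.sequences)
                train_labels.extend(fold.labels)
        merged = DatasetTable(train_seqs, train_labels, provenance=f"cv-train-{j}")
        n_val = max(1, int(round(validation_fraction * len(merged))))
        perm = rng.permutation(len(merged))
        val = merged.subset(perm[:n_val].tolist())
        tr = merged.subset(perm[n_val:].tolist())
        model = cnn_model.train(arch, encode_batch(tr), encode_batch(val), config)
        batch = encode_batch(heldout)
        scores = cnn_model.predict(model, batch)
        reports.append(metrics_from_counts(confusion(batch.labels, scores, threshold)))
    return summarize_folds(reports)
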