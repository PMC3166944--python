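"""Confusion bookkeeping, the seven evaluation measures, k-fold CV and ROC.

Metrics are precision, recall, accuracy, specificity, F1, Matthews
correlation coefficient and false positive rate, computed from a confusion
matrix whose cells may be counts or rate-derived unit masses. Any 0/0
denominator yields 0 and is flagged as degenerate rather than raising, so
pipelines stay total. Cross-validation reports per-fold metrics with their
unweighted mean and sample (n-1) standard deviation; ROC curves from the
folds are combined by vertical averaging (mean true positive rate at fixed
false positive rates) and AUC is the trapezoid integral of the averaged
curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)

METRIC_NAMES = ("precision", "recall", "accuracy", "specificity", "f1", "mcc", "fpr")


@dataclass(frozen=True)
class ConfusionMatrix:
    """tp/fp/tn/fn cells; non-negative, at least one positive total."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion cells must be non-negative")
        if self.tp + self.fp + self.tn + self.fn <= 0:
            raise ValueError("confusion matrix must have positive total")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    accuracy: float
    specificity: float
    f1: float
    mcc: float
    fpr: float
    degenerate: frozenset = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _ratio(num: float, den: float, name: str, flags: set) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """All seven measures from one confusion matrix (0/0 -> 0, flagged)."""
    flags: set = set()
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    precision = _ratio(tp, tp + fp, "precision", flags)
    recall = _ratio(tp, tp + fn, "recall", flags)
    accuracy = _ratio(tp + tn, cm.total, "accuracy", flags)
    specificity = _ratio(tn, tn + fp, "specificity", flags)
    f1 = _ratio(2 * precision * recall, precision + recall, "f1", flags)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc", flags)
    fpr = _ratio(fp, fp + tn, "fpr", flags)
    return MetricSet(precision, recall, accuracy, specificity, f1, mcc, fpr,
                     frozenset(flags))


def confusion_from_rates(recall: float, specificity: float,
                         prevalence: float) -> ConfusionMatrix:
    """Per-unit-mass confusion matrix implied by recall/specificity.

    With balanced positive/negative test sets the prevalence is 0.5; this
    reconstructs the matrix (and thus accuracy, MCC, precision) that the
    stated recall and specificity imply.
    """
    for name, v in (("recall", recall), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return ConfusionMatrix(
        tp=prevalence * recall,
        fn=prevalence * (1.0 - recall),
        tn=(1.0 - prevalence) * specificity,
        fp=(1.0 - prevalence) * (1.0 - specificity),
    )


def confusion_from_predictions(pred: Sequence[int], gold: Sequence[int]) -> ConfusionMatrix:
    pred = np.asarray(pred, dtype=bool)
    gold = np.asarray(gold, dtype=bool)
    if pred.shape != gold.shape:
        raise ValueError("prediction/gold length mismatch")
    return ConfusionMatrix(
        tp=int(np.sum(pred & gold)),
        fp=int(np.sum(pred & ~gold)),
        tn=int(np.sum(~pred & ~gold)),
        fn=int(np.sum(~pred & gold)),
    )


# ---------------------------------------------------------------------------
# k-fold


def kfold_split(labels: Sequence[int], k: int, seed: int) -> list[np.ndarray]:
    """Stratified k-fold partition with overall fold sizes differing by <= 1.

    Items of each class are shuffled, classes are concatenated, and items
    are dealt round-robin across folds; each class occupies a contiguous
    run of the deal, so per-class and overall fold sizes both differ by at
    most one. Deterministic for a given seed.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of items ({n})")
    rng = np.random.default_rng(seed)
    order: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        order.extend(idx.tolist())
    folds: list[list[int]] = [[] for _ in range(k)]
    for j, item in enumerate(order):
        folds[j % k].append(item)
    return [np.array(sorted(f), dtype=int) for f in folds]


@dataclass
class CVResult:
    """Per-fold metrics plus their mean and sample standard deviation."""

    folds: list[MetricSet]
    mean: dict[str, float]
    sd: dict[str, float]
    fold_scores: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    skipped: int = 0


def summarize_folds(folds: Sequence[MetricSet]) -> tuple[dict, dict]:
    mean = {}
    sd = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in folds], dtype=float)
        mean[name] = float(vals.mean()) if len(vals) else float("nan")
        sd[name] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd


def cross_validate(
    X: Sequence,
    y: Sequence[int],
    fit_predict: Callable[[Sequence, np.ndarray, Sequence], tuple[np.ndarray, np.ndarray]],
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Generic k-fold CV over a fit/score callback.

    ``fit_predict(X_train, y_train, X_test)`` must return (predicted labels,
    decision scores) for the test items; any model fitting — including
    vocabulary construction — happens inside the callback, so nothing leaks
    from test folds. Folds whose training portion is single-class are
    skipped with a warning.
    """
    y = np.asarray(y, dtype=int)
    folds = kfold_split(y, k, seed)
    all_idx = np.arange(len(y))
    metrics: list[MetricSet] = []
    fold_scores: list[tuple[np.ndarray, np.ndarray]] = []
    skipped = 0
    for test_idx in folds:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        y_train = y[train_idx]
        if len(np.unique(y_train)) < 2:
            logger.warning("fold skipped: single-class training portion")
            skipped += 1
            continue
        X_train = [X[i] for i in train_idx]
        X_test = [X[i] for i in test_idx]
        pred, scores = fit_predict(X_train, y_train, X_test)
        metrics.append(compute_metrics(confusion_from_predictions(pred, y[test_idx])))
        fold_scores.append((y[test_idx].copy(), np.asarray(scores, dtype=float)))
    mean, sd = summarize_folds(metrics)
    return CVResult(folds=metrics, mean=mean, sd=sd, fold_scores=fold_scores,
                    skipped=skipped)


# ---------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class RocCurve:
    """Vertically averaged ROC: tpr at a fixed fpr grid, plus trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_vertical_average(
    fold_sets: Sequence[tuple[Sequence[int], Sequence[float]]],
    grid: np.ndarray | None = None,
) -> RocCurve:
    """Average per-fold ROC curves at fixed false positive rates.

    Each fold contributes a step ROC from its ranked decision scores (tied
    scores form one step); the true positive rate is linearly interpolated
    at every grid point and averaged across folds. Folds with a single
    label are excluded with a warning.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)
    tprs = []
    for y_true, scores in fold_sets:
        y_true = np.asarray(y_true)
        if len(np.unique(y_true)) < 2:
            logger.warning("ROC fold excluded: single label")
            continue
        fpr, tpr, _ = _sk_roc_curve(y_true, np.asarray(scores, dtype=float),
                                    drop_intermediate=False)
        # upper envelope of the step curve: one point per distinct fpr,
        # keeping the highest tpr reached there (tpr is non-decreasing)
        keep = np.r_[fpr[1:] != fpr[:-1], True]
        tprs.append(np.interp(grid, fpr[keep], tpr[keep]))
    if not tprs:
        raise ValueError("no fold with both labels")
    mean_tpr = np.mean(tprs, axis=0)
    auc = float(np.trapezoid(mean_tpr, grid))
    return RocCurve(fpr=grid, tpr=mean_tpr, auc=auc)
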