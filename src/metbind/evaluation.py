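"""Performance metrics and the cross-validation harness.

Threshold metrics are the usual confusion-matrix rates:
precision = TP/(TP+FP), recall = TP/(TP+FN),
accuracy = (TP+TN)/all, F1 = 2PR/(P+R); a zero denominator yields 0
with an explicit flag.  Threshold-free performance is summarized by
AUROC (trapezoid) and AUPRC (step interpolation), and the default
decision cutoff is the grid value maximizing F1 (F1max).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .model import MLPConfig, train_tier1


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    accuracy: float
    f1: float
    zero_division_flags: frozenset[str] = frozenset()


def confusion_from_calls(calls: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    calls = np.asarray(calls, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(calls & labels)),
        fp=int(np.sum(calls & ~labels)),
        fn=int(np.sum(~calls & labels)),
        tn=int(np.sum(~calls & ~labels)),
    )


def metrics(counts: ConfusionCounts) -> Metrics:
    flags: set[str] = set()

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.add(name)
            return 0.0
        return num / den

    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = _ratio(counts.tp, counts.tp + counts.fn, "recall")
    accuracy = _ratio(counts.tp + counts.tn, counts.total, "accuracy")
    if precision + recall == 0:
        flags.add("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(precision, recall, accuracy, f1, frozenset(flags))


# ---------------------------------------------------------------------------
# Curves


@dataclass
class Curves:
    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    pr_precision: np.ndarray
    pr_recall: np.ndarray
    pr_thresholds: np.ndarray
    auroc: float
    auprc: float


def score_curves(scores: Sequence[float], labels: Sequence[int]) -> Curves:
    """ROC and PR curves over all unique score thresholds.

    AUROC is the trapezoid area; AUPRC uses step interpolation (the sum
    of precision times recall increments), which never overstates the
    area between observed points.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    precision, recall, pr_thr = precision_recall_curve(labels, scores)
    return Curves(
        fpr=fpr,
        tpr=tpr,
        roc_thresholds=roc_thr,
        pr_precision=precision,
        pr_recall=recall,
        pr_thresholds=pr_thr,
        auroc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
    )


def f1max_cutoff(
    scores: Sequence[float],
    labels: Sequence[int],
    grid: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Grid cutoff maximizing F1 (ties -> lowest cutoff).

    Returns (cutoff, f1_at_cutoff); calls use the >= convention.  The
    default grid steps by 0.01 from 0 to 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)
    best_cut, best_f1 = None, -1.0
    for cut in grid:
        m = metrics(confusion_from_calls(scores >= cut, labels))
        if m.f1 > best_f1 + 1e-12:
            best_cut, best_f1 = float(cut), m.f1
    return best_cut, best_f1


# ---------------------------------------------------------------------------
# Cross-validation harness


@dataclass
class FoldResult:
    fold_id: int
    counts: ConfusionCounts
    metrics: Metrics
    auroc: float
    auprc: float
    n_train: int
    n_test: int


@dataclass
class EvalReport:
    folds: list[FoldResult]
    pooled_metrics: Metrics
    pooled_auroc: float
    pooled_auprc: float
    mean_auroc: float
    mean_auprc: float
    f1max: float
    f1max_cut: float
    pooled_scores: np.ndarray = field(repr=False, default=None)
    pooled_labels: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "folds": [
                {
                    "fold": f.fold_id,
                    "precision": f.metrics.precision,
                    "recall": f.metrics.recall,
                    "accuracy": f.metrics.accuracy,
                    "f1": f.metrics.f1,
                    "auroc": f.auroc,
                    "auprc": f.auprc,
                    "n_train": f.n_train,
                    "n_test": f.n_test,
                }
                for f in self.folds
            ],
            "pooled": {
                "precision": self.pooled_metrics.precision,
                "recall": self.pooled_metrics.recall,
                "accuracy": self.pooled_metrics.accuracy,
                "f1": self.pooled_metrics.f1,
                "auroc": self.pooled_auroc,
                "auprc": self.pooled_auprc,
            },
            "mean_auroc": self.mean_auroc,
            "mean_auprc": self.mean_auprc,
            "f1max": self.f1max,
            "f1max_cutoff": self.f1max_cut,
        }


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    cluster_ids: Sequence[str],
    splits: Sequence,
    config: MLPConfig,
    cutoff: float = 0.5,
) -> EvalReport:
    """Train/test once per fold at the cluster level.

    Samples enter a fold's train (test) set iff their cluster id is in
    the split's train (test) clusters, so no cluster ever leaks across
    the boundary.  Reports both per-fold metrics and metrics pooled over
    the concatenated held-out scores.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    cluster_ids = np.asarray(cluster_ids, dtype=object)
    folds: list[FoldResult] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for split in splits:
        train_mask = np.isin(cluster_ids, list(split.train_cluster_ids))
        test_mask = np.isin(cluster_ids, list(split.test_cluster_ids))
        model = train_tier1(X[train_mask], y[train_mask], config)
        scores = model.predict_scores(X[test_mask])
        labels = y[test_mask]
        counts = confusion_from_calls(scores >= cutoff, labels)
        curves = score_curves(scores, labels)
        folds.append(
            FoldResult(
                fold_id=split.fold_id,
                counts=counts,
                metrics=metrics(counts),
                auroc=curves.auroc,
                auprc=curves.auprc,
                n_train=int(train_mask.sum()),
                n_test=int(test_mask.sum()),
            )
        )
        pooled_scores.append(scores)
        pooled_labels.append(labels)
    all_scores = np.concatenate(pooled_scores)
    all_labels = np.concatenate(pooled_labels)
    pooled_counts = confusion_from_calls(all_scores >= cutoff, all_labels)
    pooled_curves = score_curves(all_scores, all_labels)
    cut, f1 = f1max_cutoff(all_scores, all_labels)
    return EvalReport(
        folds=folds,
        pooled_metrics=metrics(pooled_counts),
        pooled_auroc=pooled_curves.auroc,
        pooled_auprc=pooled_curves.auprc,
        mean_auroc=float(np.mean([f.auroc for f in folds])),
        mean_auprc=float(np.mean([f.auprc for f in folds])),
        f1max=f1,
        f1max_cut=cut,
        pooled_scores=all_scores,
        pooled_labels=all_labels,
    )
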