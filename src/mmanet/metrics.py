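"""Segmentation evaluation: dice, specificity, sensitivity, F1.

All metrics come from pixel confusion counts on hard binary masks:

    dice        = 2|A n B| / (|A| + |B|)
    specificity = TN / (TN + FP)
    sensitivity = TP / (TP + FN)
    F1          = 2 TP / (2 TP + FP + FN)

where A is the prediction support and B the ground-truth support; on hard
masks dice and F1 are the same quantity. Degenerate denominators (a class
absent from both masks) are scored 1 with a warning so per-case means stay
defined on slices lacking a tissue. Aggregation is per CASE: a case's slices
are pixel-pooled before the metric is computed, then metrics are averaged
over cases (and over folds when fold labels are supplied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "confusion_counts", "dice_score", "specificity",
           "sensitivity", "f1_score", "evaluate_cases", "MetricsReport",
           "METRIC_NAMES"]

METRIC_NAMES = ("dice", "specificity", "sensitivity", "f1")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (values in {{0,1}})")
    return arr.astype(bool)


def confusion_counts(pred_mask, gt_mask) -> ConfusionCounts:
    """Exact pixel confusion counts between two binary masks."""
    p = _check_binary(pred_mask, "pred_mask")
    g = _check_binary(gt_mask, "gt_mask")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.sum(p & g))
    tn = int(np.sum(~p & ~g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    return ConfusionCounts(tp, tn, fp, fn)


def dice_score(pred_mask, gt_mask) -> float:
    """2|A n B| / (|A| + |B|); both masks empty -> 1 by convention."""
    p = _check_binary(pred_mask, "pred_mask")
    g = _check_binary(gt_mask, "gt_mask")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(p & g)) / denom


def _ratio(num: int, denom: int, name: str) -> float:
    if denom == 0:
        warnings.warn(f"{name}: undefined (denominator 0); returning 1.0",
                      stacklevel=3)
        return 1.0
    return num / denom


def specificity(counts: ConfusionCounts) -> float:
    return _ratio(counts.tn, counts.tn + counts.fp, "specificity")


def sensitivity(counts: ConfusionCounts) -> float:
    return _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")


def f1_score(counts: ConfusionCounts) -> float:
    return _ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn, "f1")


@dataclass
class MetricsReport:
    """Per-case table plus class-level summary (Tables-style layout)."""

    per_case: pd.DataFrame     # columns: case_id, fold, class_id, metric columns
    summary: pd.DataFrame      # index: class_id; columns: metric means

    def to_csv(self, path) -> None:
        self.per_case.to_csv(path, index=False)


def _case_metrics(pred: np.ndarray, gt: np.ndarray) -> dict[str, float]:
    counts = confusion_counts(pred, gt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            "dice": dice_score(pred, gt),
            "specificity": specificity(counts),
            "sensitivity": sensitivity(counts),
            "f1": f1_score(counts),
        }


def evaluate_cases(predictions: Mapping[str, np.ndarray],
                   ground_truths: Mapping[str, np.ndarray],
                   class_ids: Sequence[int],
                   folds: Mapping[str, int] | None = None,
                   per_slice: bool = False) -> MetricsReport:
    """Per-class metrics with case-level aggregation.

    ``predictions``/``ground_truths`` map case_id to an integer mask stack
    (S, H, W) or single mask (H, W). By default all of a case's slices are
    pixel-pooled before computing that case's metrics; ``per_slice=True``
    averages slice-wise metrics within the case instead. Case means are
    averaged within each fold and fold means averaged into the summary (a
    straight case mean when no folds are given).
    """
    missing = set(ground_truths) - set(predictions)
    if missing:
        raise ValueError(f"missing predictions for cases: {sorted(missing)}")
    rows = []
    for case_id in sorted(ground_truths):
        pred = np.asarray(predictions[case_id])
        gt = np.asarray(ground_truths[case_id])
        if pred.shape != gt.shape:
            raise ValueError(f"case {case_id}: shape mismatch {pred.shape} vs {gt.shape}")
        fold = folds.get(case_id, 0) if folds else 0
        for cls in class_ids:
            pb, gb = (pred == cls).astype(int), (gt == cls).astype(int)
            if per_slice and pred.ndim == 3:
                vals = pd.DataFrame(
                    [_case_metrics(pb[i], gb[i]) for i in range(pred.shape[0])]
                ).mean().to_dict()
            else:
                vals = _case_metrics(pb, gb)
            rows.append({"case_id": case_id, "fold": fold, "class_id": cls, **vals})
    per_case = pd.DataFrame(rows)
    fold_means = per_case.groupby(["fold", "class_id"])[list(METRIC_NAMES)].mean()
    summary = fold_means.groupby("class_id").mean()
    return MetricsReport(per_case=per_case, summary=summary)
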