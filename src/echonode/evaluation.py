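"""Segmentation evaluation: confusion-count metrics, overlap measures,
and COCO-convention average precision.

Accuracy, precision and recall are the usual confusion-matrix ratios and
can be applied at pixel level (one predicted mask vs. one reference mask)
or at detection level (counts of matched instances).  Overlap between two
masks is reported both as IoU (Jaccard) and Dice, which are linked by
``dice = 2*iou / (1 + iou)``.

Average precision follows the COCO protocol: predictions sorted by
confidence, greedy matching against at most one unmatched reference per
IoU threshold, 101-point interpolated area under the precision-recall
curve, averaged over IoU thresholds 0.50:0.05:0.95 for the headline
number.  AP values are on the 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "APResult",
    "confusion_from_masks",
    "accuracy",
    "precision_recall",
    "iou_dice",
    "average_precision",
    "COCO_THRESHOLDS",
]

COCO_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))

#: COCO object-size buckets, in pixels of instance area
SIZE_BUCKETS = {"small": (0, 32**2), "medium": (32**2, 96**2), "large": (96**2, np.inf)}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise UndefinedMetricError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class APResult:
    ap: float
    ap50: float
    ap75: float
    per_threshold: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "ap": self.ap,
            "ap50": self.ap50,
            "ap75": self.ap75,
            "per_threshold": [list(x) for x in self.per_threshold],
        }


def confusion_from_masks(predicted: np.ndarray, reference: np.ndarray) -> ConfusionCounts:
    """Pixel-level confusion counts of one predicted/reference mask pair."""
    p = np.asarray(predicted, dtype=bool)
    r = np.asarray(reference, dtype=bool)
    if p.shape != r.shape:
        raise UndefinedMetricError(f"shape mismatch {p.shape} vs {r.shape}")
    return ConfusionCounts(
        tp=int((p & r).sum()),
        fp=int((p & ~r).sum()),
        tn=int((~p & ~r).sum()),
        fn=int((~p & r).sum()),
    )


def accuracy(counts: ConfusionCounts) -> float:
    """(TN + TP) / (TN + TP + FN + FP)."""
    if counts.total == 0:
        raise UndefinedMetricError("accuracy undefined on zero total count")
    return (counts.tn + counts.tp) / counts.total


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    """precision = TP/(TP+FP), recall = TP/(TP+FN)."""
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError("precision undefined: no positive prediction")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("recall undefined: no positive reference")
    return counts.tp / (counts.tp + counts.fp), counts.tp / (counts.tp + counts.fn)


def iou_dice(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Intersection-over-union (Jaccard) and Dice overlap of two masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise UndefinedMetricError(f"shape mismatch {a.shape} vs {b.shape}")
    inter = int((a & b).sum())
    union = int((a | b).sum())
    if union == 0:
        raise UndefinedMetricError("overlap undefined: both masks empty")
    iou = inter / union
    dice = 2 * inter / (int(a.sum()) + int(b.sum()))
    return iou, dice


def _interpolated_ap(tp_flags: np.ndarray, n_references: int) -> float:
    """101-point interpolated AP (fraction in [0, 1]) from per-prediction
    hit flags in confidence order."""
    if len(tp_flags) == 0:
        return 0.0
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / n_references
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope: best precision at any recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    recall_grid = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, recall_grid, side="left")
    sampled = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
    return float(sampled.mean())


def average_precision(
    predictions: list[tuple[np.ndarray, float]],
    references: list[np.ndarray],
    thresholds: tuple[float, ...] = COCO_THRESHOLDS,
) -> APResult:
    """COCO-style mask AP.

    ``predictions`` are ``(mask, confidence)`` pairs with confidences in
    [0, 1]; each reference can be matched by at most one prediction per
    IoU threshold, assigned greedily in descending confidence order to
    the unmatched reference of highest IoU.
    """
    if not references:
        raise UndefinedMetricError("AP undefined without reference instances")
    for _, conf in predictions:
        if not 0.0 <= conf <= 1.0:
            raise UndefinedMetricError(f"confidence {conf} outside [0, 1]")

    order = sorted(range(len(predictions)), key=lambda i: -predictions[i][1])
    ious = np.zeros((len(predictions), len(references)))
    for i, (pmask, _) in enumerate(predictions):
        for j, rmask in enumerate(references):
            if np.asarray(pmask, bool).any() or np.asarray(rmask, bool).any():
                ious[i, j] = iou_dice(pmask, rmask)[0]

    per_threshold = []
    for t in thresholds:
        matched: set[int] = set()
        flags = np.zeros(len(order), dtype=bool)
        for rank, i in enumerate(order):
            best_j, best_iou = -1, t
            for j in range(len(references)):
                if j in matched:
                    continue
                if ious[i, j] >= best_iou:
                    best_j, best_iou = j, ious[i, j]
            if best_j >= 0:
                matched.add(best_j)
                flags[rank] = True
        per_threshold.append((float(t), 100.0 * _interpolated_ap(flags, len(references))))

    by_t = dict(per_threshold)
    return APResult(
        ap=float(np.mean([v for _, v in per_threshold])),
        ap50=by_t.get(0.5, float("nan")),
        ap75=by_t.get(0.75, float("nan")),
        per_threshold=tuple(per_threshold),
    )
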