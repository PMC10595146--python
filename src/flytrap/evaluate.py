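"""Validation metrics and temporal detection counting.

Scalar metrics follow the standard definitions on a 2x2 confusion
tally — accuracy (TP+TN)/n, precision TP/(TP+FP), recall TP/(TP+FN) and
the F1 harmonic mean — with ROC curves built by sweeping the decision
threshold over the unique scores and AUC by trapezoidal integration
(equivalently the Mann-Whitney pairwise-concordance probability).

For trap monitoring, per-day detection quality is tracked as TP/FP/FN
series against the ground-truth fly count: detections are matched
one-to-one to annotated boxes greedily by descending overlap, matched
predictions count as TP, unmatched predictions as FP and unmatched
ground truth as FN, so tp + fn always equals the true count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .core import BoundingBox, POSITIVE_LABEL
from .classify import ClassifierBundle, ensemble_predict
from .detect import LocateConfig, SegmentConfig, extract_all_crops, locate_elements, segment_trap
from .synthgen import TrapSequence


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally of a binary classifier's decisions."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Confusion counts plus the derived scalar and ranking metrics."""

    confusion: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc: list[tuple[float, float]] | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "tp": self.confusion.tp, "tn": self.confusion.tn,
            "fp": self.confusion.fp, "fn": self.confusion.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


@dataclass(frozen=True)
class DailyCount:
    """Per-day detection tally against ground truth for one classifier."""

    date: datetime
    tp: int
    fp: int
    fn: int
    true_count: int

    def __post_init__(self) -> None:
        if self.tp + self.fn != self.true_count:
            raise ValueError("tp + fn must equal the ground-truth count")


def confusion(labels, predictions, positive=POSITIVE_LABEL) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with the declared positive class."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError(
            f"labels and predictions differ in length: {y.shape} vs {p.shape}")
    yp = y == positive
    pp = p == positive
    return ConfusionCounts(
        tp=int(np.sum(yp & pp)),
        tn=int(np.sum(~yp & ~pp)),
        fp=int(np.sum(~yp & pp)),
        fn=int(np.sum(yp & ~pp)),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0.0",
                      stacklevel=3)
        return 0.0
    return num / den


def scalar_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F1 from a confusion tally.

    Zero-denominator cases (e.g. precision with no positive predictions)
    return 0.0 with a warning, keeping daily aggregates well defined.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    accuracy = (c.tp + c.tn) / c.total
    precision = _safe_ratio(c.tp, c.tp + c.fp, "precision")
    recall = _safe_ratio(c.tp, c.tp + c.fn, "recall")
    f1 = _safe_ratio(2.0 * precision * recall, precision + recall, "f1")
    return MetricsReport(confusion=c, accuracy=accuracy, precision=precision,
                         recall=recall, f1=f1)


def roc_auc(labels, scores, positive=POSITIVE_LABEL
            ) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) from a full threshold sweep, and the AUC.

    Scores must be oriented so larger means more positive.  Requires both
    classes present; AUC is the area under the piecewise-linear curve,
    equal to the probability a random positive outscores a random
    negative (ties counting half).
    """
    y = np.asarray(labels) == positive
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def match_detections(pred_boxes: list[BoundingBox], gt_boxes: list[BoundingBox],
                     iou_threshold: float = 0.3) -> tuple[int, int, int]:
    """Greedy one-to-one box matching; returns (tp, fp, fn).

    Candidate pairs at or above the IoU threshold are matched in
    descending-overlap order, each box used at most once.  Matched
    predictions are TPs, unmatched predictions FPs, unmatched ground
    truth FNs.
    """
    pairs = []
    for i, pb in enumerate(pred_boxes):
        for j, gb in enumerate(gt_boxes):
            iou = pb.iou(gb)
            if iou >= iou_threshold:
                pairs.append((iou, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_pred: set[int] = set()
    used_gt: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_pred or j in used_gt:
            continue
        used_pred.add(i)
        used_gt.add(j)
        tp += 1
    return tp, len(pred_boxes) - tp, len(gt_boxes) - tp


def count_series(sequence: TrapSequence, bundle: ClassifierBundle,
                 segment_config: SegmentConfig = SegmentConfig(),
                 locate_config: LocateConfig = LocateConfig(),
                 iou_threshold: float = 0.3) -> dict[str, list[DailyCount]]:
    """Per-day TP/FP/FN evolution for RF-only, SVM-only and the ensemble.

    Each day is pushed through the full pipeline (segment, locate,
    classify); each model's positive boxes are matched to the annotated
    olive-fly boxes.  The true count is the number of olive flies present
    in the ground truth that day.
    """
    series: dict[str, list[DailyCount]] = {"rf": [], "svm": [], "ensemble": []}
    vote_cols = {"rf": "rf_vote", "svm": "svm_vote", "ensemble": "ensemble"}
    for image, elements in sequence.days:
        gt_boxes = [el.box for el in elements if el.label == POSITIVE_LABEL]
        mask = segment_trap(image, segment_config)
        boxes = locate_elements(image, mask, locate_config)
        votes = ensemble_predict(bundle, extract_all_crops(image, boxes)) \
            if boxes else None
        for model, col in vote_cols.items():
            if votes is None:
                pos_boxes = []
            else:
                pos_boxes = [b for b, v in zip(boxes, votes[col])
                             if v == bundle.positive_label]
            tp, fp, _ = match_detections(pos_boxes, gt_boxes, iou_threshold)
            series[model].append(DailyCount(
                date=image.timestamp, tp=tp, fp=fp,
                fn=len(gt_boxes) - tp, true_count=len(gt_boxes)))
    return series


def series_to_frame(series: dict[str, list[DailyCount]]) -> pd.DataFrame:
    """Tidy frame (date, model, tp, fp, fn, true_count) for CSV export."""
    rows = [
        {"date": dc.date, "model": model, "tp": dc.tp, "fp": dc.fp,
         "fn": dc.fn, "true_count": dc.true_count}
        for model, counts in series.items()
        for dc in counts
    ]
    return pd.DataFrame(rows)
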