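"""Bounding-box overlap geometry (IoU / CIoU) and detection metrics (AP / mAP).

Complete-IoU augments the plain overlap ratio with a normalized
center-distance penalty and an aspect-ratio similarity term:

    CIoU   = IoU - rho^2 / c^2 - alpha * v
    L_CIoU = 1 - IoU + rho^2 / c^2 + alpha * v
    v      = (4 / pi^2) * (arctan(w_gt / h_gt) - arctan(w / h))^2
    alpha  = v / (1 - IoU + v)          (alpha = 0 when v = 0)

where rho is the center distance and c the diagonal of the minimal
enclosing rectangle.  The detection metrics follow the standard
confidence-sweep construction: greedy matching of detections to ground
truth at an IoU threshold, precision P = TP/(TP+FP), recall
R = TP/(TP+FN), AP as the all-point-interpolated area under the P(R)
envelope, and mAP as the mean AP over the five face-feature classes
(face, open/closed eyes, open/closed mouth).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Box",
    "Detection",
    "CiouBreakdown",
    "PrCurve",
    "FEATURE_CLASSES",
    "iou",
    "ciou",
    "match_detections",
    "precision_recall",
    "recognition_rate",
    "pr_curve",
    "average_precision",
    "mean_average_precision",
    "evaluate_detections",
]

#: The five face-feature categories scored by the detector evaluation.
FEATURE_CLASSES = ("face", "o_eyes", "c_eyes", "o_mouth", "c_mouth")


@dataclass(frozen=True)
class Box:
    """Axis-aligned box from min/max corners; pixels, origin top-left."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)


@dataclass(frozen=True)
class Detection:
    class_id: str
    box: Box
    confidence: float

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class CiouBreakdown:
    """All intermediate terms of the CIoU computation."""

    iou: float
    rho2: float   # squared center distance (length units squared)
    c2: float     # squared enclosing-rectangle diagonal
    v: float      # aspect-ratio similarity term
    alpha: float  # weight on v
    ciou: float
    l_ciou: float


@dataclass(frozen=True)
class PrCurve:
    """Precision/recall sweep for one class.

    ``recall`` and ``precision`` are aligned with detections sorted by
    descending confidence (one point per detection); ``n_gt`` is the
    ground-truth count the recall is measured against.
    """

    recall: tuple[float, ...]
    precision: tuple[float, ...]
    tp: int
    fp: int
    fn: int
    n_gt: int


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def ciou(pred: Box, gt: Box) -> CiouBreakdown:
    """Complete-IoU breakdown between a predicted and a ground-truth box.

    The aspect term ``v`` compares the ground-truth aspect ratio with
    the prediction's, so the breakdown is not symmetric under argument
    swap (the IoU, rho^2 and c^2 terms are).
    """
    overlap = iou(pred, gt)
    (cx_p, cy_p), (cx_g, cy_g) = pred.center, gt.center
    rho2 = (cx_p - cx_g) ** 2 + (cy_p - cy_g) ** 2
    ex = max(pred.x_max, gt.x_max) - min(pred.x_min, gt.x_min)
    ey = max(pred.y_max, gt.y_max) - min(pred.y_min, gt.y_min)
    c2 = ex**2 + ey**2
    v = (4.0 / math.pi**2) * (
        math.atan(gt.width / gt.height) - math.atan(pred.width / pred.height)
    ) ** 2
    # alpha's defining ratio is 0/0 at a perfect match; take the
    # continuous limit alpha = 0 whenever v = 0.
    alpha = 0.0 if v == 0.0 else v / (1.0 - overlap + v)
    ciou_val = overlap - rho2 / c2 - alpha * v
    l_ciou = 1.0 - overlap + rho2 / c2 + alpha * v
    return CiouBreakdown(overlap, rho2, c2, v, alpha, ciou_val, l_ciou)


def match_detections(
    detections: Sequence[Detection],
    gt_boxes: Sequence[Box],
    iou_threshold: float = 0.5,
) -> tuple[list[bool], list[bool]]:
    """Greedy confidence-ordered matching within one class.

    Detections are processed in descending confidence (ties keep input
    order); each claims the unmatched ground-truth box of highest IoU,
    provided that IoU reaches ``iou_threshold``.  Returns per-detection
    TP flags (aligned with the *input* detection order) and per-gt
    matched flags; unmatched ground truths are the false negatives.
    """
    order = sorted(range(len(detections)),
                   key=lambda i: -detections[i].confidence)
    is_tp = [False] * len(detections)
    gt_matched = [False] * len(gt_boxes)
    for i in order:
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(gt_boxes):
            if gt_matched[j]:
                continue
            o = iou(detections[i].box, gt)
            if o > best_iou:
                best_j, best_iou = j, o
        if best_j >= 0 and best_iou >= iou_threshold:
            is_tp[i] = True
            gt_matched[best_j] = True
    return is_tp, gt_matched


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); zero denominators give 0 with a warning."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        warnings.warn("no positive predictions: precision defined as 0")
        p = 0.0
    else:
        p = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no ground-truth instances: recall defined as 0")
        r = 0.0
    else:
        r = tp / (tp + fn)
    return p, r


def recognition_rate(n_correct: int, n_total: int) -> float:
    """Per-class recognition accuracy: correctly identified / total instances.

    Equivalently the recall TP / (TP + FN) when every instance is either
    correctly identified or missed.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_correct <= n_total):
        raise ValueError("n_correct must lie in [0, n_total]")
    return n_correct / n_total


def pr_curve(
    detections: Sequence[Detection],
    gt_boxes: Sequence[Box],
    iou_threshold: float = 0.5,
) -> PrCurve:
    """Full confidence sweep for one class."""
    is_tp, gt_matched = match_detections(detections, gt_boxes, iou_threshold)
    order = sorted(range(len(detections)),
                   key=lambda i: -detections[i].confidence)
    n_gt = len(gt_boxes)
    recalls: list[float] = []
    precisions: list[float] = []
    tp_cum = fp_cum = 0
    for i in order:
        if is_tp[i]:
            tp_cum += 1
        else:
            fp_cum += 1
        precisions.append(tp_cum / (tp_cum + fp_cum))
        recalls.append(tp_cum / n_gt if n_gt else 0.0)
    fn = n_gt - sum(gt_matched)
    return PrCurve(tuple(recalls), tuple(precisions),
                   tp=tp_cum, fp=fp_cum, fn=fn, n_gt=n_gt)


def average_precision(curve: PrCurve) -> float:
    """All-point-interpolated area under the precision/recall envelope.

    At each recall level the envelope takes the maximum precision
    achieved at that recall or beyond; the area is the sum of envelope
    precision times recall increment.  An empty curve scores 0 with a
    warning.
    """
    if len(curve.recall) == 0:
        warnings.warn("empty precision/recall curve: AP defined as 0")
        return 0.0
    recall = np.concatenate(([0.0], np.asarray(curve.recall), [curve.recall[-1]]))
    precision = np.concatenate(([1.0], np.asarray(curve.precision), [0.0]))
    # Precision envelope: running maximum from the right.
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    dr = np.diff(recall)
    return float(np.sum(dr * envelope[1:]))


def mean_average_precision(per_class_ap: Mapping[str, float]) -> float:
    """Arithmetic mean of per-class APs (NaN entries — classes with no
    ground truth — are excluded with a warning)."""
    aps = {k: v for k, v in per_class_ap.items() if not math.isnan(v)}
    skipped = set(per_class_ap) - set(aps)
    if skipped:
        warnings.warn(
            f"classes without ground truth excluded from mAP: {sorted(skipped)}"
        )
    if not aps:
        warnings.warn("no classes with ground truth: mAP defined as 0")
        return 0.0
    return sum(aps.values()) / len(aps)


def evaluate_detections(
    detections: Sequence[Detection],
    ground_truth: Sequence[tuple[str, Box]],
    iou_threshold: float = 0.5,
    classes: Sequence[str] = FEATURE_CLASSES,
) -> tuple[dict[str, float], float]:
    """Per-class AP and mAP over a labelled detection/ground-truth set.

    ``ground_truth`` pairs each box with its class label.  Classes with
    no ground-truth instances receive AP = NaN and are excluded from the
    mean.
    """
    per_class: dict[str, float] = {}
    for cls in classes:
        dets = [d for d in detections if d.class_id == cls]
        gts = [b for c, b in ground_truth if c == cls]
        if not gts:
            per_class[cls] = math.nan
            continue
        if not dets:
            per_class[cls] = 0.0
            continue
        per_class[cls] = average_precision(pr_curve(dets, gts, iou_threshold))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m_ap = mean_average_precision(per_class)
    return per_class, m_ap
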