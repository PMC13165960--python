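"""Detection metrics: IoU, greedy confidence-ordered matching, AP/mAP@0.5
(101-point interpolation), and field error rates (missed detection and
maturity misclassification).

Rates follow the deployment accounting convention: the missed-detection rate
is unmatched ground truths over all ground truths; the maturity
misclassification rate counts predictions that localized a ground truth
(IoU ≥ threshold) but assigned the wrong stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset_pipeline import CLASS_NAMES, DetectionLabel

logger = logging.getLogger(__name__)


@dataclass
class Prediction:
    """A detector output: label fields plus a confidence score."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    confidence: float

    def corners(self):
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)


@dataclass
class MatchResult:
    """Outcome of matching one image's predictions against its ground truth."""

    is_tp: list[bool]                 # per prediction, in input order
    matched_gt: list[int | None]      # index into gts, or None
    ious: list[float]
    confidences: list[float]
    pred_classes: list[int]
    gt_matched: list[bool]            # per ground truth
    gt_classes: list[int]
    #: predictions that localized a gt (best IoU >= thresh) with wrong class
    misclassified: list[bool] = field(default_factory=list)


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two (x1, y1, x2, y2) boxes."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def match_detections(preds: list[Prediction], gts: list[DetectionLabel],
                     iou_thresh: float = 0.5) -> MatchResult:
    """Greedy matching in descending confidence.

    A prediction is a true positive iff it shares the class of, and has
    IoU >= threshold with, a not-yet-matched ground truth. Predictions that
    localize a ground truth but get the stage wrong are flagged as
    misclassifications.
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    gt_matched = [False] * len(gts)
    is_tp = [False] * len(preds)
    matched_gt: list[int | None] = [None] * len(preds)
    ious = [0.0] * len(preds)
    misclassified = [False] * len(preds)

    for i in order:
        p = preds[i]
        best_iou, best_j = 0.0, None           # class-matched candidates
        best_any_iou, best_any_j = 0.0, None   # any-class, for misclass flag
        for j, gt in enumerate(gts):
            v = iou(p.corners(), gt.corners())
            if v > best_any_iou:
                best_any_iou, best_any_j = v, j
            if gt.class_id == p.class_id and not gt_matched[j] and v > best_iou:
                best_iou, best_j = v, j
        if best_j is not None and best_iou >= iou_thresh:
            is_tp[i] = True
            matched_gt[i] = best_j
            ious[i] = best_iou
            gt_matched[best_j] = True
        elif best_any_j is not None and best_any_iou >= iou_thresh \
                and gts[best_any_j].class_id != p.class_id:
            misclassified[i] = True
            ious[i] = best_any_iou

    return MatchResult(
        is_tp=is_tp, matched_gt=matched_gt, ious=ious,
        confidences=[p.confidence for p in preds],
        pred_classes=[p.class_id for p in preds],
        gt_matched=gt_matched, gt_classes=[gt.class_id for gt in gts],
        misclassified=misclassified,
    )


def average_precision(results: list[MatchResult], class_id: int) -> float | None:
    """AP for one class over a dataset, via 101-point interpolation.

    Returns None (and logs) when the class has no ground truth.
    """
    n_gt = sum(c == class_id for r in results for c in r.gt_classes)
    if n_gt == 0:
        logger.warning("class %s has no ground truth; excluded from mAP",
                       CLASS_NAMES[class_id])
        return None
    scored = []
    for r in results:
        for conf, tp, cls in zip(r.confidences, r.is_tp, r.pred_classes):
            if cls == class_id:
                scored.append((conf, tp))
    if not scored:
        return 0.0
    scored.sort(key=lambda t: -t[0])
    tps = np.cumsum([t[1] for t in scored])
    fps = np.cumsum([not t[1] for t in scored])
    recall = tps / n_gt
    precision = tps / (tps + fps)
    return interpolated_ap(recall, precision)


def interpolated_ap(recall: np.ndarray, precision: np.ndarray) -> float:
    """101-point interpolated AP from a raw PR curve."""
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        mask = recall >= r - 1e-12
        ap += float(precision[mask].max()) if mask.any() else 0.0
    return ap / 101


def map50(results: list[MatchResult]) -> float:
    """Unweighted class-mean AP at IoU 0.5; zero-gt classes are excluded."""
    aps = [average_precision(results, c) for c in range(len(CLASS_NAMES))]
    aps = [a for a in aps if a is not None]
    if not aps:
        raise ValueError("no class has ground truth")
    return float(np.mean(aps))


def error_rates(results: list[MatchResult],
                conf_thresh: float = 0.25) -> dict[str, float]:
    """Missed-detection rate, maturity-misclassification rate, and F1.

    missed_rate
        unmatched ground truths / total ground truths.
    misclass_rate
        localized-but-wrong-stage predictions / (correctly matched +
        misclassified ground-truth associations).
    f1
        harmonic mean of precision and recall over predictions with
        confidence >= ``conf_thresh``.
    """
    n_gt = sum(len(r.gt_classes) for r in results)
    if n_gt == 0:
        raise ValueError("error rates need at least one ground truth")
    missed = sum(not m for r in results for m in r.gt_matched)
    n_misclass = sum(bool(m) for r in results for m in r.misclassified)
    n_matched = sum(bool(t) for r in results for t in r.is_tp)

    denom = n_matched + n_misclass
    if denom == 0:
        logger.warning("no matched or misclassified objects; misclass rate 0")
        misclass_rate = 0.0
    else:
        misclass_rate = n_misclass / denom

    tp = fp = 0
    for r in results:
        for conf, is_tp in zip(r.confidences, r.is_tp):
            if conf >= conf_thresh:
                tp += bool(is_tp)
                fp += not is_tp
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / n_gt
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0

    return {
        "missed_rate": missed / n_gt,
        "misclass_rate": misclass_rate,
        "f1": f1,
        "n_gt": n_gt,
        "n_missed": missed,
        "n_misclassified": n_misclass,
    }
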