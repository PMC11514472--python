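"""Detector scoring: IOU, per-class confusion matrix and trapezoid AUPRC.

Predictions are matched to ground truth greedily by descending confidence;
a match requires bounding-box IOU at or above the threshold and each truth
box is consumed at most once. The confusion matrix follows detection
practice: rows are truth categories plus a ``background`` row for false
alarms, columns are predicted categories plus a ``background`` column for
missed truths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import Box, CATEGORIES
from .errors import ParameterError

BACKGROUND = "background"


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes (general clamped form)."""
    iw = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    ih = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = iw * ih
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def _greedy_match(
    predictions: list[Box], truths: list[Box], iou_min: float
) -> list[tuple[int, int]]:
    """(prediction index, truth index) pairs, score-ordered, one-to-one."""
    order = sorted(
        range(len(predictions)), key=lambda i: (-predictions[i].score, i)
    )
    taken: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for pi in order:
        best_t, best_iou = -1, iou_min
        for ti, truth in enumerate(truths):
            if ti in taken:
                continue
            o = iou(predictions[pi], truth)
            if o > best_iou or (o == best_iou and best_t == -1 and o >= iou_min):
                best_t, best_iou = ti, o
        if best_t >= 0:
            taken.add(best_t)
            pairs.append((pi, best_t))
    return pairs


def confusion_matrix(
    predictions: list[Box], truths: list[Box], iou_min: float = 0.5
) -> pd.DataFrame:
    """Category confusion counts under greedy score-ordered matching.

    ``matrix.loc[t, p]`` counts truths of category ``t`` matched by a
    prediction of category ``p``; unmatched truths land in the background
    column and unmatched predictions in the background row.
    """
    if not 0.0 < iou_min <= 1.0:
        raise ParameterError("iou_min must lie in (0, 1]")
    labels = list(CATEGORIES) + [BACKGROUND]
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    pairs = _greedy_match(predictions, truths, iou_min)
    matched_p = {pi for pi, _ in pairs}
    matched_t = {ti for _, ti in pairs}
    for pi, ti in pairs:
        mat.loc[truths[ti].category, predictions[pi].category] += 1
    for ti, truth in enumerate(truths):
        if ti not in matched_t:
            mat.loc[truth.category, BACKGROUND] += 1
    for pi, pred in enumerate(predictions):
        if pi not in matched_p:
            mat.loc[BACKGROUND, pred.category] += 1
    return mat


@dataclass
class PRCurve:
    """(recall, precision) pairs with non-decreasing recall."""

    points: list[tuple[float, float]]
    iou_min: float = 0.5

    def __post_init__(self):
        recalls = [r for r, _p in self.points]
        if any(b < a for a, b in zip(recalls, recalls[1:])):
            raise ParameterError("recall must be non-decreasing along the curve")


def pr_curve(
    predictions: list[Box],
    truths: list[Box],
    category: str,
    iou_min: float = 0.5,
) -> PRCurve:
    """Precision–recall pairs for one category, sweeping the score threshold.

    The sweep visits every distinct prediction score from high to low; the
    curve is anchored at recall 0 with the precision of the first point.
    """
    preds = [p for p in predictions if p.category == category]
    gts = [t for t in truths if t.category == category]
    if not gts:
        raise ParameterError(f"no ground-truth boxes of category {category!r}")
    thresholds = sorted({p.score for p in preds}, reverse=True)
    points: list[tuple[float, float]] = []
    for thr in thresholds:
        kept = [p for p in preds if p.score >= thr]
        pairs = _greedy_match(kept, gts, iou_min)
        tp = len(pairs)
        precision = tp / len(kept) if kept else 1.0
        recall = tp / len(gts)
        points.append((recall, precision))
    if not points:
        points = [(0.0, 1.0)]
    points.insert(0, (0.0, points[0][1]))
    return PRCurve(points, iou_min)


def auprc(curve: PRCurve) -> float:
    """Composite trapezoid area under the precision–recall curve."""
    pts = curve.points
    if len(pts) < 2:
        raise ParameterError("need at least two (recall, precision) points")
    area = 0.0
    for (r0, p0), (r1, p1) in zip(pts, pts[1:]):
        area += (p0 + p1) / 2.0 * (r1 - r0)
    return area


def evaluate_detector(
    predictions: list[Box],
    truths: list[Box],
    iou_thresholds: tuple[float, ...] = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2)),
) -> dict:
    """Per-class AUPRC across IOU thresholds plus the 0.5-IOU confusion matrix."""
    out: dict = {"auprc": {}, "pr_points": {}, "confusion": None}
    present = sorted({t.category for t in truths})
    for cat in present:
        out["auprc"][cat] = {}
        for thr in iou_thresholds:
            curve = pr_curve(predictions, truths, cat, float(thr))
            out["auprc"][cat][float(thr)] = auprc(curve)
            if abs(thr - 0.5) < 1e-12:
                out["pr_points"][cat] = curve.points
    cm = confusion_matrix(predictions, truths, 0.5)
    out["confusion"] = cm
    return out
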