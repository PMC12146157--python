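"""Detection evaluation: matching, P/R/AP/mAP, count errors, region overlap.

Matching is the standard greedy one-to-one protocol: predictions are
visited in descending confidence and claim the unmatched same-class
ground-truth box of highest IoU above the threshold.  AP integrates the
precision-recall curve either with the 101-point interpolation and the
monotone precision envelope (the dominant convention, the default) or
as the exact staircase over ranking prefixes (used by oracle tests).

Count/area agreement between predictions and annotations is summarised
by MAPE (mean absolute percentage error) and RMSE; region agreement by
Dice and IoU over rasterized per-class box unions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .boxgeom import CLASS_NAMES, BoundingBox, iou

__all__ = [
    "MatchResult", "EvalReport", "match_detections", "precision_recall",
    "average_precision", "mean_ap", "regression_errors", "overlap_scores",
    "COCO_THRESHOLDS", "evaluate_detections",
]

#: the ten IoU thresholds 0.50, 0.55, ..., 0.95
COCO_THRESHOLDS = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


@dataclass
class MatchResult:
    """Outcome of greedy matching at one IoU threshold (all classes pooled
    per the caller's grouping)."""

    tp: int
    fp: int
    fn: int
    pairs: list = field(default_factory=list)   # (pred_idx, gt_idx, iou)


def _sort_by_confidence(preds: list[BoundingBox]) -> list[int]:
    # descending confidence, ties broken by original index (stable)
    return sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, i))


def match_detections(preds: list[BoundingBox], gts: list[BoundingBox],
                     iou_threshold: float) -> MatchResult:
    """Greedy one-to-one matching in descending confidence order.

    A prediction matches the unmatched ground-truth box of the same
    class with the highest IoU >= threshold; IoU ties are broken by
    ground-truth index.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must lie in (0, 1]")
    taken = [False] * len(gts)
    pairs = []
    for pi in _sort_by_confidence(preds):
        p = preds[pi]
        best_iou, best_gi = 0.0, -1
        for gi, g in enumerate(gts):
            if taken[gi] or g.class_id != p.class_id:
                continue
            o = iou(p, g)
            if o >= iou_threshold and o > best_iou:
                best_iou, best_gi = o, gi
        if best_gi >= 0:
            taken[best_gi] = True
            pairs.append((pi, best_gi, best_iou))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(preds) - tp, fn=len(gts) - tp, pairs=pairs)


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); 0 when the denominator is 0."""
    p = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else 0.0
    r = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else 0.0
    return p, r


def _tp_flags(preds, gts, iou_threshold):
    """Confidence-ranked TP/FP flags via the greedy matching above."""
    order = _sort_by_confidence(preds)
    matched = {pi for pi, _, _ in
               match_detections(preds, gts, iou_threshold).pairs}
    return np.array([pi in matched for pi in order], dtype=bool)


def average_precision(preds: list[BoundingBox], gts: list[BoundingBox],
                      iou_threshold: float,
                      interpolation: str = "101") -> float:
    """Area under the precision-recall curve for one class.

    ``interpolation="101"`` samples the monotone precision envelope at
    101 recall points; ``"exact"`` integrates the raw staircase over
    every ranking prefix.  Raises on zero ground-truth boxes (the class
    carries no recall axis).
    """
    if not gts:
        raise ValueError("average_precision undefined with zero gt boxes")
    if not preds:
        return 0.0
    flags = _tp_flags(preds, gts, iou_threshold)
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / len(gts)
    precision = tp_cum / (tp_cum + fp_cum)
    if interpolation == "exact":
        prev_r = 0.0
        ap = 0.0
        for p, r, is_tp in zip(precision, recall, flags):
            if is_tp:
                ap += (r - prev_r) * p
                prev_r = r
        return float(ap)
    if interpolation == "101":
        # monotone envelope then 101-point sampling
        env = np.maximum.accumulate(precision[::-1])[::-1]
        pts = np.linspace(0.0, 1.0, 101)
        idx = np.searchsorted(recall, pts, side="left")
        sampled = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
        return float(sampled.mean())
    raise ValueError(f"unknown interpolation {interpolation!r}")


def _per_class(boxes):
    out = {}
    for b in boxes:
        out.setdefault(b.class_id, []).append(b)
    return out


def mean_ap(preds: list[BoundingBox], gts: list[BoundingBox],
            thresholds=(0.5,), interpolation: str = "101") -> float:
    """Mean AP over classes (with gt present) and IoU thresholds."""
    gt_by_class = _per_class(gts)
    if not gt_by_class:
        raise ValueError("mean_ap needs at least one class with gt boxes")
    pred_by_class = _per_class(preds)
    aps = []
    for cid, class_gts in gt_by_class.items():
        class_preds = pred_by_class.get(cid, [])
        aps.append(np.mean([
            average_precision(class_preds, class_gts, t, interpolation)
            for t in thresholds]))
    return float(np.mean(aps))


def regression_errors(actual, predicted) -> tuple[float, float]:
    """(MAPE in percent, RMSE) between paired scalar summaries.

    Entries with a zero actual value are excluded from MAPE (with a
    warning); RMSE uses all entries.
    """
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size == 0:
        raise ValueError("regression_errors needs at least one pair")
    if y.shape != yhat.shape:
        raise ValueError("actual and predicted must have the same length")
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    nz = y != 0
    if not np.all(nz):
        warnings.warn("excluding zero-valued actual entries from MAPE",
                      stacklevel=2)
    if not np.any(nz):
        return 0.0, rmse
    mape = float(np.mean(np.abs((y[nz] - yhat[nz]) / y[nz])) * 100.0)
    return mape, rmse


def _rasterize(boxes, image_size) -> np.ndarray:
    h, w = image_size
    mask = np.zeros((h, w), dtype=bool)
    for b in boxes:
        x1 = max(0, int(np.floor(b.x1)))
        y1 = max(0, int(np.floor(b.y1)))
        x2 = min(w, int(np.ceil(b.x2)))
        y2 = min(h, int(np.ceil(b.y2)))
        if x2 > x1 and y2 > y1:
            mask[y1:y2, x1:x2] = True
    return mask


def overlap_scores(pred_boxes: list[BoundingBox], gt_boxes: list[BoundingBox],
                   image_size) -> tuple[float, float]:
    """Class-mean Dice and IoU of rasterized box-union masks.

    Per class the union of predicted boxes and the union of ground
    truth boxes are painted into binary masks; classes where both
    masks are empty are skipped.
    """
    h, w = image_size
    if h <= 0 or w <= 0:
        raise ValueError("image_size must be positive")
    preds_c = _per_class(pred_boxes)
    gts_c = _per_class(gt_boxes)
    dices, ious = [], []
    for cid in sorted(set(preds_c) | set(gts_c)):
        a = _rasterize(preds_c.get(cid, []), image_size)
        b = _rasterize(gts_c.get(cid, []), image_size)
        sa, sb = int(a.sum()), int(b.sum())
        if sa == 0 and sb == 0:
            continue
        inter = int((a & b).sum())
        union = sa + sb - inter
        dices.append(2.0 * inter / (sa + sb))
        ious.append(inter / union)
    if not dices:
        raise ValueError("no non-empty mask pair to score")
    return float(np.mean(dices)), float(np.mean(ious))


@dataclass
class EvalReport:
    """Per-class and aggregate detection metrics."""

    per_class: dict          # name -> {precision, recall, ap50, ap50_95}
    map50: float
    map50_95: float
    dice: float | None = None
    iou_region: float | None = None
    count_mape: float | None = None
    count_rmse: float | None = None
    area_mape: float | None = None
    area_rmse: float | None = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=float)

    def to_table(self) -> str:
        """Aligned text table: one row per class plus the aggregate."""
        header = f"{'class':>8} {'P':>7} {'R':>7} {'mAP@.5':>8} {'mAP@.5:.95':>11}"
        lines = [header]
        for name, row in self.per_class.items():
            lines.append(f"{name:>8} {row['precision']:>7.3f} "
                         f"{row['recall']:>7.3f} {row['ap50']:>8.3f} "
                         f"{row['ap50_95']:>11.3f}")
        lines.append(f"{'all':>8} {'':>7} {'':>7} {self.map50:>8.3f} "
                     f"{self.map50_95:>11.3f}")
        return "\n".join(lines)


def evaluate_detections(preds: list[BoundingBox], gts: list[BoundingBox],
                        image_size=None,
                        per_image_counts=None,
                        class_names=CLASS_NAMES) -> EvalReport:
    """Full evaluation of pooled predictions against pooled ground truth.

    ``class_names`` maps class ids to report row names (models trained
    on a class subset re-index from 0).  ``per_image_counts``, when
    given, is a pair of sequences (actual, predicted) per image for the
    count MAPE/RMSE.
    """
    gt_by_class = _per_class(gts)
    pred_by_class = _per_class(preds)
    skipped = [cid for cid in pred_by_class if cid not in gt_by_class]
    if skipped:
        warnings.warn(
            f"classes without gt excluded from mAP: {[class_names[c] for c in skipped]}",
            stacklevel=2)
    per_class = {}
    ap50s, ap5095s = [], []
    for cid, class_gts in sorted(gt_by_class.items()):
        class_preds = pred_by_class.get(cid, [])
        m = match_detections(class_preds, class_gts, 0.5)
        p, r = precision_recall(m)
        ap50 = average_precision(class_preds, class_gts, 0.5)
        ap5095 = float(np.mean([
            average_precision(class_preds, class_gts, t)
            for t in COCO_THRESHOLDS]))
        per_class[class_names[cid]] = {
            "precision": p, "recall": r, "ap50": ap50, "ap50_95": ap5095,
        }
        ap50s.append(ap50)
        ap5095s.append(ap5095)
    report = EvalReport(per_class=per_class,
                        map50=float(np.mean(ap50s)),
                        map50_95=float(np.mean(ap5095s)))
    if image_size is not None:
        try:
            report.dice, report.iou_region = overlap_scores(preds, gts, image_size)
        except ValueError:
            pass
    if per_image_counts is not None:
        actual, predicted = per_image_counts
        report.count_mape, report.count_rmse = regression_errors(actual, predicted)
    return report
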