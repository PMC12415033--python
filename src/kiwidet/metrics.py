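"""Detection evaluation: greedy matching, precision/recall, AP and
mAP@50 / mAP@50-95.

AP is the area under the precision envelope as a function of recall,
evaluated by 101-point interpolation (recall grid 0, 0.01, ..., 1);
`method="all_points"` integrates the exact envelope instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .losses import iou_xyxy

__all__ = ["Detection", "PRCurve", "match_detections", "average_precision",
           "mean_ap", "COCO_THRESHOLDS"]

COCO_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class Detection:
    box: np.ndarray          # xyxy, input pixels
    confidence: float
    class_id: int = 0
    image_id: str | int = 0

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")


@dataclass(frozen=True)
class PRCurve:
    """Confidence-ranked (confidence, is_tp) record plus the ground-truth
    count the recall axis is measured against."""
    pairs: tuple             # ((conf, is_tp), ...) sorted by conf desc
    n_ground_truth: int


def match_detections(dets: list[Detection], gts: dict, iou_threshold: float = 0.5):
    """Greedy one-to-one matching in confidence order.

    `gts` maps image_id -> list of (box_xyxy, class_id). A detection is
    a TP iff it overlaps an unmatched same-class ground truth at
    IoU >= threshold; each ground truth matches at most once. Ties in
    confidence are broken by insertion order (stable sort).

    Returns (labeled, n_gt) where labeled is [(det, is_tp), ...] in
    rank order.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    used = {img: np.zeros(len(v), bool) for img, v in gts.items()}
    labeled = []
    for i in order:
        d = dets[i]
        cand = gts.get(d.image_id, [])
        best, best_iou = -1, iou_threshold
        for j, (gb, gc) in enumerate(cand):
            if gc != d.class_id or used[d.image_id][j]:
                continue
            v = iou_xyxy(d.box, gb)
            if v >= best_iou:
                best, best_iou = j, v
        if best >= 0:
            used[d.image_id][best] = True
            labeled.append((d, True))
        else:
            labeled.append((d, False))
    n_gt = sum(len(v) for v in gts.values())
    return labeled, n_gt


def curve_from_matches(labeled, n_gt: int) -> PRCurve:
    return PRCurve(tuple((d.confidence, tp) for d, tp in labeled), n_gt)


def average_precision(curve: PRCurve, method: str = "interp101") -> float:
    """Area under the precision envelope vs recall."""
    if curve.n_ground_truth <= 0:
        raise ValueError("AP is undefined with zero ground-truth objects")
    if not curve.pairs:
        return 0.0
    tp = np.array([p[1] for p in curve.pairs], np.float64)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1 - tp)
    recall = cum_tp / curve.n_ground_truth
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope (monotone non-increasing in recall)
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if method == "interp101":
        grid = np.linspace(0, 1, 101)
        # epsilon guards float drift when a recall hits a grid point exactly
        idx = np.searchsorted(recall, grid - 1e-12, side="left")
        vals = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
        return float(vals.mean())
    if method == "all_points":
        r = np.concatenate([[0.0], recall])
        e = np.concatenate([env[:1] if len(env) else [0.0], env])
        return float(np.sum((r[1:] - r[:-1]) * e[1:]))
    raise ValueError(f"unknown AP method {method!r}")


def precision_recall_at(labeled, n_gt: int, conf_threshold: float = 0.25):
    """Operating-point precision/recall at a confidence threshold."""
    kept = [(d, tp) for d, tp in labeled if d.confidence >= conf_threshold]
    tp = sum(1 for _, t in kept if t)
    fp = len(kept) - tp
    p = tp / (tp + fp) if kept else 0.0
    r = tp / n_gt if n_gt else 0.0
    return p, r


def mean_ap(dets: list[Detection], gts: dict, thresholds=COCO_THRESHOLDS,
            conf_threshold: float = 0.25, method: str = "interp101") -> dict:
    """mAP@50 and mAP@50-95 (mean over classes, then thresholds), plus
    the operating-point precision/recall at IoU 0.5.

    `gts` maps image_id -> list of (box_xyxy, class_id); raises on an
    empty ground-truth set.
    """
    n_gt_total = sum(len(v) for v in gts.values())
    if n_gt_total == 0:
        raise ValueError("no ground-truth objects to evaluate against")
    classes = sorted({c for v in gts.values() for _, c in v})
    ap_per_thr = {}
    for t in thresholds:
        aps = []
        for c in classes:
            cd = [d for d in dets if d.class_id == c]
            cg = {img: [(b, cc) for b, cc in v if cc == c] for img, v in gts.items()}
            if sum(len(v) for v in cg.values()) == 0:
                continue
            labeled, n_gt = match_detections(cd, cg, t)
            aps.append(average_precision(curve_from_matches(labeled, n_gt), method))
        ap_per_thr[t] = float(np.mean(aps)) if aps else 0.0
    labeled, n_gt = match_detections(dets, gts, 0.5)
    p, r = precision_recall_at(labeled, n_gt, conf_threshold)
    map50 = ap_per_thr.get(0.5, ap_per_thr[min(ap_per_thr)])
    return {"map50": map50,
            "map5095": float(np.mean(list(ap_per_thr.values()))),
            "precision": p, "recall": r,
            "conf_threshold": conf_threshold,
            "ap_per_threshold": {float(k): v for k, v in ap_per_thr.items()}}
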