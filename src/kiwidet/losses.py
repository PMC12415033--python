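"""Bounding-box regression losses and the detection training criterion.

Six IoU-family losses are provided (GIoU, DIoU, CIoU, EIoU, SIoU,
MPDIoU). MPDIoU augments 1 - IoU with the squared distances between
corresponding top-left and bottom-right corners of the predicted and
ground-truth boxes, normalised by the squared image diagonal
(h^2 + w^2). Unlike CIoU's aspect-ratio term — which vanishes whenever
the two boxes share centre and aspect ratio regardless of a size
mismatch — the corner distances vanish only at exact coincidence.

All loss kernels run on autograd tensors, so the same code path serves
scalar oracle checks and batched training. `DetectionLoss` is the full
criterion of the dual-branch head: task-aligned assignment,
binary-cross-entropy classification, the selected IoU-family box term
and a distribution-focal term on the discretised box sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.head import decode_boxes, make_anchors

IOU_KINDS = ("iou", "giou", "diou", "ciou", "eiou", "siou", "mpdiou")
EPS = 1e-9


@dataclass(frozen=True)
class BoxXYXY:
    """Absolute-corner box: top-left (x1, y1), bottom-right (x2, y2)."""
    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if self.x2 < self.x1 or self.y2 < self.y1:
            raise ValueError(f"degenerate box: {self}")

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], np.float32)


@dataclass(frozen=True)
class ImageExtent:
    """Width/height (pixels) of the image containing the boxes."""
    w: float
    h: float

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError("image extent must be positive")


def _t(x) -> Tensor:
    if isinstance(x, BoxXYXY):
        return Tensor(x.as_array().reshape(1, 4))
    if isinstance(x, Tensor):
        return x
    a = np.asarray(x, np.float32)
    return Tensor(a.reshape(1, 4) if a.ndim == 1 else a)


def _maximum(a, b):
    return a + (b - a).clamp_min(0.0)


def _minimum(a, b):
    return a - (a - b).clamp_min(0.0)


def _iou_parts(p: Tensor, g: Tensor):
    px1, py1, px2, py2 = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    gx1, gy1, gx2, gy2 = g[:, 0], g[:, 1], g[:, 2], g[:, 3]
    iw = (_minimum(px2, gx2) - _maximum(px1, gx1)).clamp_min(0.0)
    ih = (_minimum(py2, gy2) - _maximum(py1, gy1)).clamp_min(0.0)
    inter = iw * ih
    area_p = (px2 - px1) * (py2 - py1)
    area_g = (gx2 - gx1) * (gy2 - gy1)
    union = area_p + area_g - inter
    iou = inter / (union + EPS)
    return iou, union


def iou_xyxy(a, b) -> float:
    """Plain intersection-over-union of two boxes (0 for a zero-area union)."""
    v, union = _iou_parts(_t(a), _t(b))
    return 0.0 if float(union.data[0]) <= 0 else float(v.data[0])


# alias used throughout the package
iou = iou_xyxy


def iou_family_loss(kind: str, pred, gt, extent: ImageExtent | tuple | None = None) -> Tensor:
    """Elementwise box-regression loss, shape (N,).

    `pred` may be an autograd tensor (gradients flow); `gt` and the
    extent are treated as constants. All kinds reduce to ``1 - IoU``
    plus a non-negative penalty and are exactly zero on coincident
    boxes.
    """
    if kind not in IOU_KINDS:
        raise ValueError(f"unknown box loss {kind!r}; choose from {IOU_KINDS}")
    p, g = _t(pred), _t(gt)
    iou_v, _ = _iou_parts(p, g)
    px1, py1, px2, py2 = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    gx1, gy1, gx2, gy2 = g[:, 0], g[:, 1], g[:, 2], g[:, 3]

    if kind == "iou":
        return 1.0 - iou_v

    if kind == "mpdiou":
        if extent is None:
            raise ValueError("mpdiou requires the image extent")
        if isinstance(extent, ImageExtent):
            w, h = extent.w, extent.h
        else:
            w, h = extent
        if w <= 0 or h <= 0:
            raise ValueError("image extent must be positive")
        d1 = (px1 - gx1) ** 2 + (py1 - gy1) ** 2
        d2 = (px2 - gx2) ** 2 + (py2 - gy2) ** 2
        return 1.0 - iou_v + (d1 + d2) * (1.0 / (h * h + w * w))

    # enclosing box, shared by the remaining kinds
    cw = _maximum(px2, gx2) - _minimum(px1, gx1)
    ch = _maximum(py2, gy2) - _minimum(py1, gy1)

    if kind == "giou":
        _, union = _iou_parts(p, g)
        c_area = cw * ch
        return 1.0 - iou_v + (c_area - union) / (c_area + EPS)

    c2 = cw ** 2 + ch ** 2 + EPS
    dcx = (gx1 + gx2 - px1 - px2) * 0.5
    dcy = (gy1 + gy2 - py1 - py2) * 0.5
    rho2 = dcx ** 2 + dcy ** 2

    if kind == "diou":
        return 1.0 - iou_v + rho2 / c2

    pw, ph = px2 - px1, py2 - py1
    gw, gh = gx2 - gx1, gy2 - gy1

    if kind == "ciou":
        v = (4.0 / math.pi ** 2) * ((gw / (gh + EPS)).arctan()
                                    - (pw / (ph + EPS)).arctan()) ** 2
        alpha = Tensor(v.data / (1.0 - iou_v.data + v.data + EPS))  # no grad
        return 1.0 - iou_v + rho2 / c2 + alpha * v

    if kind == "eiou":
        return (1.0 - iou_v + rho2 / c2
                + (pw - gw) ** 2 / (cw ** 2 + EPS)
                + (ph - gh) ** 2 / (ch ** 2 + EPS))

    # siou: angle-aware distance cost plus shape cost
    sigma = (dcx ** 2 + dcy ** 2 + EPS) ** 0.5
    sin_a = dcy.abs() / sigma
    sin_b = dcx.abs() / sigma
    thr = 2 ** 0.5 / 2
    use_b = (sin_a.data > thr).astype(np.float32)  # constant selector
    sin_alpha = sin_a * (1.0 - use_b) + sin_b * use_b
    angle_cost = 2.0 * sin_alpha * (1.0 - sin_alpha ** 2).clamp_min(0.0) ** 0.5
    gamma = 2.0 - angle_cost
    rho_x = (dcx / (cw + EPS)) ** 2
    rho_y = (dcy / (ch + EPS)) ** 2
    dist_cost = 2.0 - (-1.0 * gamma * rho_x).exp() - (-1.0 * gamma * rho_y).exp()
    om_w = (pw - gw).abs() / (_maximum(pw, gw) + EPS)
    om_h = (ph - gh).abs() / (_maximum(ph, gh) + EPS)
    shape_cost = (1.0 - (-1.0 * om_w).exp()) ** 4 + (1.0 - (-1.0 * om_h).exp()) ** 4
    return 1.0 - iou_v + 0.5 * (dist_cost + shape_cost)


def mpdiou_loss(pred, gt, extent) -> float | Tensor:
    """Minimum-point-distance IoU loss; scalar for plain box inputs,
    elementwise tensor for batched tensors."""
    out = iou_family_loss("mpdiou", pred, gt, extent)
    if isinstance(pred, (BoxXYXY, list, tuple, np.ndarray)) and not isinstance(pred, Tensor):
        return float(out.data[0]) if out.data.size == 1 else out.data
    return out


def mpdiou_grad(pred: np.ndarray, gt: np.ndarray, extent) -> np.ndarray:
    """Analytic gradient of the MPDIoU loss w.r.t. the predicted corners."""
    p = Tensor(np.asarray(pred, np.float32).reshape(1, 4), requires_grad=True)
    loss = iou_family_loss("mpdiou", p, gt, extent)
    loss.sum().backward()
    return p.grad.reshape(4).copy()


# --------------------------------------------------------------------
# training criterion

def _pairwise_iou_np(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(N,4) x (M,4) IoU matrix (NumPy, no grad)."""
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    aa = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    ab = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (aa[:, None] + ab[None, :] - inter + EPS)


def task_aligned_assign(scores, boxes, anchors, gt_boxes, gt_cls, topk,
                        alpha=0.5, beta=6.0):
    """Task-aligned label assignment for one image (no gradients).

    Returns fg mask (A,), per-anchor gt index, and the per-anchor
    soft classification targets (A, nc).
    """
    a, nc = scores.shape
    m = len(gt_boxes)
    if m == 0:
        return np.zeros(a, bool), np.zeros(a, np.int64), np.zeros((a, nc), np.float32)
    inside = ((anchors[:, None, 0] > gt_boxes[None, :, 0])
              & (anchors[:, None, 0] < gt_boxes[None, :, 2])
              & (anchors[:, None, 1] > gt_boxes[None, :, 1])
              & (anchors[:, None, 1] < gt_boxes[None, :, 3]))  # (A, M)
    ious = _pairwise_iou_np(boxes, gt_boxes)                    # (A, M)
    cls_score = scores[:, gt_cls]                               # (A, M)
    metric = (cls_score ** alpha) * (ious ** beta) * inside
    # top-k anchors per gt
    k = min(topk, a)
    cand = np.zeros_like(inside)
    top = np.argsort(-metric, axis=0, kind="stable")[:k]        # (k, M)
    cand[top, np.arange(m)[None, :]] = metric[top, np.arange(m)[None, :]] > 0
    # resolve anchors claimed by several gts: keep highest metric
    claimed = cand.sum(axis=1)
    conflict = claimed > 1
    if conflict.any():
        best = metric.argmax(axis=1)
        fix = np.zeros_like(cand)
        fix[np.arange(a), best] = True
        cand[conflict] = fix[conflict]
    fg = cand.any(axis=1)
    tgt_idx = np.where(fg, cand.argmax(axis=1), 0)
    # normalised soft targets: metric scaled into each gt's best IoU
    pos_metric = metric * cand
    max_metric = pos_metric.max(axis=0) + EPS                   # (M,)
    max_iou = (ious * cand).max(axis=0)                         # (M,)
    norm = pos_metric * (max_iou / max_metric)[None, :]         # (A, M)
    tscores = np.zeros((a, nc), np.float32)
    fg_idx = np.nonzero(fg)[0]
    tscores[fg_idx, gt_cls[tgt_idx[fg_idx]]] = norm[fg_idx, tgt_idx[fg_idx]]
    return fg, tgt_idx, tscores


class DetectionLoss:
    """Total detection loss over both head branches.

    components: box (selected IoU-family loss on decoded boxes),
    cls (BCE against task-aligned soft targets), dfl (distribution
    focal regression of the discretised box sides).
    """

    def __init__(self, nc, strides=(8, 16, 32), reg_max=16, box_loss="mpdiou",
                 extent=(640, 640), gains=(7.5, 0.5, 1.5)):
        self.nc, self.strides, self.reg_max = nc, strides, reg_max
        self.kind = box_loss
        self.extent = extent
        self.gain_box, self.gain_cls, self.gain_dfl = gains

    def _branch(self, levels, targets, topk):
        shapes = [o.shape[2:] for o in levels]
        anchors, stv = make_anchors(shapes, self.strides)
        bs = levels[0].shape[0]
        flat = ag.concat([o.reshape(o.shape[0], o.shape[1], -1) for o in levels],
                         axis=2)
        box_logits = flat[:, :4 * self.reg_max]
        cls_logits = flat[:, 4 * self.reg_max:]
        pboxes = decode_boxes(box_logits, anchors, stv, self.reg_max)  # (B,4,A)
        scores_np = 1.0 / (1.0 + np.exp(-cls_logits.data))             # (B,nc,A)

        total_cls = None
        box_terms, dfl_terms, weight_sum = [], [], 0.0
        tscore_sum = 0.0
        all_ts = []
        for i in range(bs):
            gtb, gtc = targets[i]
            fg, tgt_idx, tscores = task_aligned_assign(
                scores_np[i].T, pboxes.data[i].T, anchors, gtb, gtc, topk)
            all_ts.append(tscores)
            tscore_sum += tscores.sum()
            if not fg.any():
                continue
            idx = np.nonzero(fg)[0]
            w = tscores[idx].sum(axis=1)                # per-anchor weight
            pb = pboxes[i].transpose(1, 0)[idx]         # (F,4) tensor
            gb = gtb[tgt_idx[idx]]                      # (F,4) ndarray
            lb = iou_family_loss(self.kind, pb, gb, self.extent)
            box_terms.append((lb * Tensor(w)).sum())
            # DFL: soft two-bin cross-entropy on ltrb distances (stride units)
            tl = np.stack([anchors[idx, 0] - gb[:, 0], anchors[idx, 1] - gb[:, 1],
                           gb[:, 2] - anchors[idx, 0], gb[:, 3] - anchors[idx, 1]],
                          axis=1) / stv[idx, None]
            tl = np.clip(tl, 0, self.reg_max - 1 - 0.01)
            lo = np.floor(tl).astype(np.int64)
            hi = lo + 1
            wl, wh = hi - tl, tl - lo
            logits = box_logits[i].reshape(4, self.reg_max, -1)[:, :, idx]
            logp = ag.log_softmax(logits, axis=1)        # (4, reg_max, F)
            sides = np.arange(4)[:, None]
            fsel = np.arange(len(idx))[None, :]
            nll = -1.0 * (logp[sides, lo.T, fsel] * Tensor(wl.T)
                          + logp[sides, hi.T, fsel] * Tensor(wh.T))
            dfl_terms.append((nll.mean(axis=0) * Tensor(w)).sum())
            weight_sum += float(w.sum())
        ts = np.stack(all_ts)                            # (B, A, nc)
        cls_all = ag.bce_with_logits(cls_logits.transpose(0, 2, 1), ts).sum()
        denom = max(tscore_sum, 1.0)
        cls_loss = cls_all * (1.0 / denom)
        zero = Tensor(np.zeros(()))
        box_loss = (sum(box_terms) * (1.0 / denom)) if box_terms else zero
        dfl_loss = (sum(dfl_terms) * (1.0 / denom)) if dfl_terms else zero
        return box_loss, cls_loss, dfl_loss

    def __call__(self, outputs: dict, targets):
        """`outputs` is the head dict; `targets` a list (per image) of
        (boxes_xyxy ndarray (M,4) in input pixels, class ids (M,))."""
        comps = {"box": 0.0, "cls": 0.0, "dfl": 0.0}
        total = None
        for branch, topk in (("one2many", 10), ("one2one", 1)):
            if branch not in outputs:
                continue
            b, c, d = self._branch(outputs[branch], targets, topk)
            part = self.gain_box * b + self.gain_cls * c + self.gain_dfl * d
            total = part if total is None else total + part
            comps["box"] += float(b.data)
            comps["cls"] += float(c.data)
            comps["dfl"] += float(d.data)
        return total, comps


def detection_training_loss(predictions: dict, targets, config) -> tuple:
    """Functional wrapper: total loss tensor + per-component values."""
    crit = DetectionLoss(config.num_classes, box_loss=config.box_loss,
                         extent=(config.input_side, config.input_side))
    return crit(predictions, targets)
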