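"""Decoupled anchor-free detection head with dual assignment branches.

The training-time head carries two structurally identical branch pairs:
a one-to-many branch (dense supervision) and a one-to-one branch
(NMS-free inference) fed detached features. Box regression is
distributional (DFL): each box side is a softmax over `reg_max`
discrete cell offsets whose expectation gives the distance from the
anchor point, in stride units.
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import Module, ModuleList, Sequential, Conv2d, ConvBN


class DetectHead(Module):
    def __init__(self, nc: int, ch: tuple, strides=(8, 16, 32), reg_max: int = 16):
        super().__init__()
        self.nc, self.ch, self.strides, self.reg_max = nc, tuple(ch), tuple(strides), reg_max
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))

        def box_branch(x):
            return Sequential(ConvBN(x, c2, 3), ConvBN(c2, c2, 3),
                              Conv2d(c2, 4 * reg_max, 1, bias=True))

        def cls_branch(x):
            return Sequential(
                Sequential(ConvBN(x, x, 3, g=x), ConvBN(x, c3, 1)),
                Sequential(ConvBN(c3, c3, 3, g=c3), ConvBN(c3, c3, 1)),
                Conv2d(c3, nc, 1, bias=True))

        self.cv2 = ModuleList([box_branch(x) for x in ch])
        self.cv3 = ModuleList([cls_branch(x) for x in ch])
        self.one2one_cv2 = ModuleList([box_branch(x) for x in ch])
        self.one2one_cv3 = ModuleList([cls_branch(x) for x in ch])

    def bias_init(self, imgsz: int = 640):
        """Prior-aware output bias initialisation (stabilises early training)."""
        for cv2, cv3 in ((self.cv2, self.cv3), (self.one2one_cv2, self.one2one_cv3)):
            for box, cls, s in zip(cv2, cv3, self.strides):
                box.seq[-1].bias.data[:] = 1.0
                cls.seq[-1].bias.data[:] = math.log(5 / self.nc / (imgsz / s) ** 2)

    def _run(self, feats, cv2, cv3):
        return [ag.concat([b(f), c(f)], axis=1) for f, b, c in zip(feats, cv2, cv3)]

    def forward(self, feats, branch: str = "both"):
        out = {}
        if branch in ("both", "one2many"):
            out["one2many"] = self._run(feats, self.cv2, self.cv3)
        if branch in ("both", "one2one"):
            det = [f.detach() for f in feats] if branch == "both" else feats
            out["one2one"] = self._run(det, self.one2one_cv2, self.one2one_cv3)
        return out


def make_anchors(shapes, strides, offset=0.5):
    """Anchor points (cell centres, input-pixel units) and per-anchor stride."""
    pts, stv = [], []
    for (h, w), s in zip(shapes, strides):
        xs = (np.arange(w, dtype=np.float32) + offset) * s
        ys = (np.arange(h, dtype=np.float32) + offset) * s
        gx, gy = np.meshgrid(xs, ys)
        pts.append(np.stack([gx.ravel(), gy.ravel()], axis=-1))
        stv.append(np.full(h * w, s, np.float32))
    return np.concatenate(pts), np.concatenate(stv)


def dfl_expectation(box_logits: Tensor, reg_max: int) -> Tensor:
    """(B, 4*reg_max, A) logits -> (B, 4, A) expected ltrb distances (stride units)."""
    b, _, a = box_logits.shape
    x = box_logits.reshape(b, 4, reg_max, a)
    p = ag.softmax(x, axis=2)
    proj = Tensor(np.arange(reg_max, dtype=np.float32).reshape(1, 1, reg_max, 1))
    return (p * proj).sum(axis=2)


def decode_boxes(box_logits: Tensor, anchors: np.ndarray, strides: np.ndarray,
                 reg_max: int) -> Tensor:
    """Differentiable decode of DFL logits to xyxy boxes in input pixels."""
    d = dfl_expectation(box_logits, reg_max) * Tensor(strides.reshape(1, 1, -1))
    ax = Tensor(anchors[:, 0].reshape(1, -1))
    ay = Tensor(anchors[:, 1].reshape(1, -1))
    x1 = ax - d[:, 0]
    y1 = ay - d[:, 1]
    x2 = ax + d[:, 2]
    y2 = ay + d[:, 3]
    return ag.concat([t.reshape(t.shape[0], 1, t.shape[1]) for t in (x1, y1, x2, y2)],
                     axis=1)


def decode_predictions(level_outputs, strides, nc, reg_max=16,
                       conf_threshold=0.25, max_det=300):
    """NMS-free decode of raw one-to-one head outputs (NumPy, no grad).

    Returns per-image arrays (boxes xyxy, scores, class ids).
    """
    shapes = [o.data.shape[2:] for o in level_outputs]
    anchors, stv = make_anchors(shapes, strides)
    flat = np.concatenate(
        [o.data.reshape(o.data.shape[0], o.data.shape[1], -1) for o in level_outputs],
        axis=2)
    bs = flat.shape[0]
    box_logits = flat[:, :4 * reg_max]
    cls_logits = flat[:, 4 * reg_max:]
    p = box_logits.reshape(bs, 4, reg_max, -1)
    p = np.exp(p - p.max(axis=2, keepdims=True))
    p /= p.sum(axis=2, keepdims=True)
    d = (p * np.arange(reg_max, dtype=np.float32).reshape(1, 1, reg_max, 1)).sum(axis=2)
    d *= stv.reshape(1, 1, -1)
    boxes = np.stack([anchors[:, 0] - d[:, 0], anchors[:, 1] - d[:, 1],
                      anchors[:, 0] + d[:, 2], anchors[:, 1] + d[:, 3]], axis=1)
    scores = 1.0 / (1.0 + np.exp(-cls_logits))
    results = []
    for i in range(bs):
        cls_id = scores[i].argmax(axis=0)
        conf = scores[i].max(axis=0)
        keep = conf >= conf_threshold
        order = np.argsort(-conf[keep], kind="stable")[:max_det]
        results.append((boxes[i].T[keep][order], conf[keep][order],
                        cls_id[keep][order]))
    return results
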