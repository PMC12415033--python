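"""YOLO-format annotation I/O, letterboxing, deterministic dataset
splitting and box-distribution statistics.

Conventions: pixel-space boxes are 0-based half-open [x1, x2);
normalized boxes are centre/size fractions of the image side in
[0, 1]. Empty label files are valid negative images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .losses import BoxXYXY, ImageExtent

__all__ = ["BoxYOLO", "DatasetSplit", "read_labels", "write_labels",
           "yolo_to_xyxy", "xyxy_to_yolo", "letterbox", "Affine",
           "split_dataset", "dataset_stats", "load_image", "LabelParseError"]


class LabelParseError(ValueError):
    pass


@dataclass(frozen=True)
class BoxYOLO:
    """Normalized centre-size box: `class_id cx cy w h`, all in [0, 1]."""
    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box width/height must be positive")


def read_labels(path) -> list[BoxYOLO]:
    """Parse one YOLO txt label file; empty file -> [] (negative image)."""
    boxes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 5:
                raise LabelParseError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
            try:
                cid = int(float(parts[0]))
                vals = [float(v) for v in parts[1:]]
            except ValueError as e:
                raise LabelParseError(f"{path}:{ln}: {e}") from None
            try:
                boxes.append(BoxYOLO(cid, *vals))
            except ValueError as e:
                raise LabelParseError(f"{path}:{ln}: {e}") from None
    return boxes


def write_labels(path, boxes: list[BoxYOLO], decimals: int = 6):
    """Write YOLO txt labels, clamping box edges into [0, 1]."""
    lines = []
    for b in boxes:
        x1 = max(b.cx - b.w / 2, 0.0)
        x2 = min(b.cx + b.w / 2, 1.0)
        y1 = max(b.cy - b.h / 2, 0.0)
        y2 = min(b.cy + b.h / 2, 1.0)
        lines.append(f"{b.class_id} {(x1+x2)/2:.{decimals}f} {(y1+y2)/2:.{decimals}f} "
                     f"{x2-x1:.{decimals}f} {y2-y1:.{decimals}f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def yolo_to_xyxy(box: BoxYOLO, extent: ImageExtent) -> BoxXYXY:
    return BoxXYXY((box.cx - box.w / 2) * extent.w,
                   (box.cy - box.h / 2) * extent.h,
                   (box.cx + box.w / 2) * extent.w,
                   (box.cy + box.h / 2) * extent.h)


def xyxy_to_yolo(box: BoxXYXY, extent: ImageExtent, class_id: int = 0) -> BoxYOLO:
    return BoxYOLO(class_id,
                   (box.x1 + box.x2) / 2 / extent.w,
                   (box.y1 + box.y2) / 2 / extent.h,
                   (box.x2 - box.x1) / extent.w,
                   (box.y2 - box.y1) / extent.h)


@dataclass(frozen=True)
class Affine:
    """Record of the letterbox transform: scaled by `scale`, then
    shifted by (pad_x, pad_y)."""
    scale: float
    pad_x: float
    pad_y: float

    def apply_box(self, b: BoxXYXY) -> BoxXYXY:
        return BoxXYXY(b.x1 * self.scale + self.pad_x, b.y1 * self.scale + self.pad_y,
                       b.x2 * self.scale + self.pad_x, b.y2 * self.scale + self.pad_y)

    def invert_box(self, b: BoxXYXY) -> BoxXYXY:
        return BoxXYXY((b.x1 - self.pad_x) / self.scale, (b.y1 - self.pad_y) / self.scale,
                       (b.x2 - self.pad_x) / self.scale, (b.y2 - self.pad_y) / self.scale)


def letterbox(image: np.ndarray, target_side: int = 640,
              fill: int = 114) -> tuple[np.ndarray, Affine]:
    """Aspect-preserving resize plus symmetric padding to a square."""
    h, w = image.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("empty image")
    scale = min(target_side / w, target_side / h)
    nw, nh = round(w * scale), round(h * scale)
    if (nw, nh) != (w, h):
        image = np.asarray(Image.fromarray(image).resize((nw, nh), Image.BILINEAR))
    out = np.full((target_side, target_side) + image.shape[2:], fill, image.dtype)
    px, py = (target_side - nw) // 2, (target_side - nh) // 2
    out[py:py + nh, px:px + nw] = image
    return out, Affine(scale=scale, pad_x=px, pad_y=py)


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple
    val: tuple
    test: tuple
    ratios: tuple

    def as_dict(self):
        return {"train": list(self.train), "val": list(self.val),
                "test": list(self.test)}


def split_dataset(files, ratios=(0.8, 0.1, 0.1), seed: int = 0) -> DatasetSplit:
    """Deterministic shuffled partition with largest-remainder sizing.

    The shuffle is a seeded PCG64 permutation of the sorted file list,
    so the split is a pure function of (files, ratios, seed) on any
    platform.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    files = sorted(str(f) for f in files)
    order = np.random.default_rng(seed).permutation(len(files))
    shuffled = [files[i] for i in order]
    n = len(files)
    exact = [r * n for r in ratios]
    sizes = [int(e) for e in exact]
    rem = n - sum(sizes)
    frac_order = np.argsort([-(e - int(e)) for e in exact], kind="stable")
    for i in range(rem):
        sizes[frac_order[i]] += 1
    a, b = sizes[0], sizes[0] + sizes[1]
    return DatasetSplit(tuple(shuffled[:a]), tuple(shuffled[a:b]),
                        tuple(shuffled[b:]), tuple(ratios))


def dataset_stats(label_lists: list[list[BoxYOLO]], bins: int = 10,
                  grid: int = 10) -> dict:
    """Distribution report over per-image label lists: width/height
    histograms, centre-density grid, aspect-ratio summary. Images with
    no boxes are counted but excluded from box statistics."""
    if not label_lists:
        raise ValueError("at least one label list required")
    ws, hs, cxs, cys = [], [], [], []
    n_empty = 0
    for boxes in label_lists:
        if not boxes:
            n_empty += 1
            continue
        for b in boxes:
            ws.append(b.w), hs.append(b.h), cxs.append(b.cx), cys.append(b.cy)
    ws, hs = np.array(ws), np.array(hs)
    cxs, cys = np.array(cxs), np.array(cys)
    edges = np.linspace(0, 1, bins + 1)
    aspect = ws / hs if len(ws) else np.array([])
    density, _, _ = (np.histogram2d(cys, cxs, bins=grid, range=[[0, 1], [0, 1]])
                     if len(ws) else (np.zeros((grid, grid)), None, None))
    return {
        "n_images": len(label_lists),
        "n_empty_images": n_empty,
        "n_boxes": int(len(ws)),
        "width_hist": np.histogram(ws, bins=edges)[0].tolist(),
        "height_hist": np.histogram(hs, bins=edges)[0].tolist(),
        "center_density": density.tolist(),
        "aspect_mean": float(aspect.mean()) if len(aspect) else float("nan"),
        "aspect_median": float(np.median(aspect)) if len(aspect) else float("nan"),
        "mean_wh": [float(ws.mean()), float(hs.mean())] if len(ws) else None,
    }


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_stats(stats: dict, path):
    Path(path).write_text(json.dumps(stats, indent=2))
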