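"""Deterministic synthetic-orchard scene generator.

Stands in for a trellised-orchard kiwifruit dataset that is not
publicly deposited: single-class scenes of near-circular fruit
(aspect ratio clustered at 1) on textured foliage backgrounds, with
centre-biased object placement, optional partial occluders (leaves /
branches) and a lighting mode (sunny / cloudy / night-flash).
Annotations are the tight extents of the rendered fruit *before*
occlusion, mirroring how annotators box whole fruit. Every scene is a
pure function of (spec.seed, image index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .data import BoxYOLO, write_labels

LIGHTING_MODES = ("sunny", "cloudy", "night-flash")


@dataclass(frozen=True)
class SceneSpec:
    """Generation parameters for one synthetic dataset.

    `center_bias` is the Beta-concentration of fruit-centre placement
    (1 = uniform, larger = tighter central clustering); radii are
    fractions of the image side.
    """
    n_images: int = 32
    image_side: int = 640
    fruit_count_range: tuple = (1, 8)
    fruit_radius_range: tuple = (0.04, 0.11)
    center_bias: float = 2.5
    occlusion_prob: float = 0.35
    lighting: str = "sunny"
    overlap_free: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.fruit_count_range[0] > self.fruit_count_range[1]:
            raise ValueError("empty fruit_count_range")
        if not 0 <= self.occlusion_prob <= 1:
            raise ValueError("occlusion_prob must be in [0, 1]")
        if self.lighting not in LIGHTING_MODES:
            raise ValueError(f"lighting must be one of {LIGHTING_MODES}")
        if self.fruit_radius_range[0] <= 0:
            raise ValueError("fruit radius must be positive")
        if self.fruit_radius_range[1] >= 0.5:
            raise ValueError("fruit larger than the image")


def easy_spec(n_images: int, seed: int = 0, image_side: int = 640) -> SceneSpec:
    """High-contrast, occlusion-free scenes (smoke-training regime)."""
    return SceneSpec(n_images=n_images, image_side=image_side,
                     fruit_count_range=(2, 4), fruit_radius_range=(0.09, 0.16),
                     center_bias=2.0, occlusion_prob=0.0, lighting="sunny",
                     overlap_free=True, seed=seed)


def _background(rng, side, lighting):
    # low-frequency foliage mottle upsampled to full resolution
    coarse = rng.uniform(0, 1, (8, 8, 3)).astype(np.float32)
    img = np.asarray(Image.fromarray((coarse * 255).astype(np.uint8))
                     .resize((side, side), Image.BILINEAR), np.float32) / 255
    base = {"sunny": (62, 92, 48), "cloudy": (70, 84, 62),
            "night-flash": (14, 18, 12)}[lighting]
    spread = 70 if lighting != "night-flash" else 25
    out = np.array(base, np.float32) + (img - 0.5) * spread
    return np.clip(out, 0, 255)


def generate_scene(spec: SceneSpec, index: int):
    """Render one scene; returns (uint8 RGB image, list[BoxYOLO])."""
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, index])
    side = spec.image_side
    bg = _background(rng, side, spec.lighting)
    img = Image.fromarray(bg.astype(np.uint8))
    draw = ImageDraw.Draw(img)

    n = int(rng.integers(spec.fruit_count_range[0], spec.fruit_count_range[1] + 1))
    boxes = []
    fruit_geoms = []
    placed = []
    for _ in range(n):
        cb = spec.center_bias
        for _attempt in range(30):
            r = rng.uniform(*spec.fruit_radius_range) * side
            cx = rng.beta(cb, cb) * side
            cy = rng.beta(cb, cb) * side
            if not spec.overlap_free or all(
                    np.hypot(cx - px, cy - py) > (r + pr) * 1.05
                    for px, py, pr in placed):
                break
        else:
            continue
        placed.append((cx, cy, r))
        aspect = float(np.clip(rng.normal(1.0, 0.08), 0.75, 1.33))
        rx, ry = r * np.sqrt(aspect), r / np.sqrt(aspect)
        x1, y1 = cx - rx, cy - ry
        x2, y2 = cx + rx, cy + ry
        # clip the annotation (and the rendered fruit) to the frame
        bx1, by1 = max(x1, 0.0), max(y1, 0.0)
        bx2, by2 = min(x2, side), min(y2, side)
        if bx2 - bx1 < 2 or by2 - by1 < 2:
            continue
        if spec.lighting == "night-flash":
            base = np.array([168, 132, 70]) + rng.normal(0, 8, 3)
        else:
            base = np.array([139, 105, 62]) + rng.normal(0, 10, 3)
        col = tuple(int(c) for c in np.clip(base, 0, 255))
        draw.ellipse([x1, y1, x2, y2], fill=col)
        # highlight for a little shading realism
        hl = tuple(min(int(c * 1.25), 255) for c in col)
        draw.ellipse([cx - rx * 0.45 - rx * 0.2, cy - ry * 0.45 - ry * 0.2,
                      cx - rx * 0.45 + rx * 0.2, cy - ry * 0.45 + ry * 0.2], fill=hl)
        boxes.append(BoxYOLO(0, (bx1 + bx2) / 2 / side, (by1 + by2) / 2 / side,
                             (bx2 - bx1) / side, (by2 - by1) / side))
        fruit_geoms.append((cx, cy, rx, ry))

    # partial occluders drawn after all fruit, over box interiors
    leaf_col = (46, 74, 38) if spec.lighting != "night-flash" else (10, 14, 8)
    for (cx, cy, rx, ry) in fruit_geoms:
        if rng.uniform() < spec.occlusion_prob:
            ang = rng.uniform(0, 2 * np.pi)
            ox = cx + np.cos(ang) * rx
            oy = cy + np.sin(ang) * ry
            ow, oh = rx * rng.uniform(0.6, 1.2), ry * rng.uniform(0.4, 0.9)
            draw.ellipse([ox - ow, oy - oh, ox + ow, oy + oh], fill=leaf_col)

    out = np.asarray(img, np.float32)
    if spec.lighting == "cloudy":
        out = out * 0.82 + 20          # flatter contrast
    elif spec.lighting == "night-flash":
        yy, xx = np.mgrid[0:side, 0:side].astype(np.float32) / side - 0.5
        vignette = np.clip(1.25 - 1.8 * (xx ** 2 + yy ** 2), 0.15, 1.0)
        out = out * vignette[..., None]
    noise = rng.normal(0, 3.0, out.shape).astype(np.float32)
    return np.clip(out + noise, 0, 255).astype(np.uint8), boxes


def generate_dataset(spec: SceneSpec, out_dir) -> dict:
    """Write images/ + labels/ in the YOLO directory layout and return
    (and save) a manifest; regeneration with the same spec is identical."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(spec.n_images):
        img, boxes = generate_scene(spec, i)
        name = f"scene_{i:05d}"
        Image.fromarray(img).save(out / "images" / f"{name}.png")
        write_labels(out / "labels" / f"{name}.txt", boxes)
        entries.append({"name": name, "seed": [spec.seed, i], "n_boxes": len(boxes)})
    manifest = {"spec": {k: list(v) if isinstance(v, tuple) else v
                         for k, v in vars(spec).items()},
                "images": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def scene_arrays(spec: SceneSpec, indices) -> list:
    """In-memory dataset: list of (image, boxes) without touching disk."""
    return [generate_scene(spec, i) for i in indices]
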