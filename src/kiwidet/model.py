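"""Model assembly: compound-scaled YOLOv10n-style detector with optional
heterogeneous-kernel backbone blocks and the lightweight cross-scale
fusion neck.

A `ModelConfig` names one row of the variant ladder: depth/width
scaling factors, whether backbone C2f stages use DualHet bottlenecks,
whether the neck is the stock PAN+FPN or the cross-scale fusion module
(CCFM), the HetConv partition P, and the box-loss flavour. `build_full_model`
assembles backbone + neck + dual decoupled head.

Stage widths before scaling are 64/128/256/512/1024 with stage repeats
3/6/6/3 (backbone) and 3 (neck), the YOLOv10n layout: stem and two conv
downsamples, C2f stages, spatial-channel decoupled downsampling into
the two deepest stages, SPPF and partial self-attention at stride 32,
and a compact-inverted-block C2f at the deepest neck stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .hetconv import make_c2f_dualhet
from .nn import autograd as ag
from .nn.head import DetectHead
from .nn.layers import (C2f, CIB, ConvBN, Conv2d, Module, PSA, SCDown, SPPF,
                        Upsample, seed_init)

BOX_LOSSES = ("ciou", "diou", "giou", "eiou", "siou", "mpdiou")

#: canonical variant ladder (ablation rows + baseline)
VARIANTS = ("yolov10n", "model1", "model2", "model3", "model4", "model5", "kiwi")


@dataclass
class ModelConfig:
    depth_factor: float = 0.33
    width_factor: float = 0.125
    use_c2f_dualhet: bool = False
    use_ccfm: bool = False
    het_p: int = 4
    num_classes: int = 1
    input_side: int = 640
    box_loss: str = "mpdiou"
    max_channels: int = 1024
    name: str = "custom"

    def __post_init__(self):
        if not 0 < self.depth_factor <= 1 or not 0 < self.width_factor <= 1:
            raise ValueError("scaling factors must lie in (0, 1]")
        if self.input_side % 32:
            raise ValueError("input_side must be a multiple of 32")
        if self.box_loss not in BOX_LOSSES:
            raise ValueError(f"box_loss must be one of {BOX_LOSSES}")
        if self.num_classes < 1:
            raise ValueError("num_classes must be positive")

    # -- YAML round trip (keys: depth, width, dualhet, ccfm, loss, nc, imgsz)
    def to_dict(self) -> dict:
        return {"depth": self.depth_factor, "width": self.width_factor,
                "dualhet": {"enabled": self.use_c2f_dualhet, "p": self.het_p},
                "ccfm": {"enabled": self.use_ccfm},
                "loss": {"box": self.box_loss},
                "nc": self.num_classes, "imgsz": self.input_side,
                "max_channels": self.max_channels, "name": self.name}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(depth_factor=d.get("depth", 0.33),
                   width_factor=d.get("width", 0.125),
                   use_c2f_dualhet=d.get("dualhet", {}).get("enabled", False),
                   het_p=d.get("dualhet", {}).get("p", 4),
                   use_ccfm=d.get("ccfm", {}).get("enabled", False),
                   box_loss=d.get("loss", {}).get("box", "mpdiou"),
                   num_classes=d.get("nc", 1),
                   input_side=d.get("imgsz", 640),
                   max_channels=d.get("max_channels", 1024),
                   name=d.get("name", "custom"))

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def named_config(name: str) -> ModelConfig:
    """Load one of the packaged variant configs (yolov10n, model1..model5, kiwi)."""
    ref = resources.files("kiwidet") / "configs" / f"{name}.yaml"
    if not ref.is_file():
        raise KeyError(f"unknown model variant {name!r}; packaged: {VARIANTS}")
    return ModelConfig.from_dict(yaml.safe_load(ref.read_text()))


def scale_channels(base_channels: int, width_factor: float,
                   max_channels: int = 1024) -> int:
    """Width scaling with rounding to the next multiple of 8 and a
    maximum-channel cap (applied before scaling)."""
    if base_channels <= 0:
        raise ValueError("base_channels must be positive")
    return int(math.ceil(min(base_channels, max_channels) * width_factor / 8) * 8)


def scale_depth(base_repeats: int, depth_factor: float) -> int:
    """Depth scaling: round(n * d), floored at one repeat."""
    if base_repeats < 1:
        raise ValueError("base_repeats must be >= 1")
    return max(round(base_repeats * depth_factor), 1) if base_repeats > 1 else 1


# --------------------------------------------------------------------

class Backbone(Module):
    """Staged feature extractor emitting stride-8/16/32 taps.

    Under the CCFM neck the deepest-stage SPPF and partial
    self-attention are omitted; their role is taken over by the fusion
    module's 1x1 entry projection (hybrid-encoder style).
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        c = {b: scale_channels(b, cfg.width_factor, cfg.max_channels)
             for b in (64, 128, 256, 512, 1024)}
        n3 = scale_depth(3, cfg.depth_factor)
        n6 = scale_depth(6, cfg.depth_factor)
        self.channels = (c[256], c[512], c[1024])

        def stage(ci, co, n):
            if cfg.use_c2f_dualhet:
                return make_c2f_dualhet(ci, co, n, cfg.het_p, shortcut=True)
            return C2f(ci, co, n, shortcut=True)

        self.stem = ConvBN(3, c[64], 3, 2)
        self.down1 = ConvBN(c[64], c[128], 3, 2)
        self.stage1 = stage(c[128], c[128], n3)
        self.down2 = ConvBN(c[128], c[256], 3, 2)
        self.stage2 = stage(c[256], c[256], n6)
        self.down3 = SCDown(c[256], c[512])
        self.stage3 = stage(c[512], c[512], n6)
        self.down4 = SCDown(c[512], c[1024])
        self.stage4 = stage(c[1024], c[1024], n3)
        self.has_sppf_psa = not cfg.use_ccfm
        if self.has_sppf_psa:
            self.sppf = SPPF(c[1024], c[1024])
            self.psa = PSA(c[1024])

    def forward(self, x):
        x = self.stem(x)
        x = self.stage1(self.down1(x))
        p3 = self.stage2(self.down2(x))
        p4 = self.stage3(self.down3(p3))
        p5 = self.stage4(self.down4(p4))
        if self.has_sppf_psa:
            p5 = self.psa(self.sppf(p5))
        return p3, p4, p5


class StockNeck(Module):
    """YOLOv10n PAN+FPN neck (top-down C2f fusion, bottom-up with a
    stride-2 conv / SCDown and a compact-inverted-block deepest stage)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        c = {b: scale_channels(b, cfg.width_factor, cfg.max_channels)
             for b in (256, 512, 1024)}
        n3 = scale_depth(3, cfg.depth_factor)
        self.up = Upsample()
        self.td1 = C2f(c[1024] + c[512], c[512], n3)
        self.td2 = C2f(c[512] + c[256], c[256], n3)
        self.bu_conv1 = ConvBN(c[256], c[256], 3, 2)
        self.bu1 = C2f(c[256] + c[512], c[512], n3)
        self.bu_conv2 = SCDown(c[512], c[512])
        self.bu2 = C2f(c[512] + c[1024], c[1024], n3, shortcut=True,
                       block=lambda ci, co, sc: CIB(ci, co, sc, e=1.0))
        self.channels = (c[256], c[512], c[1024])

    def forward(self, pyramid):
        p3, p4, p5 = pyramid
        t4 = self.td1(ag.concat([self.up(p5), p4], axis=1))
        t3 = self.td2(ag.concat([self.up(t4), p3], axis=1))
        b4 = self.bu1(ag.concat([self.bu_conv1(t3), t4], axis=1))
        b5 = self.bu2(ag.concat([self.bu_conv2(b4), p5], axis=1))
        return t3, b4, b5


class CCFMNeck(Module):
    """Cross-scale fusion neck.

    All three pyramid levels are aligned to one fused width (the
    unscaled 256 put through the width rule) by 1x1 projections: an
    entry projection on the deepest level and input projections on
    S3/S4. The top-down pathway is lateral 1x1 (bias only, no
    normalisation or activation) -> nearest-neighbour upsample ->
    fusion with the shallower level; the bottom-up pathway mirrors it
    with spatial-channel decoupled stride-2 downsampling. Fusion is a
    zero-parameter elementwise merge of the width-aligned streams; no
    heavy fusion blocks remain.
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cin = tuple(scale_channels(b, cfg.width_factor, cfg.max_channels)
                    for b in (256, 512, 1024))
        cf = scale_channels(256, cfg.width_factor, cfg.max_channels)
        self.reduce = ConvBN(cin[2], cf, 1)
        self.proj4 = ConvBN(cin[1], cf, 1)
        self.proj3 = ConvBN(cin[0], cf, 1)
        self.lat5 = Conv2d(cf, cf, 1, bias=True)
        self.lat4 = Conv2d(cf, cf, 1, bias=True)
        self.down3 = SCDown(cf, cf)
        self.down4 = SCDown(cf, cf)
        self.up = Upsample()
        self.channels = (cf, cf, cf)

    def forward(self, pyramid):
        p3, p4, p5 = pyramid
        f5 = self.reduce(p5)
        t4 = self.proj4(p4) + self.up(self.lat5(f5))
        t3 = self.proj3(p3) + self.up(self.lat4(t4))
        b4 = t4 + self.down3(t3)
        b5 = f5 + self.down4(b4)
        return t3, b4, b5


class Detector(Module):
    """Backbone + neck + dual decoupled head."""

    strides = (8, 16, 32)

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        self.backbone = Backbone(cfg)
        self.neck = CCFMNeck(cfg) if cfg.use_ccfm else StockNeck(cfg)
        self.head = DetectHead(cfg.num_classes, self.neck.channels, self.strides)
        self.head.bias_init(cfg.input_side)

    def forward(self, x, branch: str = "both"):
        if isinstance(x, np.ndarray):
            x = ag.Tensor(x)
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("input sides must be multiples of 32")
        return self.head(self.neck(self.backbone(x)), branch=branch)


def build_backbone(config: ModelConfig) -> Backbone:
    return Backbone(config)


def build_ccfm_neck(config: ModelConfig) -> CCFMNeck:
    return CCFMNeck(config)


def build_full_model(config: ModelConfig, seed: int | None = None) -> Detector:
    """Assemble the detector for one variant row; `seed` fixes weight init."""
    if seed is not None:
        seed_init(seed)
    return Detector(config)
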