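"""Structural accounting: exact parameter counts, MAC-based FLOPs and
serialized-size estimates for any assembled detector variant.

FLOPs are measured by instrumenting a real forward pass: every
convolution reports its multiply-accumulates to a `CostTracker`, so
heterogeneous-kernel layers are counted by construction as the sum of
their KxK and 1x1 parts. The headline GFLOP number uses the
deploy-time forward (one-to-one branch only) and 2 FLOPs per MAC,
counting conv/linear kernels only; `full_ops=True` adds pointwise work
(normalisation, activation, bias). The convention was fixed once by
calibration against the reference baseline and is not input-dependent.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

from .model import Detector, ModelConfig, build_full_model, named_config
from .nn.layers import CostTracker, Module

FLOPS_PER_MAC = 2  # multiply + add; toggle for MAC-denominated numbers


@dataclass(frozen=True)
class ModelCostSummary:
    name: str
    params: int
    params_millions: float
    gflops: float
    size_mb: float
    input_side: int


def count_params(model: Module) -> int:
    """Sum of trainable tensor element counts (exact integer)."""
    return sum(p.data.size for p in model.parameters())


def count_flops(model: Detector, input_side: int | None = None,
                head_mode: str = "one2one", full_ops: bool = False,
                flops_per_mac: int = FLOPS_PER_MAC) -> float:
    """GFLOPs of one forward pass at `input_side` (square input).

    head_mode 'one2one' profiles the deploy forward (NMS-free branch);
    'dual' profiles the training-time forward with both branches.
    """
    side = input_side or model.cfg.input_side
    if side % 32:
        raise ValueError("input_side must be a multiple of 32")
    x = np.zeros((1, 3, side, side), np.float32)
    was_training = model.training
    model.eval()
    with CostTracker() as t:
        model(x, branch="one2one" if head_mode == "one2one" else "both")
    if was_training:
        model.train()
    total = flops_per_mac * t.macs + (t.elems if full_ops else 0)
    return total / 1e9


def size_mb(params: int) -> float:
    """fp32 serialized-size estimate: 4 bytes per parameter."""
    return params * 4 / 1e6


def truncate_millions(params: int, decimals: int = 3) -> float:
    """Millions of parameters truncated (not rounded) to `decimals`,
    the convention of the reference summaries."""
    scale = 10 ** decimals
    return math.floor(params / 1e6 * scale) / scale


def profile_config(cfg: ModelConfig, input_side: int | None = None,
                   head_mode: str = "one2one") -> ModelCostSummary:
    model = build_full_model(cfg, seed=0)
    p = count_params(model)
    g = count_flops(model, input_side, head_mode=head_mode)
    return ModelCostSummary(name=cfg.name, params=p,
                            params_millions=p / 1e6, gflops=g,
                            size_mb=size_mb(p),
                            input_side=input_side or cfg.input_side)


def profile_variant(name: str, **kw) -> ModelCostSummary:
    return profile_config(named_config(name), **kw)


def reduction_table(variants: list[str] | list[ModelCostSummary],
                    baseline: str = "yolov10n") -> dict[str, dict]:
    """Percent reductions 100*(baseline - v)/baseline in size, params
    and FLOPs for each variant, plus the absolute numbers."""
    summaries = {}
    for v in variants:
        s = v if isinstance(v, ModelCostSummary) else profile_variant(v)
        summaries[s.name] = s
    if baseline not in summaries:
        raise KeyError(f"baseline {baseline!r} missing from variants")
    b = summaries[baseline]
    out = {}
    for name, s in summaries.items():
        out[name] = {
            "params_millions": s.params_millions,
            "gflops": s.gflops,
            "size_mb": s.size_mb,
            "reduction_size_pct": 100.0 * (b.size_mb - s.size_mb) / b.size_mb,
            "reduction_params_pct": 100.0 * (b.params - s.params) / b.params,
            "reduction_flops_pct": 100.0 * (b.gflops - s.gflops) / b.gflops,
        }
    return out


def write_cost_csv(rows: dict[str, dict], path):
    cols = ["variant"] + list(next(iter(rows.values())).keys())
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for name, r in rows.items():
            w.writerow([name] + [f"{v:.6g}" for v in r.values()])
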