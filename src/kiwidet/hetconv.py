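"""Heterogeneous-kernel convolution: analytic cost model and layers.

A HetConv filter applies KxK kernels to a fraction 1/P of its input
channels and 1x1 kernels to the rest. Relative to a standard KxK
convolution with the same shape this cuts multiply-accumulates to

    R_HC = 1/P + (1 - 1/P) / K**2

with no extra sequential stage (unlike depthwise-separable
factorisations). `standard_conv_cost` / `hetconv_cost` give the exact
per-layer MAC and parameter counts; `make_hetconv_layer` /
`make_c2f_dualhet` build the corresponding trainable blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn.layers import C2f, DualHetBlock, HetConv2d

__all__ = ["HetConvSpec", "CostReport", "standard_conv_cost", "hetconv_cost",
           "make_hetconv_layer", "make_c2f_dualhet"]


class InvalidPartitionError(ValueError):
    """P does not divide the input-channel count."""


@dataclass(frozen=True)
class HetConvSpec:
    """Shape of one convolution layer.

    in_channels M, out_channels N, kernel_size K (odd), part P (divisor
    of M; P=1 is a standard KxK conv), input/output spatial sides D_i,
    D_o in pixels.
    """

    in_channels: int
    out_channels: int
    kernel_size: int = 3
    part: int = 1
    input_side: int = 1
    output_side: int = 1

    def __post_init__(self):
        for name in ("in_channels", "out_channels", "kernel_size", "part",
                     "input_side", "output_side"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.in_channels % self.part:
            raise InvalidPartitionError(
                f"part P={self.part} does not divide M={self.in_channels}")


@dataclass(frozen=True)
class CostReport:
    """MAC-level FLOP count, trainable parameter count (bias excluded)
    and the cost ratio relative to the standard conv of the same shape."""

    flops: int
    params: int
    ratio_vs_standard: float


def standard_conv_cost(spec: HetConvSpec) -> CostReport:
    """Cost of a dense KxK convolution: D_o^2 * M * N * K^2 MACs."""
    m, n, k, d = spec.in_channels, spec.out_channels, spec.kernel_size, spec.output_side
    fl = d * d * m * n * k * k
    return CostReport(flops=fl, params=n * m * k * k, ratio_vs_standard=1.0)


def hetconv_cost(spec: HetConvSpec) -> CostReport:
    """Cost of the heterogeneous layer: the KxK part over M/P channels
    plus the 1x1 part over the remaining M - M/P channels."""
    m, n, k, p, d = (spec.in_channels, spec.out_channels, spec.kernel_size,
                     spec.part, spec.output_side)
    fl_k = d * d * m * n * k * k // p
    fl_1 = d * d * n * (m - m // p)
    fl = fl_k + fl_1
    params = n * (m // p) * k * k + n * (m - m // p)
    return CostReport(flops=fl, params=params,
                      ratio_vs_standard=fl / standard_conv_cost(spec).flops)


def hetconv_ratio(p: int, k: int) -> float:
    """Closed-form reduction ratio 1/P + (1 - 1/P)/K^2."""
    return 1.0 / p + (1.0 - 1.0 / p) / (k * k)


# cost formulas for the classic efficient-convolution alternatives
# (comparison only; the package builds no such layers)

def depthwise_conv_cost(spec: HetConvSpec) -> CostReport:
    """Depthwise KxK (one kernel per input channel, N ignored)."""
    m, k, d = spec.in_channels, spec.kernel_size, spec.output_side
    fl = d * d * m * k * k
    return CostReport(flops=fl, params=m * k * k,
                      ratio_vs_standard=fl / standard_conv_cost(spec).flops)


def pointwise_conv_cost(spec: HetConvSpec) -> CostReport:
    """1x1 convolution M -> N."""
    m, n, d = spec.in_channels, spec.out_channels, spec.output_side
    fl = d * d * m * n
    return CostReport(flops=fl, params=n * m,
                      ratio_vs_standard=fl / standard_conv_cost(spec).flops)


def group_conv_cost(spec: HetConvSpec, groups: int) -> CostReport:
    """Grouped KxK convolution with `groups` groups."""
    if spec.in_channels % groups or spec.out_channels % groups:
        raise InvalidPartitionError("groups must divide both channel counts")
    r = standard_conv_cost(spec)
    return CostReport(flops=r.flops // groups, params=r.params // groups,
                      ratio_vs_standard=1.0 / groups)


def cost_table_csv(specs, path):
    """Per-layer HetConv cost table: layer, M, N, K, P, flops, params, ratio."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["layer", "M", "N", "K", "P", "flops", "params", "ratio"])
        for i, s in enumerate(specs):
            r = hetconv_cost(s)
            w.writerow([i, s.in_channels, s.out_channels, s.kernel_size,
                        s.part, r.flops, r.params,
                        f"{r.ratio_vs_standard:.6f}"])


def make_hetconv_layer(spec: HetConvSpec, stride: int = 1, bias: bool = False) -> HetConv2d:
    """Trainable HetConv layer whose weight count equals
    ``hetconv_cost(spec).params`` (plus N bias terms if enabled)."""
    return HetConv2d(spec.in_channels, spec.out_channels, spec.kernel_size,
                     spec.part, stride, bias=bias)


def make_c2f_dualhet(c_in: int, c_out: int, n_blocks: int = 1, het_p: int = 4,
                     shortcut: bool = True) -> C2f:
    """C2f block whose bottlenecks are DualHetBlocks (two chained
    HetConv layers, each with batch-norm + SiLU, residual when shapes
    match)."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    hidden = int(c_out * 0.5)
    if hidden % het_p:
        raise InvalidPartitionError(
            f"het_p={het_p} does not divide hidden width {hidden}")
    return C2f(c_in, c_out, n_blocks, shortcut,
               block=lambda ci, co, sc: DualHetBlock(ci, co, sc, het_p))
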