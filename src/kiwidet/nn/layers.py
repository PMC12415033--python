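"""Detector building blocks on the NumPy autograd core.

The block set mirrors the YOLOv10-family vocabulary: `ConvBN` (conv +
batch-norm + SiLU), the cross-stage-partial `C2f`, spatial-channel
decoupled downsampling (`SCDown`), `SPPF`, partial self-attention
(`PSA`), the compact inverted block stage (`C2fCIB`), plus the
heterogeneous-kernel convolution `HetConv2d` and the `DualHetBlock`
bottleneck replacement built from two chained HetConv layers.

Every convolution routes through `Conv2d`/`HetConv2d`, which report
multiply-accumulate counts to an active `CostTracker`, so structural
profiling is exact by construction.
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Tensor


# --------------------------------------------------------------------
# profiling context

class CostTracker:
    """Accumulates MACs (conv/linear kernels) and pointwise-op element
    counts during a forward pass."""

    _active = None

    def __init__(self):
        self.macs = 0
        self.elems = 0

    def __enter__(self):
        CostTracker._active = self
        return self

    def __exit__(self, *exc):
        CostTracker._active = None

    @classmethod
    def add_macs(cls, n):
        if cls._active is not None:
            cls._active.macs += int(n)

    @classmethod
    def add_elems(cls, n):
        if cls._active is not None:
            cls._active.elems += int(n)


# --------------------------------------------------------------------
# module base

class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, ModuleList):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix=""):
        for k, p in self._params.items():
            yield f"{prefix}{k}", p
        for k, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{k}.")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode=True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self):
        return {k: p.data.copy() for k, p in self.named_parameters()} | {
            f"{k}:buf": v for k, v in self.named_buffers()}

    def load_state_dict(self, sd):
        for k, p in self.named_parameters():
            if p.data.shape != sd[k].shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{p.data.shape} vs {sd[k].shape}")
            p.data[...] = sd[k]
        for k, v in self.named_buffers():
            v[...] = sd[f"{k}:buf"]

    def named_buffers(self, prefix=""):
        for k in getattr(self, "_buffers", ()):
            yield f"{prefix}{k}", getattr(self, k)
        for k, m in self._modules.items():
            yield from m.named_buffers(f"{prefix}{k}.")

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.seq = ModuleList(mods)

    def forward(self, x):
        for m in self.seq:
            x = m(x)
        return x


_rng = np.random.default_rng(0)


def seed_init(seed: int):
    """Reseed the weight-initialisation stream (call before building)."""
    global _rng
    _rng = np.random.default_rng(seed)


def _kaiming(shape, fan_in):
    bound = math.sqrt(2.0 / fan_in)
    return Tensor(_rng.normal(0.0, bound, size=shape).astype(np.float32),
                  requires_grad=True)


def autopad(k):
    return k // 2


# --------------------------------------------------------------------
# primitives

class Conv2d(Module):
    """Plain convolution (optional bias, no normalisation)."""

    def __init__(self, cin, cout, k=1, s=1, p=None, g=1, bias=True):
        super().__init__()
        if cin <= 0 or cout <= 0 or k <= 0:
            raise ValueError("non-positive convolution dimension")
        if cin % g:
            raise ValueError("groups must divide in_channels")
        self.cin, self.cout, self.k, self.s, self.g = cin, cout, k, s, g
        self.p = autopad(k) if p is None else p
        self.weight = _kaiming((cout, cin // g, k, k), cin // g * k * k)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        y = ag.conv2d(x, self.weight, self.bias, self.s, self.p, self.g)
        CostTracker.add_macs(y.data[0, 0].size * self.cout * (self.cin // self.g)
                             * self.k * self.k)
        if self.bias is not None:
            CostTracker.add_elems(y.data[0].size)
        return y


class BatchNorm2d(Module):
    _buffers = ("running_mean", "running_var")

    def __init__(self, c, eps=1e-3, momentum=0.03):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)

    def forward(self, x):
        CostTracker.add_elems(x.data[0].size)
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.size / c
            self.running_mean += self.momentum * (
                mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (
                var.data.reshape(-1) * n / max(n - 1, 1) - self.running_var)
            xhat = (x - mu) / (var + self.eps) ** 0.5
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            xhat = (x - Tensor(mu)) / Tensor(sd)
        return xhat * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


class ConvBN(Module):
    """Conv -> BatchNorm -> SiLU (the standard detector conv unit)."""

    def __init__(self, cin, cout, k=1, s=1, p=None, g=1, act=True):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, s, p, g, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def forward(self, x):
        y = self.bn(self.conv(x))
        if self.act:
            CostTracker.add_elems(y.data[0].size)
            y = y.silu()
        return y


class HetConv2d(Module):
    """Heterogeneous-kernel convolution.

    Each of the `cout` filters applies KxK kernels to `cin/p` input
    channels and 1x1 kernels to the remaining `cin - cin/p`. The KxK
    subsets are interleaved by filter index (filter f covers channels
    c with c % p == f % p), so collectively the filter bank gives every
    input channel KxK spatial coverage.
    """

    def __init__(self, cin, cout, k=3, p_part=4, s=1, bias=False):
        super().__init__()
        if cin % p_part:
            raise ValueError(f"partition p={p_part} does not divide "
                             f"in_channels={cin}")
        self.cin, self.cout, self.k, self.p, self.s = cin, cout, k, p_part, s
        m3 = cin // p_part
        self.w3 = _kaiming((cout, m3, k, k), m3 * k * k + (cin - m3))
        self.w1 = (None if cin == m3 else
                   _kaiming((cout, cin - m3, 1, 1), m3 * k * k + (cin - m3)))
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None
        # filter indices grouped by residue class
        self._sel = [np.arange(r, cout, p_part) for r in range(p_part)]
        order = np.concatenate([s for s in self._sel if s.size])
        self._inv = np.argsort(order)

    def forward(self, x):
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {x.shape[1]}")
        p, k = self.p, self.k
        pieces = []
        all_c = np.arange(self.cin)
        for r in range(p):
            sel = self._sel[r]
            if sel.size == 0:
                continue
            y = ag.conv2d(x[:, r::p], self.w3[sel], None, self.s, autopad(k))
            CostTracker.add_macs(y.data[0, 0].size * sel.size * (self.cin // p) * k * k)
            if self.w1 is not None:
                comp = all_c[all_c % p != r]
                y1 = ag.conv2d(x[:, comp], self.w1[sel], None, self.s, 0)
                CostTracker.add_macs(y1.data[0, 0].size * sel.size * comp.size)
                y = y + y1
            pieces.append(y)
        out = pieces[0] if len(pieces) == 1 else ag.concat(pieces, axis=1)
        out = out[:, self._inv] if len(pieces) > 1 else out
        if self.bias is not None:
            out = out + self.bias.reshape(1, self.cout, 1, 1)
        return out


# --------------------------------------------------------------------
# composite blocks

class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, e=0.5, k=(3, 3)):
        super().__init__()
        ch = int(c2 * e)
        self.cv1 = ConvBN(c1, ch, k[0])
        self.cv2 = ConvBN(ch, c2, k[1])
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class DualHetBlock(Module):
    """Two chained HetConv layers (each + BN + SiLU) replacing the
    3x3/3x3 bottleneck; residual add when the shape allows."""

    def __init__(self, c1, c2, shortcut=True, p_part=4, k=3):
        super().__init__()
        self.h1 = HetConv2d(c1, c2, k, p_part)
        self.bn1 = BatchNorm2d(c2)
        self.h2 = HetConv2d(c2, c2, k, p_part)
        self.bn2 = BatchNorm2d(c2)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.bn1(self.h1(x))
        CostTracker.add_elems(y.data[0].size)
        y = y.silu()
        y = self.bn2(self.h2(y))
        CostTracker.add_elems(y.data[0].size)
        y = y.silu()
        return x + y if self.add else y


class C2f(Module):
    """Cross-stage-partial block: split, n sequential inner blocks on
    one branch, dense concatenation, 1x1 fusion."""

    def __init__(self, c1, c2, n=1, shortcut=False, block=None):
        super().__init__()
        self.c = int(c2 * 0.5)
        self.cv1 = ConvBN(c1, 2 * self.c, 1)
        self.cv2 = ConvBN((2 + n) * self.c, c2, 1)
        make = block or (lambda ci, co, sc: Bottleneck(ci, co, sc, e=1.0))
        self.m = ModuleList([make(self.c, self.c, shortcut) for _ in range(n)])

    def forward(self, x):
        y = self.cv1(x)
        ys = [y[:, :self.c], y[:, self.c:]]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(ag.concat(ys, axis=1))


class SCDown(Module):
    """Spatial-channel decoupled downsampling: 1x1 channel projection
    then depthwise stride-2 conv."""

    def __init__(self, c1, c2, k=3, s=2):
        super().__init__()
        self.cv1 = ConvBN(c1, c2, 1, 1)
        self.cv2 = ConvBN(c2, c2, k, s, g=c2, act=False)

    def forward(self, x):
        return self.cv2(self.cv1(x))


class SPPF(Module):
    def __init__(self, c1, c2, k=5):
        super().__init__()
        ch = c1 // 2
        self.cv1 = ConvBN(c1, ch, 1)
        self.cv2 = ConvBN(ch * 4, c2, 1)
        self.k = k

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(ag.maxpool2d(y[-1], self.k, 1, self.k // 2))
        return self.cv2(ag.concat(y, axis=1))


class Attention(Module):
    def __init__(self, dim, num_heads=8, attn_ratio=0.5):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        self.scale = self.key_dim ** -0.5
        h = dim + self.key_dim * num_heads * 2
        self.qkv = ConvBN(dim, h, 1, act=False)
        self.proj = ConvBN(dim, dim, 1, act=False)
        self.pe = ConvBN(dim, dim, 3, g=dim, act=False)

    def forward(self, x):
        b, c, hh, ww = x.shape
        n = hh * ww
        qkv = self.qkv(x).reshape(b, self.num_heads,
                                  self.key_dim * 2 + self.head_dim, n)
        q = qkv[:, :, :self.key_dim]
        k = qkv[:, :, self.key_dim:2 * self.key_dim]
        v = qkv[:, :, 2 * self.key_dim:]
        attn = ag.matmul(q.transpose(0, 1, 3, 2), k) * self.scale
        CostTracker.add_macs(self.num_heads * n * n * self.key_dim)
        attn = ag.softmax(attn, axis=-1)
        out = ag.matmul(v, attn.transpose(0, 1, 3, 2))
        CostTracker.add_macs(self.num_heads * n * n * self.head_dim)
        out = out.reshape(b, c, hh, ww) + self.pe(v.reshape(b, c, hh, ww))
        return self.proj(out)


class PSA(Module):
    """Partial self-attention: attention + FFN on half the channels."""

    def __init__(self, c, e=0.5):
        super().__init__()
        self.c = int(c * e)
        self.cv1 = ConvBN(c, 2 * self.c, 1)
        self.cv2 = ConvBN(2 * self.c, c, 1)
        self.attn = Attention(self.c, num_heads=max(self.c // 64, 1))
        self.ffn = Sequential(ConvBN(self.c, self.c * 2, 1),
                              ConvBN(self.c * 2, self.c, 1, act=False))

    def forward(self, x):
        y = self.cv1(x)
        a, b = y[:, :self.c], y[:, self.c:]
        b = b + self.attn(b)
        b = b + self.ffn(b)
        return self.cv2(ag.concat([a, b], axis=1))


class CIB(Module):
    """Compact inverted block (depthwise/pointwise sandwich)."""

    def __init__(self, c1, c2, shortcut=True, e=1.0):
        super().__init__()
        ch = int(c2 * e)
        self.seq = Sequential(
            ConvBN(c1, c1, 3, g=c1),
            ConvBN(c1, 2 * ch, 1),
            ConvBN(2 * ch, 2 * ch, 3, g=2 * ch),
            ConvBN(2 * ch, c2, 1),
            ConvBN(c2, c2, 3, g=c2),
        )
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.seq(x)
        return x + y if self.add else y


class Upsample(Module):
    def forward(self, x):
        return ag.upsample_nearest2(x)
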