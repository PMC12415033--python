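"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operator set the detector needs: grouped 2-D
convolution (im2col), batched matmul, nearest-neighbour upsampling, max
pooling, softmax, SiLU/sigmoid, slicing/concatenation and elementwise
arithmetic with broadcasting. Gradients are accumulated by topological
walk over the recorded tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "matmul", "conv2d", "maxpool2d",
           "upsample_nearest2", "softmax", "log_softmax", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- elementwise arithmetic --------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(-g * self.data / other.data ** 2,
                                                   other.shape))
            out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = _make(self.data ** p, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def exp(self):
        out = _make(np.exp(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def arctan(self):
        out = _make(np.arctan(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / (1.0 + self.data ** 2))
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = _make(np.abs(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * sign)
        return out

    def clamp_min(self, lo: float):
        mask = self.data >= lo
        out = _make(np.maximum(self.data, lo), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(s, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * s * (1 - s))
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(self.data * s, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * s * (1 + self.data * (1 - s)))
        return out

    # -- reductions / shape ------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bwd(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        out = _make(self.data.transpose(axes), (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out.requires_grad:
            def bwd(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
            out._backward = bwd
        return out


def _make(data: np.ndarray, parents) -> Tensor:
    out = Tensor(data)
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=1) -> Tensor:
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = bwd
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = _make(a.data @ b.data, (a, b))
    if out.requires_grad:
        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))
        out._backward = bwd
    return out


def softmax(x: Tensor, axis=-1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = _make(s, (x,))
    if out.requires_grad:
        def bwd(g):
            x._accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)))
        out._backward = bwd
    return out


def log_softmax(x: Tensor, axis=-1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    ls = z - np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = _make(ls, (x,))
    if out.requires_grad:
        def bwd(g):
            x._accumulate(g - np.exp(ls) * g.sum(axis=axis, keepdims=True))
        out._backward = bwd
    return out


def bce_with_logits(z: Tensor, target: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy on logits (numerically stable)."""
    t = np.asarray(target, dtype=np.float32)
    zd = z.data
    loss = np.maximum(zd, 0) - zd * t + np.log1p(np.exp(-np.abs(zd)))
    out = _make(loss, (z,))
    if out.requires_grad:
        sig = 1.0 / (1.0 + np.exp(-zd))
        out._backward = lambda g: z._accumulate(g * (sig - t))
    return out


# -- spatial ops -----------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - k) // stride + 1
    wo = (x.shape[3] - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]           # (b, c, ho, wo, k, k)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, xshape, k: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    b, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    out = np.zeros((b, c, hp, wp), dtype=np.float32)
    cols = cols.reshape(b, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, i, j]
    return out[:, :, pad:pad + h, pad:pad + w] if pad else out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution; x (B,C,H,W), w (Cout, C//g, K, K)."""
    bs, c, h, wd = x.shape
    cout, cg, k, _ = w.shape
    if c != cg * groups:
        raise ValueError(f"channel mismatch: input has {c} channels, "
                         f"kernel expects {cg * groups}")
    cols, ho, wo = _im2col(x.data, k, stride, pad)
    cols_g = cols.reshape(bs, groups, cg * k * k, ho * wo)
    wg = w.data.reshape(groups, cout // groups, cg * k * k)
    y = np.einsum("goc,bgcl->bgol", wg, cols_g, optimize=True)
    y = y.reshape(bs, cout, ho, wo)
    if b is not None:
        y = y + b.data.reshape(1, cout, 1, 1)
    out = _make(y, (x, w) if b is None else (x, w, b))
    if out.requires_grad:
        def bwd(g):
            gg = g.reshape(bs, groups, cout // groups, ho * wo)
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                dw = np.einsum("bgol,bgcl->goc", gg, cols_g, optimize=True)
                w._accumulate(dw.reshape(w.shape))
            if x.requires_grad:
                dcols = np.einsum("goc,bgol->bgcl", wg, gg, optimize=True)
                dcols = dcols.reshape(bs, c * k * k, ho * wo)
                x._accumulate(_col2im(dcols, x.shape, k, stride, pad, ho, wo))
        out._backward = bwd
    return out


def maxpool2d(x: Tensor, k: int, stride: int = 1, pad: int = 0) -> Tensor:
    b, c, h, w = x.shape
    xd = x.data
    if pad:
        xd = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                    constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xd, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(b, c, ho, wo, k * k)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = _make(y, (x,))
    if out.requires_grad:
        def bwd(g):
            full = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
            ii, jj = np.divmod(idx, k)
            bi, ci, oi, oj = np.indices(idx.shape)
            np.add.at(full, (bi, ci, oi * stride + ii, oj * stride + jj), g)
            x._accumulate(full[:, :, pad:pad + h, pad:pad + w] if pad else full)
        out._backward = bwd
    return out


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling."""
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = _make(y, (x,))
    if out.requires_grad:
        b, c, h, w = x.shape
        out._backward = lambda g: x._accumulate(
            g.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5)))
    return out
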