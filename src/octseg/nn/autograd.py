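"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the tensor operations the segmentation networks need:
elementwise arithmetic, matmul, reductions, reshaping/concatenation, 2-D
convolution (grouped, stride 1, 'same' padding), 2x2 stride-2 transposed
convolution, and 2x2 max pooling.  All data is float32; gradients are
accumulated by a topological backward sweep.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "concat", "conv2d", "conv_transpose2x2", "maxpool2x2",
    "softmax", "log_softmax",
]


def _as_f32(a) -> np.ndarray:
    arr = np.asarray(a)
    if arr.dtype != np.float32:
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


class Tensor:
    """A NumPy array plus the local backward rules that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents: tuple = ()):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in parents
        )
        # parents kept only while a grad path exists
        self._parents = tuple((p, f) for p, f in parents if p.requires_grad)

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autodiff ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p, _ in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = _as_f32(grad)
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, vjp in node._parents:
                contrib = vjp(g)
                if parent.grad is None:
                    parent.grad = contrib.astype(np.float32, copy=False)
                else:
                    parent.grad = parent.grad + contrib

    # -- elementwise arithmetic ---------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        o = Tensor._lift(other)
        return Tensor(self.data + o.data, parents=(
            (self, lambda g: _unbroadcast(g, self.shape)),
            (o, lambda g: _unbroadcast(g, o.shape)),
        ))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=((self, lambda g: -g),))

    def __sub__(self, other):
        o = Tensor._lift(other)
        return Tensor(self.data - o.data, parents=(
            (self, lambda g: _unbroadcast(g, self.shape)),
            (o, lambda g: _unbroadcast(-g, o.shape)),
        ))

    def __rsub__(self, other):
        return Tensor._lift(other) - self

    def __mul__(self, other):
        o = Tensor._lift(other)
        return Tensor(self.data * o.data, parents=(
            (self, lambda g: _unbroadcast(g * o.data, self.shape)),
            (o, lambda g: _unbroadcast(g * self.data, o.shape)),
        ))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = Tensor._lift(other)
        return Tensor(self.data / o.data, parents=(
            (self, lambda g: _unbroadcast(g / o.data, self.shape)),
            (o, lambda g: _unbroadcast(-g * self.data / (o.data ** 2), o.shape)),
        ))

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        return Tensor(self.data ** p, parents=(
            (self, lambda g: g * p * self.data ** (p - 1)),
        ))

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=((self, lambda g, o=out: g * o),))

    def log(self):
        return Tensor(np.log(self.data), parents=(
            (self, lambda g: g / self.data),
        ))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor(out, parents=((self, lambda g, o=out: g / (2.0 * o)),))

    def sigmoid(self):
        # numerically stable logistic
        x = self.data
        out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                       np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = out.astype(np.float32)
        return Tensor(out, parents=((self, lambda g, o=out: g * o * (1.0 - o)),))

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=(
            (self, lambda g, m=mask: g * m),
        ))

    # -- reductions / shaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.shape).astype(np.float32)
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.shape).astype(np.float32)

        return Tensor(out, parents=((self, vjp),))

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor(self.data.reshape(shape), parents=(
            (self, lambda g: g.reshape(self.shape)),
        ))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(axes), parents=(
            (self, lambda g: g.transpose(inv)),
        ))

    def __getitem__(self, idx):
        def vjp(g):
            out = np.zeros(self.shape, dtype=np.float32)
            out[idx] = g
            return out

        return Tensor(self.data[idx], parents=((self, vjp),))

    def matmul(self, other: "Tensor"):
        o = Tensor._lift(other)
        return Tensor(self.data @ o.data, parents=(
            (self, lambda g: g @ o.data.T),
            (o, lambda g: self.data.T @ g),
        ))

    __matmul__ = matmul


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor(out, parents=tuple(
        (t, make_vjp(i)) for i, t in enumerate(tensors)
    ))


def softmax(x: Tensor, axis: int) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, no grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> contiguous (N*Ho*Wo, C*kh*kw) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # N,C,Ho,Wo,kh,kw
    n, c, ho, wo = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n * ho * wo, c * kh * kw)


def _corr2d_cols(cols: np.ndarray, w: np.ndarray, out_shape) -> np.ndarray:
    """GEMM path: patch matrix times flattened kernels (single group)."""
    n, co, ho, wo = out_shape
    out = cols @ w.reshape(co, -1).T           # (N*Ho*Wo, Co)
    return np.ascontiguousarray(
        out.reshape(n, ho, wo, co).transpose(0, 3, 1, 2))


def _corr2d(x: np.ndarray, w: np.ndarray, pad: int, groups: int,
            cols_out: list | None = None) -> np.ndarray:
    """Grouped stride-1 cross-correlation; x (N,Ci,H,W), w (Co,Ci/g,kh,kw).

    If ``cols_out`` is given, the per-group im2col matrices are appended to
    it so the backward pass can reuse them.
    """
    n, ci, h, wd = x.shape
    co, cig, kh, kw = w.shape
    cog = co // groups
    ho, wo = h + 2 * pad - kh + 1, wd + 2 * pad - kw + 1
    outs = []
    for g in range(groups):
        xg = x[:, g * cig:(g + 1) * cig] if groups > 1 else x
        cols = _im2col(xg, kh, kw, pad)
        if cols_out is not None:
            cols_out.append(cols)
        wg = w[g * cog:(g + 1) * cog]
        outs.append(_corr2d_cols(cols, wg, (n, cog, ho, wo)))
    return outs[0] if groups == 1 else np.concatenate(outs, axis=1)


def _flip_swap(w: np.ndarray, groups: int) -> np.ndarray:
    """180-degree-flip kernels and swap in/out channel roles per group."""
    co = w.shape[0]
    cog = co // groups
    wf = w[:, :, ::-1, ::-1]
    return np.ascontiguousarray(np.concatenate(
        [wf[g * cog:(g + 1) * cog].transpose(1, 0, 2, 3)
         for g in range(groups)], axis=0))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int,
           groups: int = 1) -> Tensor:
    cols_cache: list[np.ndarray] = []
    out = _corr2d(x.data, w.data, padding, groups,
                  cols_out=cols_cache if w.requires_grad else None)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)
    co, cig, kh, kw = w.shape
    cog = co // groups

    def vjp_x(g):
        return _corr2d(np.ascontiguousarray(g), _flip_swap(w.data, groups),
                       kh - 1 - padding, groups)

    def vjp_w(g):
        n = g.shape[0]
        parts = []
        for gi in range(groups):
            dg = g[:, gi * cog:(gi + 1) * cog]
            dmat = np.ascontiguousarray(
                dg.transpose(0, 2, 3, 1)).reshape(-1, cog)
            dw = dmat.T @ cols_cache[gi]        # (Cog, Cig*kh*kw)
            parts.append(dw.reshape(cog, cig, kh, kw))
        return (parts[0] if groups == 1
                else np.concatenate(parts, axis=0)).astype(np.float32)

    parents = [(x, vjp_x), (w, vjp_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(out, parents=tuple(parents))


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Stride-2, kernel-2 transposed convolution (the UNet upsampler).

    Non-overlapping output tiles make this an einsum; w has shape (Ci,Co,2,2).
    """
    n, ci, h, ww_ = x.shape
    co = w.shape[1]
    out = np.einsum("nchw,coij->nohiwj", x.data, w.data,
                    optimize=True).reshape(n, co, 2 * h, 2 * ww_)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)
    out = np.ascontiguousarray(out, dtype=np.float32)

    def vjp_x(g):
        gr = g.reshape(n, co, h, 2, ww_, 2)
        return np.einsum("nohiwj,coij->nchw", gr, w.data, optimize=True)

    def vjp_w(g):
        gr = g.reshape(n, co, h, 2, ww_, 2)
        return np.einsum("nchw,nohiwj->coij", x.data, gr, optimize=True)

    parents = [(x, vjp_x), (w, vjp_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(out, parents=tuple(parents))


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = (xr == out[:, :, :, None, :, None])
    cnt = mask.sum(axis=(3, 5), keepdims=True)

    def vjp(g):
        gg = g[:, :, :, None, :, None] * mask / cnt
        return gg.reshape(n, c, h, w).astype(np.float32)

    return Tensor(out, parents=((x, vjp),))
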