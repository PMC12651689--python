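"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the primitives the segmentation network needs:
elementwise arithmetic, matmul, reductions, shape ops, sigmoid /
leaky-ReLU, 2D convolution (stride 1, arbitrary padding), 2x2 stride-2
transposed convolution, and 2x2 max pooling.  Gradients flow through a
dynamically built tape; :meth:`Tensor.backward` walks it in reverse
topological order.

The working dtype is a module-level default (float32 — single-precision
matmuls are about twice as fast on one CPU and training is insensitive
to the difference); finite-difference gradient checks switch it to
float64 via :func:`set_default_dtype`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "as_tensor", "set_default_dtype"]

DTYPE = np.dtype(np.float32)


def set_default_dtype(dt) -> np.dtype:
    """Set the dtype newly created tensors use; returns the previous one."""
    global DTYPE
    previous = DTYPE
    DTYPE = np.dtype(dt)
    return previous


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape machinery for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0))

        return Tensor._make(self.data ** e, (self,), backward)

    # -- transcendental ------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * 0.5 / o)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o * (1.0 - o))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return Tensor._make(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.1):
        mask = self.data > 0
        scale = np.where(mask, 1.0, slope)

        def backward(g, a=self, s=scale):
            if a.requires_grad:
                a._accum(g * s)

        return Tensor._make(self.data * scale, (self,), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            if ax is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if kd else np.expand_dims(g, ax)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max over one axis; ties route the gradient to the first maximum."""
        out_data = self.data.max(axis=axis, keepdims=True)
        idx = self.data.argmax(axis=axis)
        onehot = np.zeros_like(self.data)
        np.put_along_axis(onehot, np.expand_dims(idx, axis), 1.0, axis=axis)

        def backward(g, a=self, oh=onehot, ax=axis, kd=keepdims):
            if a.requires_grad:
                gg = g if kd else np.expand_dims(g, ax)
                a._accum(oh * gg)

        return Tensor._make(out_data if keepdims else out_data.squeeze(axis),
                            (self,), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g, a=self, s=old):
            if a.requires_grad:
                a._accum(g.reshape(s))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g, a=self, i=inv):
            if a.requires_grad:
                a._accum(g.transpose(i))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    # -- linear algebra ------------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- convolution primitives ---------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               padding: int = 0):
        """Stride-1 cross-correlation.  x: (N,C,H,W), weight: (O,C,kh,kw)."""
        w = weight
        x = self
        n, c, h, wd = x.shape
        o, c2, kh, kw = w.shape
        if c != c2:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
        p = padding
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
        cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,Ho,Wo,kh,kw
        ho, wo = cols.shape[2], cols.shape[3]
        cols2 = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
        wr = w.data.reshape(o, c * kh * kw)
        out = (cols2 @ wr.T).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
        if bias is not None:
            out = out + bias.data.reshape(1, o, 1, 1)
        parents = (x, w) if bias is None else (x, w, bias)

        def backward(g, a=x, ww=w, bb=bias, cc=cols2):
            gr = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
            if ww.requires_grad:
                ww._accum((gr.T @ cc).reshape(o, c, kh, kw))
            if bb is not None and bb.requires_grad:
                bb._accum(g.sum(axis=(0, 2, 3)))
            if a.requires_grad:
                # full correlation of g with spatially flipped, transposed kernel
                pg = kh - 1 - p
                gp = np.pad(g, ((0, 0), (0, 0), (pg, pg), (pg, pg))) if pg else g
                wflip = ww.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # C,O,kh,kw
                gcols = sliding_window_view(gp, (kh, kw), axis=(2, 3))
                hh, wwd = gcols.shape[2], gcols.shape[3]
                gcols2 = gcols.transpose(0, 2, 3, 1, 4, 5).reshape(
                    n * hh * wwd, o * kh * kw)
                gx = (gcols2 @ wflip.reshape(c, o * kh * kw).T).reshape(
                    n, hh, wwd, c).transpose(0, 3, 1, 2)
                a._accum(gx)

        return Tensor._make(out, parents, backward)

    def conv_transpose2x2(self, weight: "Tensor", bias: "Tensor | None" = None):
        """2x2-kernel, stride-2 transposed convolution (non-overlapping).

        x: (N,C,H,W), weight: (C,O,2,2) -> (N,O,2H,2W).
        """
        x = self
        w = weight
        n, c, h, wd = x.shape
        c2, o, kh, kw = w.shape
        if c != c2 or (kh, kw) != (2, 2):
            raise ValueError("conv_transpose2x2 expects weight (C,O,2,2) matching input C")
        y6 = np.einsum("nchw,coab->nohawb", x.data, w.data, optimize=True)
        out = y6.reshape(n, o, 2 * h, 2 * wd)
        if bias is not None:
            out = out + bias.data.reshape(1, o, 1, 1)
        parents = (x, w) if bias is None else (x, w, bias)

        def backward(g, a=x, ww=w, bb=bias):
            g6 = g.reshape(n, o, h, 2, wd, 2)
            if a.requires_grad:
                a._accum(np.einsum("nohawb,coab->nchw", g6, ww.data, optimize=True))
            if ww.requires_grad:
                ww._accum(np.einsum("nchw,nohawb->coab", a.data, g6, optimize=True))
            if bb is not None and bb.requires_grad:
                bb._accum(g.sum(axis=(0, 2, 3)))

        return Tensor._make(out, parents, backward)

    def maxpool2x2(self):
        """2x2 stride-2 max pooling; ties route the gradient to the first max."""
        x = self
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
        hh, ww = h // 2, w // 2
        windows = x.data.reshape(n, c, hh, 2, ww, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, hh, ww, 4)
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

        def backward(g, a=x, ii=idx):
            if not a.requires_grad:
                return
            gw = np.zeros((n, c, hh, ww, 4), dtype=g.dtype)
            np.put_along_axis(gw, ii[..., None], g[..., None], axis=-1)
            gx = gw.reshape(n, c, hh, ww, 2, 2).transpose(
                0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
            a._accum(gx)

        return Tensor._make(out, (x,), backward)

    # -- tape ----------------------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=self.data.dtype).copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep at 500-epoch scale
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list, axis: int = 1) -> Tensor:
    """Concatenate along `axis` with gradient splitting."""
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, off=offsets, ax=axis):
        for t, lo, hi in zip(ts, off[:-1], off[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)
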