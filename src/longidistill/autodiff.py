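"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides the handful of differentiable operations the temporal networks in
this package need: broadcast arithmetic, matmul, the sigmoid/tanh/ReLU
nonlinearities, log/exp, reductions, slicing, stacking, and a sliding-window
gather used by the 1-D convolution.  Gradients flow through a dynamically
recorded tape; ``Tensor.backward`` runs a topological sweep.

The engine is deliberately small: every op's backward rule is written out
explicitly and verified against central finite differences in the test
suite.  It is not a general-purpose framework — only what the models here
exercise is implemented.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "no_grad",
    "concatenate",
    "stack",
    "split",
    "conv1d",
    "sliding_windows",
    "sigmoid",
    "tanh",
    "relu",
    "softmax",
    "grad_enabled",
]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the context (inference / teacher passes)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")
    __array_priority__ = 100  # ensure ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False, _parents: Sequence["Tensor"] = (),
                 _backward: Callable[[np.ndarray], None] | None = None, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and grad_enabled()
        self._backward = _backward
        self._parents = tuple(_parents)
        self.name = name

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        # gradients are never mutated in place, so no defensive copy needed
        if self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative topological sort (graphs from long sequences can be deep)
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        stack_.clear()
        while visiting:
            node, processed = visiting.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visiting.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    visiting.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data
        out = _make(out_data, (self, other))
        if out.requires_grad:
            def _bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g, a.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(g, b.shape))
            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            def _bw(g, a=self):
                if a.requires_grad:
                    a._accumulate(-g)
            out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def _bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g * b.data, a.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(g * a.data, b.shape))
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def _bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g / b.data, a.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(-g * a.data / b.data ** 2, b.shape))
            out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = _make(self.data ** p, (self,))
        if out.requires_grad:
            def _bw(g, a=self):
                a._accumulate(g * p * a.data ** (p - 1))
            out._backward = _bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out.requires_grad:
            def _bw(g, a=self, b=other):
                if a.requires_grad:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                    a._accumulate(_unbroadcast(ga, a.shape))
                if b.requires_grad:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                    b._accumulate(_unbroadcast(gb, b.shape))
            out._backward = _bw
        return out

    # -- shaping ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            def _bw(g, a=self):
                a._accumulate(g.reshape(a.shape))
            out._backward = _bw
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = _make(self.data.transpose(axes), (self,))
        if out.requires_grad:
            inv = np.argsort(axes) if axes else None
            def _bw(g, a=self, inv=inv):
                a._accumulate(g.transpose(inv))
            out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out.requires_grad:
            def _bw(g, a=self, idx=idx):
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accumulate(full)
            out._backward = _bw
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def _bw(g, a=self):
                if axis is None:
                    a._accumulate(np.broadcast_to(g, a.shape).copy())
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    a._accumulate(np.broadcast_to(gg, a.shape).copy())
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = _make(out_data, (self,))
        if out.requires_grad:
            def _bw(g, a=self):
                if axis is None:
                    mask = (a.data == out_data)
                    a._accumulate(mask * (g / mask.sum()))
                else:
                    expanded = out_data if keepdims else np.expand_dims(out_data, axis)
                    mask = (a.data == expanded)
                    counts = mask.sum(axis=axis, keepdims=True)
                    gg = g if keepdims else np.expand_dims(g, axis)
                    a._accumulate(mask * gg / counts)
            out._backward = _bw
        return out

    # -- elementwise functions --------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        out = _make(out_data, (self,))
        if out.requires_grad:
            def _bw(g, a=self):
                a._accumulate(g * out_data)
            out._backward = _bw
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out.requires_grad:
            def _bw(g, a=self):
                a._accumulate(g / a.data)
            out._backward = _bw
        return out

    def clip(self, lo: float, hi: float):
        out = _make(np.clip(self.data, lo, hi), (self,))
        if out.requires_grad:
            inside = (self.data > lo) & (self.data < hi)
            def _bw(g, a=self):
                a._accumulate(g * inside)
            out._backward = _bw
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    req = grad_enabled() and any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _parents=[p for p in parents if p.requires_grad] if req else ())


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))
    out = _make(out_data, (x,))
    if out.requires_grad:
        def _bw(g, a=x):
            a._accumulate(g * out_data * (1.0 - out_data))
        out._backward = _bw
    return out


def tanh(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out_data = np.tanh(x.data)
    out = _make(out_data, (x,))
    if out.requires_grad:
        def _bw(g, a=x):
            a._accumulate(g * (1.0 - out_data ** 2))
        out._backward = _bw
    return out


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = _make(np.maximum(x.data, 0.0), (x,))
    if out.requires_grad:
        pos = x.data > 0
        def _bw(g, a=x):
            a._accumulate(g * pos)
        out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Normalized exponential along ``axis`` (numerically shifted)."""
    x = _as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)
    out = _make(out_data, (x,))
    if out.requires_grad:
        def _bw(g, a=x):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - dot))
        out._backward = _bw
    return out


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in ts], axis=axis), ts)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in ts]
        splits = np.cumsum(sizes)[:-1]
        def _bw(g, ts=ts):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(ts, parts):
                if t.requires_grad:
                    t._accumulate(p)
        out._backward = _bw
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out = _make(np.stack([t.data for t in ts], axis=axis), ts)
    if out.requires_grad:
        def _bw(g, ts=ts):
            for i, t in enumerate(ts):
                if t.requires_grad:
                    t._accumulate(np.take(g, i, axis=axis))
        out._backward = _bw
    return out


def split(x: Tensor, n_sections: int, axis: int = -1) -> list[Tensor]:
    """Split into equal sections along ``axis`` (inverse of concatenate)."""
    x = _as_tensor(x)
    axis = axis % x.ndim
    if x.shape[axis] % n_sections:
        raise ValueError("axis length not divisible by n_sections")
    size = x.shape[axis] // n_sections
    outs = []
    for s in range(n_sections):
        sl = tuple(slice(None) if a != axis else slice(s * size, (s + 1) * size)
                   for a in range(x.ndim))
        part = _make(x.data[sl], (x,))
        if part.requires_grad:
            def _bw(g, a=x, sl=sl):
                full = np.zeros_like(a.data)
                full[sl] = g
                a._accumulate(full)
            part._backward = _bw
        outs.append(part)
    return outs


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int) -> Tensor:
    """Valid 1-D cross-correlation along the last axis.

    x: (N, C_in, F), w: (C_out, C_in, k), b: (C_out,) ->
    (N, C_out, L) with L = (F - k)//stride + 1.  Forward contracts over a
    zero-copy strided window view; backward scatters with k vectorized adds.
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    n, c_in, f = x.shape
    c_out, _, k = w.shape
    if f < k:
        raise ValueError(f"input length {f} shorter than kernel {k}")
    length = (f - k) // stride + 1
    s0, s1, s2 = x.data.strides
    xw = np.lib.stride_tricks.as_strided(
        x.data, (n, c_in, length, k), (s0, s1, s2 * stride, s2))
    out_data = np.einsum("nclk,ock->nol", xw, w.data, optimize=True)
    out_data += b.data[None, :, None]
    out = _make(out_data, (x, w, b))
    if out.requires_grad:
        def _bw(g):
            if w.requires_grad:
                w._accumulate(np.einsum("nol,nclk->ock", g, xw, optimize=True))
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2)))
            if x.requires_grad:
                gy = np.einsum("nol,ock->nclk", g, w.data, optimize=True)
                dx = np.zeros_like(x.data)
                hi = (length - 1) * stride + 1
                for j in range(k):
                    dx[:, :, j:j + hi:stride] += gy[:, :, :, j]
                x._accumulate(dx)
        out._backward = _bw
    return out


def sliding_windows(x: Tensor, size: int, stride: int, axis: int = -1) -> Tensor:
    """Gather overlapping windows along ``axis``.

    Output inserts a trailing window dimension: for a (..., F) input the
    result is (..., n_windows, size) with n_windows = (F - size)//stride + 1.
    Backward scatter-adds window gradients back to source positions.
    """
    x = _as_tensor(x)
    axis = axis % x.ndim
    length = x.shape[axis]
    if length < size:
        raise ValueError(f"input length {length} shorter than window size {size}")
    n_win = (length - size) // stride + 1
    starts = np.arange(n_win) * stride
    idx = starts[:, None] + np.arange(size)[None, :]  # (n_win, size)
    out_data = np.take(x.data, idx.reshape(-1), axis=axis)
    new_shape = x.shape[:axis] + (n_win, size) + x.shape[axis + 1:]
    out_data = out_data.reshape(new_shape)
    out = _make(out_data, (x,))
    if out.requires_grad:
        def _bw(g, a=x):
            flat = g.reshape(a.shape[:axis] + (n_win * size,) + a.shape[axis + 1:])
            full = np.zeros_like(a.data)
            moved_full = np.moveaxis(full, axis, 0)
            moved_g = np.moveaxis(flat, axis, 0)
            np.add.at(moved_full, idx.reshape(-1), moved_g)
            a._accumulate(np.moveaxis(moved_full, 0, axis))
        out._backward = _bw
    return out
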