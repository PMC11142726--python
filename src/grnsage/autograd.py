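"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps a float64 ndarray
and records, for every operation, a closure that routes the output gradient
back to its parents.  ``backward()`` runs a topological sort of the recorded
graph and accumulates gradients into every tensor created with
``requires_grad=True``.

Only the operations the regulatory-edge model needs are provided: broadcast
arithmetic, matmul, the ReLU/tanh/sigmoid/log/exp family, reductions,
reshaping/indexing/concatenation, 2-D convolution and max-pooling.  All
computation is float64, which is what makes finite-difference gradient
checks meaningful.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "maxpool2d", "segment_max"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
            out.requires_grad = True
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: training graphs can be deep
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- basic properties --------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self.data, other.data
        out_data = a @ b

        def backward(g):
            if a.ndim == 1 and b.ndim == 1:  # dot product, g scalar
                self._accum(g * b)
                other._accum(g * a)
            elif a.ndim == 1:  # (k,) @ (k, n) -> (n,)
                self._accum(b @ g)
                other._accum(np.outer(a, g))
            elif b.ndim == 1:  # (m, k) @ (k,) -> (m,)
                self._accum(np.outer(g, b))
                other._accum(a.T @ g)
            else:
                self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
                other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.abs(self.data))),
            np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))),
        )

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def softplus(self):
        """log(1 + e^x), computed stably; gradient is sigmoid(x)."""
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.abs(self.data))),
            np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))),
        )

        def backward(g):
            self._accum(g * sig)

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g / (2.0 * out_data))

        return Tensor._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the unclamped region."""
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, axes)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def broadcast_to(self, shape):
        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))

        return Tensor._make(np.broadcast_to(self.data, shape).copy(), (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, key, g)

        return Tensor._make(out_data.copy(), (self,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Valid (no padding), stride-1 cross-correlation.

    x: (B, C, H, W); w: (F, C, kh, kw); b: (F,) -> out (B, F, Ho, Wo).
    """
    B, C, H, W = x.data.shape
    F, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, kernel {Cw}")
    if kh > H or kw > W:
        raise ValueError(f"conv2d kernel ({kh}x{kw}) exceeds input extent ({H}x{W})")
    Ho, Wo = H - kh + 1, W - kw + 1
    windows = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(2, 3))
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(F, C * kh * kw)
    out2d = cols @ wmat.T
    if b is not None:
        out2d = out2d + b.data
    out_data = out2d.reshape(B, Ho, Wo, F).transpose(0, 3, 1, 2)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g2d = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, F)
        w._accum((g2d.T @ cols).reshape(F, C, kh, kw))
        if b is not None:
            b._accum(g2d.sum(axis=0))
        dcols = (g2d @ wmat).reshape(B, Ho, Wo, C, kh, kw)
        dx = np.zeros_like(x.data)
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i : i + Ho, j : j + Wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        x._accum(dx)

    return Tensor._make(out_data, parents, backward)


def maxpool2d(x: Tensor, ph: int, pw: int) -> Tensor:
    """Non-overlapping max pooling; trailing remainder rows/columns dropped."""
    B, C, H, W = x.data.shape
    Ho, Wo = H // ph, W // pw
    if Ho < 1 or Wo < 1:
        raise ValueError(f"pool window ({ph}x{pw}) exceeds input extent ({H}x{W})")
    cropped = x.data[:, :, : Ho * ph, : Wo * pw]
    windows = cropped.reshape(B, C, Ho, ph, Wo, pw).transpose(0, 1, 2, 4, 3, 5)
    flat = windows.reshape(B, C, Ho, Wo, ph * pw)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, arg[..., None], g[..., None], axis=-1)
        dx = np.zeros_like(x.data)
        dx[:, :, : Ho * ph, : Wo * pw] = (
            dflat.reshape(B, C, Ho, Wo, ph, pw).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho * ph, Wo * pw)
        )
        x._accum(dx)

    return Tensor._make(out_data, (x,), backward)


def segment_max(x: Tensor, segments: Sequence[Sequence[int]]) -> Tensor:
    """Row-wise elementwise max over index groups; empty groups give zeros.

    Gradient is routed to the argmax row of each group (first on ties).
    """
    n_out = len(segments)
    d = x.data.shape[1]
    out_data = np.zeros((n_out, d))
    argrows = np.full((n_out, d), -1, dtype=np.intp)
    for v, idx in enumerate(segments):
        if len(idx) == 0:
            continue
        idx = np.asarray(idx, dtype=np.intp)
        block = x.data[idx]
        a = block.argmax(axis=0)
        out_data[v] = block[a, np.arange(d)]
        argrows[v] = idx[a]

    def backward(g):
        dx = np.zeros_like(x.data)
        valid = argrows >= 0
        cols = np.broadcast_to(np.arange(d), argrows.shape)
        np.add.at(dx, (argrows[valid], cols[valid]), g[valid])
        x._accum(dx)

    return Tensor._make(out_data, (x,), backward)
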