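"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations applied to
it on a tape; :meth:`Tensor.backward` replays the tape in reverse topological
order and accumulates gradients.  The op set is exactly what the spatiotemporal
predictor and the policy/value networks need: broadcast arithmetic, matmul,
the sigmoid/tanh/leaky-relu nonlinearities, exp/log, reductions, reshaping,
gather (fancy indexing, used by im2col convolution), zero padding and
axis-wise max (used by max pooling).

Shapes stay small here (desk-scale grids, tens of hidden units), so clarity
wins over throughput; everything is float64 so oracle comparisons at 1e-10
tolerances are meaningful.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "stack", "minimum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- basic protocol ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    # -- graph construction helpers ---------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, _parents=parents if req else (),
                      _backward=backward if req else None)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / b.data**2, b.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        p = float(p)

        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g * p * a.data ** (p - 1.0))

        return Tensor._make(self.data**p, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            ad, bd = a.data, b.data
            if a.requires_grad:
                if bd.ndim == 1:
                    ga = np.multiply.outer(g, bd) if g.ndim else g * bd
                elif ad.ndim == 1:
                    ga = g @ np.swapaxes(bd, -1, -2)
                else:
                    ga = g @ np.swapaxes(bd, -1, -2)
                a._accumulate(_unbroadcast(np.asarray(ga), a.shape))
            if b.requires_grad:
                if ad.ndim == 1:
                    gb = np.multiply.outer(ad, g) if g.ndim else ad * g
                elif bd.ndim == 1:
                    gb = np.swapaxes(ad, -1, -2) @ g
                else:
                    gb = np.swapaxes(ad, -1, -2) @ g
                b._accumulate(_unbroadcast(np.asarray(gb), b.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities -----------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._accumulate(g * od)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._accumulate(g * (1.0 - od**2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        out_data = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.abs(self.data))),
            np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))),
        )

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._accumulate(g * od * (1.0 - od))

        return Tensor._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.01) -> "Tensor":
        mask = np.where(self.data > 0, 1.0, slope)

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accumulate(g * m)

        return Tensor._make(self.data * mask, (self,), backward)

    def relu(self) -> "Tensor":
        return self.leaky_relu(0.0)

    def sqrt(self) -> "Tensor":
        return self**0.5

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is zero outside [lo, hi] (straight-through inside)."""
        inside = ((self.data >= lo) & (self.data <= hi)).astype(np.float64)

        def backward(g, a=self, m=inside):
            if a.requires_grad:
                a._accumulate(g * m)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            g = np.asarray(g)
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.size if axis is None else (
            np.prod([self.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Axis-wise maximum; gradient routed to the (first) argmax."""
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        # split ties evenly so the gradient check stays symmetric
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def backward(g, a=self, m=mask, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            g = np.asarray(g)
            if not kd:
                g = np.expand_dims(g, ax)
            a._accumulate(g * m)

        res = out_data if keepdims else out_data.squeeze(axis=axis)
        return Tensor._make(res, (self,), backward)

    # -- shape ops -------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(np.asarray(g).reshape(a.shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g, a=self, inv=tuple(inv)):
            if a.requires_grad:
                a._accumulate(np.transpose(np.asarray(g), inv))

        return Tensor._make(np.transpose(self.data, axes), (self,), backward)

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def __getitem__(self, idx) -> "Tensor":
        def backward(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accumulate(full)

        return Tensor._make(self.data[idx], (self,), backward)

    def pad2d(self, pad: int, axes: tuple[int, int] = (-3, -2)) -> "Tensor":
        """Zero-pad two spatial axes by ``pad`` on each side."""
        if pad == 0:
            return self
        axes = tuple(a % self.ndim for a in axes)
        widths = [(pad, pad) if a in axes else (0, 0) for a in range(self.ndim)]
        sl = tuple(slice(pad, -pad) if a in axes else slice(None)
                   for a in range(self.ndim))

        def backward(g, a=self, sl=sl):
            if a.requires_grad:
                a._accumulate(np.asarray(g)[sl])

        return Tensor._make(np.pad(self.data, widths), (self,), backward)

    # -- softmax / log-softmax (stable, composite backward) --------------------
    def log_softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        sm = np.exp(out_data)

        def backward(g, a=self, sm=sm, ax=axis):
            if a.requires_grad:
                g = np.asarray(g)
                a._accumulate(g - sm * g.sum(axis=ax, keepdims=True))

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        return self.log_softmax(axis=axis).exp()

    # -- backward pass -----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    data = np.concatenate([t.data for t in tensors], axis=axis)

    def backward(g, ts=tensors, offs=offsets, ax=axis):
        g = np.asarray(g)
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(data, tuple(tensors), backward)


def minimum(a: Tensor, b: Tensor) -> Tensor:
    """Element-wise minimum; the gradient follows the selected branch."""
    a, b = as_tensor(a), as_tensor(b)
    take_a = (a.data <= b.data).astype(np.float64)

    def backward(g, a=a, b=b, m=take_a):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * m, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (1.0 - m), b.shape))

    return Tensor._make(np.minimum(a.data, b.data), (a, b), backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g, ts=tensors, ax=axis):
        g = np.asarray(g)
        for k, t in enumerate(ts):
            if t.requires_grad:
                t._accumulate(np.take(g, k, axis=ax))

    return Tensor._make(data, tuple(tensors), backward)
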