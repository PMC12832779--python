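"""Minimal reverse-mode automatic differentiation over numpy arrays.

The compute stack is CPU-only by design: volumes are small (<= 128^3) and the
scaled-down configurations used in tests train in minutes. All floating point
data is float32.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

DTYPE = np.float32

_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (inference paths)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        if x.dtype != DTYPE:
            return x.astype(DTYPE)
        return x
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
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
    """An ndarray with an optional autograd tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "retain_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self.retain_grad = False
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph machinery ----------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(DTYPE, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free intermediate gradients as soon as they are consumed
            if node._parents and not node.retain_grad:
                node.grad = None

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out = Tensor(self.data + other.data)
        _attach(out, (self, other), lambda g: (
            _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)))
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data * other.data)
        _attach(out, (self, other), lambda g: (
            _unbroadcast(g * other.data, self.shape),
            _unbroadcast(g * self.data, other.shape)))
        return out

    __rmul__ = __mul__

    def __neg__(self):
        out = Tensor(-self.data)
        _attach(out, (self,), lambda g: (-g,))
        return out

    def __sub__(self, other):
        other = _wrap(other)
        out = Tensor(self.data - other.data)
        _attach(out, (self, other), lambda g: (
            _unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)))
        return out

    def __rsub__(self, other):
        return _wrap(other) - self

    def __truediv__(self, other):
        other = _wrap(other)
        out = Tensor(self.data / other.data)
        _attach(out, (self, other), lambda g: (
            _unbroadcast(g / other.data, self.shape),
            _unbroadcast(-g * self.data / (other.data ** 2), other.shape)))
        return out

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p)
        _attach(out, (self,), lambda g: (g * p * self.data ** (p - 1),))
        return out

    def __matmul__(self, other):
        other = _wrap(other)
        out = Tensor(np.matmul(self.data, other.data))

        def bw(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        _attach(out, (self, other), bw)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx])
        parts = idx if isinstance(idx, tuple) else (idx,)
        fancy = any(isinstance(p, (np.ndarray, list)) for p in parts)

        def bw(g):
            full = np.zeros_like(self.data)
            if fancy:
                np.add.at(full, idx, g)  # duplicate indices accumulate
            else:
                full[idx] += g
            return (full,)

        _attach(out, (self,), bw)
        return out

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape))
        _attach(out, (self,), lambda g: (g.reshape(self.shape),))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes))
        _attach(out, (self,), lambda g: (g.transpose(inv),))
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).astype(DTYPE),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for a in sorted(a % self.ndim for a in ax):
                    g = np.expand_dims(g, a)
            return (np.broadcast_to(g, self.shape).astype(DTYPE),)

        _attach(out, (self,), bw)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data))
        _attach(out, (self,), lambda g: (g * out.data,))
        return out

    def log(self):
        out = Tensor(np.log(self.data))
        _attach(out, (self,), lambda g: (g / self.data,))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)))
        _attach(out, (self,), lambda g: (g * out.data * (1.0 - out.data),))
        return out

    def leaky_relu(self, slope: float = 0.01):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data))
        _attach(out, (self,), lambda g: (
            g * np.where(self.data > 0, 1.0, slope).astype(DTYPE),))
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data))
        _attach(out, (self,), lambda g: (g * (1.0 - out.data ** 2),))
        return out

    def gelu(self):
        """tanh-approximation GELU."""
        c = 0.7978845608028654  # sqrt(2/pi)
        inner = (c * (self + 0.044715 * self * self * self)).tanh()
        return 0.5 * self * (1.0 + inner)

    def relu(self):
        out = Tensor(np.maximum(self.data, 0))
        _attach(out, (self,), lambda g: (g * (self.data > 0),))
        return out

    def clamp(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi))
        mask = ((self.data >= lo) & (self.data <= hi)).astype(DTYPE)
        _attach(out, (self,), lambda g: (g * mask,))
        return out

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s)

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        _attach(out, (self,), bw)
        return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _attach(out: Tensor, parents: tuple[Tensor, ...], grad_fn) -> None:
    """Register the backward closure if any parent participates in the tape."""
    if not _grad_enabled:
        return
    if not any(p.requires_grad or p._parents for p in parents):
        return
    out.requires_grad = True
    out._parents = parents

    def backward(g: np.ndarray) -> None:
        grads = grad_fn(g)
        for p, gp in zip(parents, grads):
            if gp is not None and (p.requires_grad or p._parents):
                p._accumulate(_as_array(gp))

    out._backward = backward


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    _attach(out, tuple(tensors), bw)
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis))

    def bw(g):
        return tuple(np.moveaxis(g, axis, 0))

    _attach(out, tuple(tensors), bw)
    return out


def pad3d(x: Tensor, pad: int) -> Tensor:
    """Zero-pad the last three (spatial) axes symmetrically."""
    if pad == 0:
        return x
    widths = [(0, 0)] * (x.ndim - 3) + [(pad, pad)] * 3
    out = Tensor(np.pad(x.data, widths))
    sl = (Ellipsis,) + (slice(pad, -pad),) * 3
    _attach(out, (x,), lambda g: (g[sl],))
    return out
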