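"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine sized for CPU-scale convolutional models: a
:class:`Tensor` wraps an ``ndarray``, records the operations applied to it,
and :meth:`Tensor.backward` accumulates gradients by walking the recorded
graph in reverse topological order.  Only the operations the detector needs
are implemented; all of them support numpy broadcasting with correct
gradient reduction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "no_grad", "is_grad_enabled",
           "set_default_dtype", "get_default_dtype"]

_GRAD_ENABLED = True
_DTYPE = np.float64


def set_default_dtype(dtype):
    """Set the dtype new tensors are stored in (float64 default, float32 for speed)."""
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DTYPE


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 200  # numpy defers to our __radd__ etc.

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=_DTYPE)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad = None
        self._backward = None
        self._prev = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward, requires_grad):
        out = Tensor(data)
        if requires_grad and _GRAD_ENABLED:
            out.requires_grad = True
            out._prev = tuple(p for p in parents if isinstance(p, Tensor) and p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        rg = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward, rg)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward, self.requires_grad)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        rg = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward, rg)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        rg = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        return Tensor._make(self.data / other.data, (self, other), backward, rg)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data ** p, (self,), backward, self.requires_grad)

    def __matmul__(self, other):
        other = as_tensor(other)
        rg = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward, rg)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward, self.requires_grad)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def arctan(self):
        def backward(g):
            self._accum(g / (1.0 + self.data ** 2))

        return Tensor._make(np.arctan(self.data), (self,), backward, self.requires_grad)

    def sigmoid(self):
        z = self.data
        out_data = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                            np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
        # derivative as sigma(z)*sigma(-z): stays nonzero far into saturation
        comp = np.where(z >= 0, np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))),
                        1.0 / (1.0 + np.exp(-np.abs(z))))

        def backward(g):
            self._accum(g * out_data * comp)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def backward(g):
            self._accum(g * (s * (1.0 + self.data * (1.0 - s))))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward, self.requires_grad)

    def leaky_relu(self, slope: float = 0.1):
        factor = np.where(self.data > 0, 1.0, slope)

        def backward(g):
            self._accum(g * factor)

        return Tensor._make(self.data * factor, (self,), backward, self.requires_grad)

    def clamp(self, lo=None, hi=None):
        mask = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            mask &= self.data >= lo
        if hi is not None:
            mask &= self.data <= hi

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward, self.requires_grad)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward,
                            self.requires_grad)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=True)
        # subgradient: spread equally over ties
        mask = (self.data == out_data).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)
        res = out_data if keepdims or axis is None else np.squeeze(out_data, axis=axis)
        if axis is None and not keepdims:
            res = res.reshape(())

        def backward(g):
            gg = g if (keepdims or axis is None) else np.expand_dims(g, axis)
            self._accum(mask * gg)

        return Tensor._make(res, (self,), backward, self.requires_grad)

    def maximum(self, other):
        other = as_tensor(other)
        rg = self.requires_grad or other.requires_grad
        a_wins = self.data >= other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * a_wins, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~a_wins, other.shape))

        return Tensor._make(np.maximum(self.data, other.data), (self, other), backward, rg)

    def minimum(self, other):
        other = as_tensor(other)
        rg = self.requires_grad or other.requires_grad
        a_wins = self.data <= other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * a_wins, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~a_wins, other.shape))

        return Tensor._make(np.minimum(self.data, other.data), (self, other), backward, rg)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward, self.requires_grad)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward, self.requires_grad)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), backward, self.requires_grad)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    rg = any(t.requires_grad for t in tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward, rg)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    rg = any(t.requires_grad for t in tensors)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis),
                        tensors, backward, rg)
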