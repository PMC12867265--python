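"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to express and train the dual-branch site classifier:
broadcast-aware elementwise arithmetic, batched matmul, shape ops, reductions,
the standard activations, and dedicated primitives (with hand-written
backward passes) for 1-D convolution, 1-D max pooling and embedding lookup,
which dominate runtime.  Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
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
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(np.array(-1.0, dtype=self.data.dtype)))

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, pow_const(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __getitem__(self, key):
        return getitem(self, key)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _node(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, grad: np.ndarray) -> None:
    if not t.requires_grad:
        return
    grad = grad.astype(t.data.dtype, copy=False)
    if t.grad is None:
        t.grad = grad.copy()
    else:
        t.grad += grad


# ---------------------------------------------------------------------------
# arithmetic


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(grad):
        _accum(a, _unbroadcast(grad, a.shape))
        _accum(b, _unbroadcast(grad, b.shape))

    out = _node(data, (a, b), backward)
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(grad):
        _accum(a, _unbroadcast(grad * b.data, a.shape))
        _accum(b, _unbroadcast(grad * a.data, b.shape))

    return _node(data, (a, b), backward)


def pow_const(a: Tensor, exponent: float) -> Tensor:
    data = a.data**exponent

    def backward(grad):
        _accum(a, grad * exponent * a.data ** (exponent - 1.0))

    return _node(data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(grad):
        if a.requires_grad:
            ga = grad @ np.swapaxes(b.data, -1, -2)
            _accum(a, _unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ grad
            _accum(b, _unbroadcast(gb, b.shape))

    return _node(data, (a, b), backward)


# ---------------------------------------------------------------------------
# shape ops


def reshape(a: Tensor, shape) -> Tensor:
    data = a.data.reshape(shape)

    def backward(grad):
        _accum(a, grad.reshape(a.shape))

    return _node(data, (a,), backward)


def transpose(a: Tensor, axes=None) -> Tensor:
    data = a.data.transpose(axes)
    inv = np.argsort(axes) if axes is not None else None

    def backward(grad):
        _accum(a, grad.transpose(inv) if inv is not None else grad.transpose())

    return _node(data, (a,), backward)


def getitem(a: Tensor, key) -> Tensor:
    data = a.data[key]

    def backward(grad):
        full = np.zeros_like(a.data)
        np.add.at(full, key, grad)
        _accum(a, full)

    return _node(data, (a,), backward)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * grad.ndim
            sl[axis] = slice(start, stop)
            _accum(t, grad[tuple(sl)])

    return _node(data, tensors, backward)


# ---------------------------------------------------------------------------
# reductions


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(grad):
        g = grad
        if not keepdims and axis is not None:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.shape).copy())

    return _node(data, (a,), backward)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), Tensor(np.array(1.0 / n, dtype=a.data.dtype)))


def max_(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    data = a.data.max(axis=axis, keepdims=keepdims)
    argmax = a.data.argmax(axis=axis)

    def backward(grad):
        g = grad if keepdims else np.expand_dims(grad, axis)
        full = np.zeros_like(a.data)
        np.put_along_axis(full, np.expand_dims(argmax, axis), g, axis=axis)
        _accum(a, full)

    return _node(data, (a,), backward)


# ---------------------------------------------------------------------------
# activations


def relu(a: Tensor) -> Tensor:
    data = np.maximum(a.data, 0)

    def backward(grad):
        _accum(a, grad * (a.data > 0))

    return _node(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    data = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                    np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))

    def backward(grad):
        _accum(a, grad * data * (1.0 - data))

    return _node(data, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    data = np.tanh(a.data)

    def backward(grad):
        _accum(a, grad * (1.0 - data * data))

    return _node(data, (a,), backward)


def exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)

    def backward(grad):
        _accum(a, grad * data)

    return _node(data, (a,), backward)


def log(a: Tensor) -> Tensor:
    data = np.log(a.data)

    def backward(grad):
        _accum(a, grad / a.data)

    return _node(data, (a,), backward)


def softplus(a: Tensor) -> Tensor:
    """log(1 + exp(x)), computed stably; gradient is sigmoid(x)."""
    data = np.maximum(a.data, 0) + np.log1p(np.exp(-np.abs(a.data)))

    def backward(grad):
        sig = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                       np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))
        _accum(a, grad * sig)

    return _node(data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(a.data.max(axis=axis, keepdims=True))  # constant shift
    e = exp(a - shift)
    return e / sum_(e, axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# network primitives with dedicated backward passes


def embedding_lookup(weight: Tensor, indices: np.ndarray) -> Tensor:
    """weight (V, D) gathered by integer indices (...,) -> (..., D)."""
    indices = np.asarray(indices)
    data = weight.data[indices]

    def backward(grad):
        full = np.zeros_like(weight.data)
        np.add.at(full, indices.ravel(), grad.reshape(-1, weight.shape[1]))
        _accum(weight, full)

    return _node(data, (weight,), backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None, padding: int = 0) -> Tensor:
    """1-D convolution: x (B, C_in, L), weight (C_out, C_in, K) -> (B, C_out, L_out)."""
    B, C_in, L = x.shape
    C_out, _, K = weight.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    cols = sliding_window_view(xp, K, axis=2)  # (B, C_in, L_out, K)
    data = np.einsum("bclk,ock->bol", cols, weight.data, optimize=True)
    if bias is not None:
        data = data + bias.data[None, :, None]
    L_out = data.shape[2]
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(grad):
        if weight.requires_grad:
            _accum(weight, np.einsum("bol,bclk->ock", grad, cols, optimize=True))
        if bias is not None and bias.requires_grad:
            _accum(bias, grad.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.einsum("bol,ock->bclk", grad, weight.data, optimize=True)
            dxp = np.zeros_like(xp)
            for k in range(K):
                dxp[:, :, k : k + L_out] += dcols[:, :, :, k]
            _accum(x, dxp[:, :, padding : padding + L] if padding else dxp)

    return _node(data, parents, backward)


def max_pool1d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    """Max pooling along the last axis of (B, C, L); padding uses -inf."""
    B, C, L = x.shape
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)), constant_values=-np.inf)
    else:
        xp = x.data
    windows = sliding_window_view(xp, kernel, axis=2)[:, :, ::stride, :]
    data = windows.max(axis=-1)
    within = windows.argmax(axis=-1)  # (B, C, L_out)
    L_out = data.shape[2]
    absolute = within + stride * np.arange(L_out)[None, None, :]

    def backward(grad):
        dxp = np.zeros((B, C, L + 2 * padding), dtype=x.data.dtype)
        bi, ci = np.meshgrid(np.arange(B), np.arange(C), indexing="ij")
        bi = np.repeat(bi[:, :, None], L_out, axis=2)
        ci = np.repeat(ci[:, :, None], L_out, axis=2)
        np.add.at(dxp, (bi, ci, absolute), grad)
        _accum(x, dxp[:, :, padding : padding + L] if padding else dxp)

    return _node(data, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return mul(x, Tensor(mask))


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from raw scores: mean(softplus(z) - y*z)."""
    y = Tensor(np.asarray(targets, dtype=logits.data.dtype))
    return mean(softplus(logits) - mul(logits, y))
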