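"""Neural-network layers on top of the autodiff core.

All learnable layers draw their initial weights from a generator passed in
at construction (fan-in uniform), so a model built twice from the same seed
has bit-identical parameters.  ``Module.train()`` / ``eval()`` toggle
dropout and batch-norm behaviour exactly as in the usual DL frameworks.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / math.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for key, value in self.__dict__.items():
            name = f"{prefix}{key}"
            if isinstance(value, Parameter):
                yield name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for key, value in self.__dict__.items():
            name = f"{prefix}{key}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{name}.{i}.")
            elif key.startswith("running_") and isinstance(value, np.ndarray):
                yield name, value

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {name: (owner, key) for name, owner, key in self._buffer_owners()}
        for name, value in state.items():
            if name in params:
                params[name].data = np.asarray(value, dtype=DTYPE).copy()
            elif name in buffers:
                owner, key = buffers[name]
                setattr(owner, key, np.asarray(value).copy())
            else:
                raise KeyError(f"unexpected state entry {name!r}")
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state: {sorted(missing)[:5]}")

    def _buffer_owners(self, prefix: str = ""):
        for key, value in self.__dict__.items():
            name = f"{prefix}{key}"
            if isinstance(value, Module):
                yield from value._buffer_owners(f"{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._buffer_owners(f"{name}.{i}.")
            elif key.startswith("running_") and isinstance(value, np.ndarray):
                yield name, self, key

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_fan_in_uniform(rng, (in_features, out_features), in_features))
        self.bias = Parameter(_fan_in_uniform(rng, (out_features,), in_features))

    def forward(self, x: Tensor) -> Tensor:
        return (x @ self.weight) + self.bias


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.standard_normal((num_embeddings, dim)) * 0.1)

    def forward(self, indices: np.ndarray) -> Tensor:
        return ad.embedding_lookup(self.weight, indices)


class Conv1d(Module):
    """1-D convolution with 'same' zero padding by default (odd kernels)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, padding: int | None = None):
        super().__init__()
        if padding is None:
            padding = (kernel - 1) // 2
        self.padding = padding
        fan_in = in_channels * kernel
        self.weight = Parameter(_fan_in_uniform(rng, (out_channels, in_channels, kernel), fan_in))
        self.bias = Parameter(_fan_in_uniform(rng, (out_channels,), fan_in))

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.weight, self.bias, padding=self.padding)


class MaxPool1d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel = kernel
        self.stride = stride or kernel
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return ad.max_pool1d(x, self.kernel, self.stride, self.padding)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.relu(x)


class Dropout(Module):
    """Inverted dropout; the mask generator is rebound by the trainer per run."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        return ad.dropout(x, self.p, self.rng, self.training)


class BatchNorm1d(Module):
    """Batch normalization over (B, F) or per-channel over (B, C, L)."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        channel_last = x.ndim == 2
        axes = (0,) if channel_last else (0, 2)
        if self.training:
            mu = ad.mean(x, axis=axes, keepdims=True)
            var = ad.mean((x - mu) * (x - mu), axis=axes, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.squeeze().astype(DTYPE))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.squeeze().astype(DTYPE))
        else:
            shape = (1, -1) if channel_last else (1, -1, 1)
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mu) * ad.pow_const(var + Tensor(np.array(self.eps, dtype=DTYPE)), -0.5)
        shape = (1, -1) if channel_last else (1, -1, 1)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = ad.mean(x, axis=-1, keepdims=True)
        var = ad.mean((x - mu) * (x - mu), axis=-1, keepdims=True)
        xhat = (x - mu) * ad.pow_const(var + Tensor(np.array(self.eps, dtype=DTYPE)), -0.5)
        return xhat * self.gamma + self.beta


class MultiHeadAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator, dropout: float = 0.0):
        super().__init__()
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.head_dim = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)
        self.drop = Dropout(dropout)

    def forward(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        qkv = self.qkv(x).reshape((B, T, 3, self.heads, self.head_dim))
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, H, T, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scale = Tensor(np.array(1.0 / math.sqrt(self.head_dim), dtype=DTYPE))
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale  # (B, H, T, T)
        attn = self.drop(ad.softmax(scores, axis=-1))
        ctx = attn @ v  # (B, H, T, hd)
        ctx = ctx.transpose(0, 2, 1, 3).reshape((B, T, D))
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: self-attention and position-wise FFN."""

    def __init__(self, dim: int, heads: int, ffn_dim: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        self.attn = MultiHeadAttention(dim, heads, rng, dropout=dropout)
        self.norm1 = LayerNorm(dim)
        self.ffn1 = Linear(dim, ffn_dim, rng)
        self.ffn2 = Linear(ffn_dim, dim, rng)
        self.norm2 = LayerNorm(dim)
        self.drop1 = Dropout(dropout)
        self.drop2 = Dropout(dropout)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.drop1(self.attn(x)))
        x = self.norm2(x + self.drop2(self.ffn2(ad.relu(self.ffn1(x)))))
        return x


class RNNLayer(Module):
    """Simple tanh recurrence over (B, T, D_in); returns the last hidden state."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_dim = hidden_dim
        self.wx = Parameter(_fan_in_uniform(rng, (input_dim, hidden_dim), input_dim))
        self.wh = Parameter(_fan_in_uniform(rng, (hidden_dim, hidden_dim), hidden_dim))
        self.b = Parameter(np.zeros(hidden_dim))

    def forward(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.hidden_dim), dtype=DTYPE))
        for t in range(T):
            h = ad.tanh(x[:, t, :] @ self.wx + h @ self.wh + self.b)
        return h


class LSTMLayer(Module):
    """Standard LSTM over (B, T, D_in); returns the last hidden state."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_dim = hidden_dim
        self.wx = Parameter(_fan_in_uniform(rng, (input_dim, 4 * hidden_dim), input_dim))
        self.wh = Parameter(_fan_in_uniform(rng, (hidden_dim, 4 * hidden_dim), hidden_dim))
        self.b = Parameter(np.zeros(4 * hidden_dim))

    def forward(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden_dim
        h = Tensor(np.zeros((B, H), dtype=DTYPE))
        c = Tensor(np.zeros((B, H), dtype=DTYPE))
        for t in range(T):
            gates = x[:, t, :] @ self.wx + h @ self.wh + self.b
            i = ad.sigmoid(gates[:, 0 * H : 1 * H])
            f = ad.sigmoid(gates[:, 1 * H : 2 * H])
            g = ad.tanh(gates[:, 2 * H : 3 * H])
            o = ad.sigmoid(gates[:, 3 * H : 4 * H])
            c = f * c + i * g
            h = o * ad.tanh(c)
        return h
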