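"""Dual-branch site-classifier architecture.

The full model combines two branches over a 41-nt window:

* an *inception branch* over learned 32-dim word embeddings of the integer
  encoded sequence — three stacked inception modules (four parallel conv
  paths with kernels 1 / 1-3 / 1-5 / pool-1, concatenated and batch
  normalized), a max pool, and a linear projection to a 256-vector;
* a *transformer branch* over fixed per-nucleotide provider embeddings
  (41 x D, D = 1280 by default) — a stack of post-norm transformer encoder
  layers, a feature-axis max pool (kernel 3, stride 2: 1280 -> 639 per
  position), and fully connected layers down to a 256-vector.

The two 256-vectors are concatenated and passed through two consecutive
linear layers (ReLU, 1-D batch norm and dropout between them) to a single
sigmoid probability of the central cytosine being a 5hmC site.  Single
branch ablation variants and recurrent (LSTM / simple RNN) branch types for
model selection share the same head shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np

from .nn import autodiff as ad
from .nn.layers import (DTYPE, BatchNorm1d, Conv1d, Dropout, Embedding, Linear,
                        LSTMLayer, MaxPool1d, Module, RNNLayer,
                        TransformerEncoderLayer)

BranchType = Literal["inception", "transformer", "lstm", "rnn"]


@dataclass(frozen=True)
class InceptionConfig:
    """Channel widths of the four parallel convolutional paths."""

    path_channels: tuple[int, int, int, int] = (16, 16, 16, 16)

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.path_channels):
            raise ValueError(f"path channels must be positive, got {self.path_channels}")

    @property
    def out_channels(self) -> int:
        return sum(self.path_channels)


@dataclass
class ModelConfig:
    """Architecture and training recipe of the classifier.

    Defaults follow the published configuration: 32-dim word embeddings,
    three inception modules, six transformer encoder layers over 1280-dim
    embeddings, 256-dim branch outputs, Adam at learning rate 1e-5 for 18
    epochs with batch size 500, binary cross-entropy loss, gradient-norm
    clipping at 1, dropout 0.5 inside the inception branch and 0.3
    elsewhere, and a 0.5 classification threshold.
    """

    word_embed_dim: int = 32
    n_inception_modules: int = 3
    inception: InceptionConfig = field(default_factory=InceptionConfig)
    embed_dim: int = 1280
    transformer_layers: int = 6
    transformer_heads: int = 8
    transformer_ffn_dim: int = 2048
    transformer_pool_kernel: int = 3
    transformer_pool_stride: int = 2
    transformer_hidden: int = 512
    branch_output_dim: int = 256
    fusion_hidden: int = 128
    rnn_hidden: int = 128
    dropout_inception: float = 0.5
    dropout_other: float = 0.3
    learning_rate: float = 1e-5
    epochs: int = 18
    batch_size: int = 500
    max_grad_norm: float = 1.0
    grad_clip_mode: str = "norm"  # "norm" (gradient clipping) or "weight" (max-norm constraint)
    threshold: float = 0.5
    branch_mode: str = "dual"  # dual | inception_only | transformer_only
    branch1_type: BranchType = "inception"
    branch2_type: BranchType = "transformer"

    def __post_init__(self) -> None:
        for name in ("word_embed_dim", "embed_dim", "transformer_layers", "branch_output_dim",
                     "fusion_hidden", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("dropout_inception", "dropout_other"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.branch_mode not in ("dual", "inception_only", "transformer_only"):
            raise ValueError(f"unsupported branch_mode {self.branch_mode!r}")
        for bt in (self.branch1_type, self.branch2_type):
            if bt not in ("inception", "transformer", "lstm", "rnn"):
                raise ValueError(f"unsupported branch type {bt!r}")
        if self.grad_clip_mode not in ("norm", "weight"):
            raise ValueError(f"grad_clip_mode must be 'norm' or 'weight'")

    def pooled_feature_dim(self) -> int:
        """Per-position dimension after the transformer branch's feature-axis pool."""
        return (self.embed_dim - self.transformer_pool_kernel) // self.transformer_pool_stride + 1

    def to_json(self) -> str:
        d = asdict(self)
        d["inception"] = list(self.inception.path_channels)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["inception"] = InceptionConfig(tuple(d["inception"]))
        return cls(**d)


def compact_config(**overrides) -> ModelConfig:
    """A CPU-scale variant of the default architecture for desk-size runs.

    Keeps the dual-branch topology (three inception modules over 32-dim word
    embeddings; transformer encoder stack with feature-axis pooling; 0.5 /
    0.3 dropout split; gradient-norm clipping at 1; 18 training epochs) but
    shrinks the transformer branch to 32-dim provider embeddings, two
    encoder layers and narrow hidden widths, and trains with learning rate
    1e-3 in batches of 64.  The published recipe's learning rate of 1e-5
    with batches of 500 yields only a handful of optimizer updates at these
    sample sizes — far too few for Adam (whose per-step displacement is
    bounded by the learning rate) to leave the random initialisation — so
    the compact recipe raises the step count and step size to reach
    convergence within the same 18 epochs.
    """
    base = dict(
        embed_dim=32,
        transformer_layers=2,
        transformer_heads=8,
        transformer_ffn_dim=64,
        transformer_hidden=64,
        learning_rate=1e-3,
        batch_size=64,
    )
    base.update(overrides)
    return ModelConfig(**base)


class InceptionModule(Module):
    """Four parallel length-preserving conv paths concatenated channel-wise."""

    def __init__(self, in_channels: int, cfg: InceptionConfig, rng: np.random.Generator):
        super().__init__()
        c1, c2, c3, c4 = cfg.path_channels
        self.p1 = Conv1d(in_channels, c1, 1, rng)
        self.p2a = Conv1d(in_channels, c2, 1, rng)
        self.p2b = Conv1d(c2, c2, 3, rng)
        self.p3a = Conv1d(in_channels, c3, 1, rng)
        self.p3b = Conv1d(c3, c3, 5, rng)
        self.p4_pool = MaxPool1d(3, stride=1, padding=1)
        self.p4 = Conv1d(in_channels, c4, 1, rng)
        self.bn = BatchNorm1d(cfg.out_channels)
        self.n_paths = 4

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        paths = [
            ad.relu(self.p1(x)),
            ad.relu(self.p2b(ad.relu(self.p2a(x)))),
            ad.relu(self.p3b(ad.relu(self.p3a(x)))),
            ad.relu(self.p4(self.p4_pool(x))),
        ]
        return self.bn(ad.concatenate(paths, axis=1))


def build_inception_module(in_channels: int, cfg: InceptionConfig,
                           seed: int = 0) -> InceptionModule:
    if in_channels < 1:
        raise ValueError(f"in_channels must be positive, got {in_channels}")
    return InceptionModule(in_channels, cfg, np.random.default_rng(seed))


class _InceptionBranch(Module):
    def __init__(self, input_dim: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.blocks = [InceptionModule(input_dim if i == 0 else cfg.inception.out_channels,
                                       cfg.inception, rng)
                       for i in range(cfg.n_inception_modules)]
        self.drops = [Dropout(cfg.dropout_inception) for _ in range(cfg.n_inception_modules)]
        self.pool = MaxPool1d(2, stride=2)
        flat = cfg.inception.out_channels * (41 // 2)
        self.fc = Linear(flat, cfg.branch_output_dim, rng)

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        h = x.transpose(0, 2, 1)  # (B, D, 41)
        for block, drop in zip(self.blocks, self.drops):
            h = drop(block(h))
        h = self.pool(h)
        h = h.reshape((h.shape[0], -1))
        return self.fc(h)


class _TransformerBranch(Module):
    def __init__(self, input_dim: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        heads = cfg.transformer_heads
        if input_dim % heads != 0:
            raise ValueError(f"embedding dim {input_dim} not divisible by {heads} heads")
        self.layers = [TransformerEncoderLayer(input_dim, heads, cfg.transformer_ffn_dim,
                                               rng, dropout=cfg.dropout_other)
                       for _ in range(cfg.transformer_layers)]
        self.pool = MaxPool1d(cfg.transformer_pool_kernel, stride=cfg.transformer_pool_stride)
        pooled = (input_dim - cfg.transformer_pool_kernel) // cfg.transformer_pool_stride + 1
        self.pooled_dim = pooled
        self.fc1 = Linear(41 * pooled, cfg.transformer_hidden, rng)
        self.bn = BatchNorm1d(cfg.transformer_hidden)
        self.drop = Dropout(cfg.dropout_other)
        self.fc2 = Linear(cfg.transformer_hidden, cfg.branch_output_dim, rng)

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        h = x
        for layer in self.layers:
            h = layer(h)
        h = self.pool(h)  # feature-axis pooling: (B, 41, pooled)
        h = h.reshape((h.shape[0], -1))
        h = self.drop(self.bn(ad.relu(self.fc1(h))))
        return self.fc2(h)


class _RecurrentBranch(Module):
    def __init__(self, input_dim: int, cfg: ModelConfig, rng: np.random.Generator,
                 kind: str):
        super().__init__()
        layer_cls = LSTMLayer if kind == "lstm" else RNNLayer
        self.rnn = layer_cls(input_dim, cfg.rnn_hidden, rng)
        self.fc = Linear(cfg.rnn_hidden, cfg.branch_output_dim, rng)

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        return self.fc(self.rnn(x))


def _make_branch(kind: str, input_dim: int, cfg: ModelConfig,
                 rng: np.random.Generator) -> Module:
    if kind == "inception":
        return _InceptionBranch(input_dim, cfg, rng)
    if kind == "transformer":
        return _TransformerBranch(input_dim, cfg, rng)
    if kind in ("lstm", "rnn"):
        return _RecurrentBranch(input_dim, cfg, rng, kind)
    raise ValueError(f"unsupported branch type {kind!r}")


class InTransNet(Module):
    """The assembled classifier network; forward returns raw logits (B,)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.word_embed = None
        self.branch1 = None
        self.branch2 = None
        if cfg.branch_mode in ("dual", "inception_only"):
            self.word_embed = Embedding(4, cfg.word_embed_dim, rng)
            kind = cfg.branch1_type if cfg.branch_mode == "dual" else "inception"
            self.branch1 = _make_branch(kind, cfg.word_embed_dim, cfg, rng)
        if cfg.branch_mode in ("dual", "transformer_only"):
            kind = cfg.branch2_type if cfg.branch_mode == "dual" else "transformer"
            self.branch2 = _make_branch(kind, cfg.embed_dim, cfg, rng)
        fused = cfg.branch_output_dim * (2 if cfg.branch_mode == "dual" else 1)
        self.head_bn_in = BatchNorm1d(fused)
        self.head_drop_in = Dropout(cfg.dropout_other)
        self.head1 = Linear(fused, cfg.fusion_hidden, rng)
        self.head_bn = BatchNorm1d(cfg.fusion_hidden)
        self.head_drop = Dropout(cfg.dropout_other)
        self.head2 = Linear(cfg.fusion_hidden, 1, rng)

    def forward(self, int_seqs: np.ndarray | None,
                embeddings: np.ndarray | None,
                word_activations: ad.Tensor | None = None) -> ad.Tensor:
        feats = []
        if self.branch1 is not None:
            if word_activations is not None:
                w = word_activations  # injected (B, 41, word_dim), e.g. for attribution
            else:
                if int_seqs is None:
                    raise ValueError("branch 1 requires integer-encoded sequences")
                w = self.word_embed(np.asarray(int_seqs))  # (B, 41, word_dim)
            feats.append(self.branch1(w))
        if self.branch2 is not None:
            if embeddings is None:
                raise ValueError("branch 2 requires provider embedding matrices")
            e = ad.Tensor(np.asarray(embeddings, dtype=DTYPE))
            feats.append(self.branch2(e))
        h = feats[0] if len(feats) == 1 else ad.concatenate(feats, axis=1)
        h = self.head_drop_in(ad.relu(self.head_bn_in(h)))
        h = self.head_drop(self.head_bn(ad.relu(self.head1(h))))
        return self.head2(h).reshape((-1,))

    def predict_logits(self, int_seqs, embeddings, batch_size: int = 256) -> np.ndarray:
        """Deterministic eval-mode logits, computed in batches."""
        self.eval()
        n = len(int_seqs) if int_seqs is not None else len(embeddings)
        out = np.empty(n, dtype=np.float64)
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            logits = self.forward(
                None if int_seqs is None else int_seqs[sl],
                None if embeddings is None else embeddings[sl],
            )
            out[sl] = logits.data.astype(np.float64)
        return out


def build_model(cfg: ModelConfig, seed: int = 0) -> InTransNet:
    return InTransNet(cfg, seed=seed)


def forward(model: InTransNet, int_seqs, embeddings) -> np.ndarray:
    """Eval-mode forward returning per-sample probabilities in (0, 1)."""
    logits = model.predict_logits(int_seqs, embeddings)
    return 1.0 / (1.0 + np.exp(-logits))


def count_parameters(model: Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))


def save_model(model: InTransNet, path: str | Path) -> None:
    """Serialize weights + config + seed; reload is bit-exact."""
    state = model.state_dict()
    np.savez(path, __config__=np.frombuffer(model.cfg.to_json().encode(), dtype=np.uint8),
             __seed__=np.array(model.seed), **state)


def load_model(path: str | Path) -> InTransNet:
    with np.load(path) as archive:
        cfg = ModelConfig.from_json(bytes(archive["__config__"]).decode())
        seed = int(archive["__seed__"])
        state = {k: archive[k] for k in archive.files if not k.startswith("__")}
    model = build_model(cfg, seed=seed)
    model.load_state_dict(state)
    return model
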