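"""Model training (Adam + binary cross-entropy) and prediction.

The published recipe trains with Adam at learning rate 1e-5 for 18 epochs in
batches of 500 with gradient-norm clipping at 1; those are the
:class:`~intrans5hmc.network.ModelConfig` defaults.  Training is a pure
function of (data, config, seed): weight init, per-epoch batch shuffling and
dropout masks all derive from the run seed, so a repeated run reproduces the
loss history and report bit-for-bit on the same platform.

The sklearn-style estimator :class:`InTrans5hmCClassifier` wraps the same
machinery behind ``fit`` / ``predict`` / ``predict_proba``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .embeddings import EmbeddingProvider, EmbeddingUnavailableError, SyntheticEmbeddingProvider
from .metrics import MetricReport, compute_metrics
from .network import InTransNet, ModelConfig, build_model, load_model, save_model
from .nn import autodiff as ad
from .nn.layers import Dropout
from .nn.optim import Adam, clip_grad_norm
from .samples import SampleSet, decode_integers, encode_matrix


@dataclass
class TrainedModel:
    """A fitted network with its config, seed and per-epoch loss history."""

    model: InTransNet
    config: ModelConfig
    history: list[float]
    seed: int

    def save(self, path: str | Path) -> None:
        save_model(self.model, path)
        hist_path = Path(path).with_suffix(".history.npy")
        np.save(hist_path, np.array(self.history))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        model = load_model(path)
        hist_path = Path(path).with_suffix(".history.npy")
        history = np.load(hist_path).tolist() if hist_path.exists() else []
        return cls(model=model, config=model.cfg, history=history, seed=model.seed)


def _needs(cfg: ModelConfig) -> tuple[bool, bool]:
    b1 = cfg.branch_mode in ("dual", "inception_only")
    b2 = cfg.branch_mode in ("dual", "transformer_only")
    return b1, b2


def _materialize(samples: SampleSet, provider: EmbeddingProvider | None,
                 cfg: ModelConfig) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Encode sequences and fetch all embeddings up front (fail fast)."""
    need_seq, need_emb = _needs(cfg)
    int_seqs = encode_matrix(samples) if need_seq else None
    emb = None
    if need_emb:
        if provider is None:
            raise ValueError("this branch configuration requires an embedding provider")
        if provider.dim != cfg.embed_dim:
            raise ValueError(f"provider dim {provider.dim} != config embed_dim {cfg.embed_dim}")
        emb = provider.embed_set(samples).astype(np.float32)
    return int_seqs, emb


def _apply_weight_maxnorm(model: InTransNet, max_norm: float) -> None:
    for p in model.parameters():
        if p.data.ndim >= 2:
            norm = float(np.sqrt((p.data.astype(np.float64) ** 2).sum()))
            if norm > max_norm:
                p.data *= max_norm / norm


def fit_arrays(model: InTransNet, int_seqs: np.ndarray | None,
               embeddings: np.ndarray | None, y: np.ndarray,
               cfg: ModelConfig, seed: int) -> list[float]:
    """Run the Adam/BCE training loop in place; returns per-epoch mean loss."""
    n = len(y)
    y = np.asarray(y, dtype=np.float32)
    for i, drop in enumerate(m for m in model.modules() if isinstance(m, Dropout)):
        drop.rng = np.random.default_rng([seed, 7919, i])
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        model.train()
        perm = np.random.default_rng([seed, epoch]).permutation(n)
        losses, weights = [], []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            optimizer.zero_grad()
            logits = model.forward(
                None if int_seqs is None else int_seqs[idx],
                None if embeddings is None else embeddings[idx],
            )
            loss = ad.bce_with_logits(logits, y[idx])
            loss.backward()
            if cfg.grad_clip_mode == "norm":
                clip_grad_norm(model.parameters(), cfg.max_grad_norm)
            optimizer.step()
            if cfg.grad_clip_mode == "weight":
                _apply_weight_maxnorm(model, cfg.max_grad_norm)
            losses.append(float(loss.data))
            weights.append(len(idx))
        history.append(float(np.average(losses, weights=weights)))
    model.eval()
    return history


def train(train_set: SampleSet, provider: EmbeddingProvider | None,
          cfg: ModelConfig | None = None, seed: int = 0,
          model: InTransNet | None = None) -> TrainedModel:
    """Train a (fresh or given) network on a SampleSet.

    Embeddings for every sample are fetched before training starts, so a
    provider missing any id raises immediately.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    cfg = cfg or ModelConfig()
    int_seqs, emb = _materialize(train_set, provider, cfg)
    if model is None:
        model = build_model(cfg, seed=seed)
    history = fit_arrays(model, int_seqs, emb, train_set.labels, cfg, seed)
    return TrainedModel(model=model, config=cfg, history=history, seed=seed)


def predict(trained: TrainedModel, samples: SampleSet,
            provider: EmbeddingProvider | None) -> np.ndarray:
    """Per-sample probabilities in (0, 1); thresholding is the caller's step."""
    int_seqs, emb = _materialize(samples, provider, trained.config)
    logits = trained.model.predict_logits(int_seqs, emb)
    return 1.0 / (1.0 + np.exp(-logits))


def evaluate(trained: TrainedModel, samples: SampleSet,
             provider: EmbeddingProvider | None) -> MetricReport:
    probs = predict(trained, samples, provider)
    return compute_metrics(samples.labels, probs, threshold=trained.config.threshold)


class InTrans5hmCClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style dual-branch 5hmC site classifier.

    Parameters mirror :class:`~intrans5hmc.network.ModelConfig`; ``config``
    overrides everything when given.  ``X`` may be a sequence of 41-nt
    strings, a ``SampleSet`` or an (n, 41) integer-encoded array.

    Examples
    --------
    >>> from intrans5hmc.simulate import GeneratorConfig, generate_dataset
    >>> data = generate_dataset(GeneratorConfig(n_pos=50, n_neg=50, seed=1))
    >>> clf = InTrans5hmCClassifier(branch_mode="inception_only", epochs=2,
    ...                             random_state=0)
    >>> probs = clf.fit(data.sequences, data.labels).predict_proba(data.sequences)
    """

    def __init__(self, branch_mode: str = "dual", branch1_type: str = "inception",
                 branch2_type: str = "transformer", embed_dim: int = 1280,
                 transformer_layers: int = 6, transformer_heads: int = 8,
                 transformer_ffn_dim: int = 2048, learning_rate: float = 1e-5,
                 epochs: int = 18, batch_size: int = 500,
                 dropout_inception: float = 0.5, dropout_other: float = 0.3,
                 max_grad_norm: float = 1.0, threshold: float = 0.5,
                 provider: EmbeddingProvider | None = None,
                 config: ModelConfig | None = None, random_state: int = 0):
        self.branch_mode = branch_mode
        self.branch1_type = branch1_type
        self.branch2_type = branch2_type
        self.embed_dim = embed_dim
        self.transformer_layers = transformer_layers
        self.transformer_heads = transformer_heads
        self.transformer_ffn_dim = transformer_ffn_dim
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.dropout_inception = dropout_inception
        self.dropout_other = dropout_other
        self.max_grad_norm = max_grad_norm
        self.threshold = threshold
        self.provider = provider
        self.config = config
        self.random_state = random_state

    def _config(self) -> ModelConfig:
        if self.config is not None:
            return self.config
        return ModelConfig(
            branch_mode=self.branch_mode, branch1_type=self.branch1_type,
            branch2_type=self.branch2_type, embed_dim=self.embed_dim,
            transformer_layers=self.transformer_layers,
            transformer_heads=self.transformer_heads,
            transformer_ffn_dim=self.transformer_ffn_dim,
            learning_rate=self.learning_rate, epochs=self.epochs,
            batch_size=self.batch_size, dropout_inception=self.dropout_inception,
            dropout_other=self.dropout_other, max_grad_norm=self.max_grad_norm,
            threshold=self.threshold,
        )

    def _coerce(self, X) -> tuple[np.ndarray | None, np.ndarray | None]:
        cfg = self.config_
        need_seq, need_emb = _needs(cfg)
        if isinstance(X, SampleSet):
            seqs = X.sequences
        elif len(X) > 0 and isinstance(X[0], str):
            seqs = list(X)
        else:
            seqs = [decode_integers(row) for row in np.asarray(X)]
        int_seqs = encode_matrix(seqs) if need_seq else None
        emb = None
        if need_emb:
            provider = self.provider_
            emb = np.stack([provider.embed(s) for s in seqs]).astype(np.float32)
        return int_seqs, emb

    def fit(self, X, y=None):
        self.config_ = self._config()
        if isinstance(X, SampleSet) and y is None:
            y = X.labels
        y = np.asarray(y).astype(int)
        self.classes_ = np.array([0, 1])
        need_seq, need_emb = _needs(self.config_)
        self.provider_ = self.provider
        if need_emb and self.provider_ is None:
            self.provider_ = SyntheticEmbeddingProvider(dim=self.config_.embed_dim,
                                                        seed=self.random_state)
        if need_emb and self.provider_.dim != self.config_.embed_dim:
            raise ValueError(
                f"provider dim {self.provider_.dim} != embed_dim {self.config_.embed_dim}")
        int_seqs, emb = self._coerce(X)
        self.model_ = build_model(self.config_, seed=self.random_state)
        self.history_ = fit_arrays(self.model_, int_seqs, emb, y,
                                   self.config_, self.random_state)
        self.n_features_in_ = 41
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        int_seqs, emb = self._coerce(X)
        logits = self.model_.predict_logits(int_seqs, emb)
        p1 = 1.0 / (1.0 + np.exp(-logits))
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        int_seqs, emb = self._coerce(X)
        return self.model_.predict_logits(int_seqs, emb)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.config_.threshold).astype(int)

    def report(self, X, y) -> MetricReport:
        """Nine-metric evaluation on labelled data."""
        return compute_metrics(np.asarray(y).astype(int),
                               self.predict_proba(X)[:, 1],
                               threshold=self.config_.threshold)
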