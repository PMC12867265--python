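"""Per-nucleotide embedding providers, pooling and caching.

The transformer branch of the classifier consumes a (41, D) real matrix per
sequence — one contextual vector per nucleotide, D = 1280 for the large RNA
language model whose embeddings the published pipeline uses.  The language
model itself is never loaded here: embeddings enter exclusively through a
provider contract.  Two providers are shipped:

* :class:`SyntheticEmbeddingProvider` — a deterministic stand-in (synthetic;
  see its docstring) whose rows encode local trinucleotide context plus a
  sinusoidal positional component, so sequence signal is recoverable from
  the matrices at test time without any external model.
* :class:`CachedEmbeddingProvider` — serves pre-computed matrices from an
  HDF5 cache written by an external extraction run; a missing sample id is
  a hard error, never a silent fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .samples import SEQ_LENGTH, NT_TO_INT, RnaSample, SampleSet

DEFAULT_DIM = 1280


class EmbeddingUnavailableError(KeyError):
    """Requested sample id has no embedding in the configured source."""


@dataclass(frozen=True)
class ProviderSpec:
    """Configuration of an embedding provider."""

    name: str = "synthetic"
    dim: int = DEFAULT_DIM
    seed: int = 0
    cache_path: str | None = None

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")


class EmbeddingProvider:
    """Provider contract: a pure mapping from sequence to a (41, dim) matrix."""

    name: str
    dim: int

    def embed(self, sample: RnaSample | str) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def embed_set(self, samples: SampleSet) -> np.ndarray:
        """Stack embeddings for a whole set into (n, 41, dim)."""
        if len(samples) == 0:
            return np.empty((0, SEQ_LENGTH, self.dim), dtype=np.float32)
        return np.stack([self.embed(s) for s in samples])


def _sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    pos = np.arange(length)[:, None].astype(np.float64)
    idx = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (idx // 2)) / dim)
    enc = np.where(idx % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


class SyntheticEmbeddingProvider(EmbeddingProvider):
    """Deterministic synthetic per-nucleotide embeddings (not a language model).

    Row i is ``basis[trinucleotide centred at i] + 0.3 * sinusoid(i)`` where
    the 64 basis vectors are drawn once from a seeded PCG64 generator and the
    sequence is edge-padded for the two terminal positions.  Identical
    (sequence, seed) inputs always give identical matrices, and any single
    nucleotide substitution changes the three rows whose context covers it.
    """

    def __init__(self, spec: ProviderSpec | None = None, dim: int | None = None, seed: int = 0):
        if spec is None:
            spec = ProviderSpec(name="synthetic", dim=dim or DEFAULT_DIM, seed=seed)
        self.spec = spec
        self.name = "synthetic"
        self.dim = spec.dim
        rng = np.random.Generator(np.random.PCG64(spec.seed))
        self._basis = (rng.standard_normal((64, spec.dim)) / np.sqrt(spec.dim)).astype(np.float32)
        self._positions = (0.3 * _sinusoidal_positions(SEQ_LENGTH, spec.dim)).astype(np.float32)

    def embed(self, sample: RnaSample | str) -> np.ndarray:
        seq = sample.sequence if isinstance(sample, RnaSample) else sample
        if len(seq) != SEQ_LENGTH:
            raise ValueError(f"expected length {SEQ_LENGTH}, got {len(seq)}")
        padded = seq[0] + seq + seq[-1]
        codes = [NT_TO_INT[ch] for ch in padded]
        tri = [codes[i] * 16 + codes[i + 1] * 4 + codes[i + 2] for i in range(SEQ_LENGTH)]
        return self._basis[tri] + self._positions


def synthetic_provider(spec: ProviderSpec) -> SyntheticEmbeddingProvider:
    return SyntheticEmbeddingProvider(spec)


class CachedEmbeddingProvider(EmbeddingProvider):
    """Serve fixed embeddings for known sample ids from an HDF5 cache.

    This is the adapter for externally extracted language-model embeddings;
    which hidden layer was exported and whether special tokens were stripped
    are properties of the extraction run recorded in the cache manifest.
    """

    def __init__(self, cache_path: str | Path):
        self.cache_path = Path(cache_path)
        if not self.cache_path.exists():
            raise FileNotFoundError(self.cache_path)
        with h5py.File(self.cache_path, "r") as fh:
            manifest = json.loads(fh.attrs["manifest"])
        self.manifest = manifest
        self.name = manifest["provider"]
        self.dim = int(manifest["dim"])

    def embed(self, sample: RnaSample | str) -> np.ndarray:
        sid = sample.id if isinstance(sample, RnaSample) else str(sample)
        with h5py.File(self.cache_path, "r") as fh:
            group = fh["embeddings"]
            if sid not in group:
                raise EmbeddingUnavailableError(
                    f"embedding unavailable for sample {sid!r} in cache {self.cache_path}"
                )
            return np.asarray(group[sid], dtype=np.float32)

    def ids(self) -> list[str]:
        with h5py.File(self.cache_path, "r") as fh:
            return list(fh["embeddings"].keys())


def external_lm_adapter(spec: ProviderSpec) -> CachedEmbeddingProvider:
    if not spec.cache_path:
        raise ValueError("external provider requires spec.cache_path")
    return CachedEmbeddingProvider(spec.cache_path)


def mean_pool(matrix: np.ndarray) -> np.ndarray:
    """Average a (positions, D) embedding matrix along the sequence axis."""
    matrix = np.asarray(matrix)
    if matrix.ndim == 2:
        return matrix.mean(axis=0)
    if matrix.ndim == 3:  # batch
        return matrix.mean(axis=1)
    raise ValueError(f"expected 2-D or 3-D input, got shape {matrix.shape}")


def cache_store(samples: SampleSet, provider: EmbeddingProvider, path: str | Path) -> Path:
    """Write one (41, dim) float32 array per sample id plus a JSON manifest."""
    path = Path(path)
    ids = samples.ids
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids; refusing to write cache")
    manifest = {
        "provider": provider.name,
        "dim": provider.dim,
        "n_samples": len(samples),
        "format": "hdf5/embeddings-group",
        "dtype": "float32",
    }
    if isinstance(provider, SyntheticEmbeddingProvider):
        manifest["seed"] = provider.spec.seed
    with h5py.File(path, "w") as fh:
        fh.attrs["manifest"] = json.dumps(manifest, sort_keys=True)
        group = fh.create_group("embeddings")
        for sample in samples:
            group.create_dataset(sample.id, data=provider.embed(sample).astype(np.float32))
    return path
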