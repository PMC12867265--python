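"""Shared fixtures: small synthetic datasets, a tiny model config, providers."""

import numpy as np
import pytest
from hypothesis import settings

from intrans5hmc.embeddings import SyntheticEmbeddingProvider

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from intrans5hmc.network import ModelConfig
from intrans5hmc.simulate import GeneratorConfig, MotifSpec, generate_dataset


def random_sequence(rng: np.random.Generator) -> str:
    """A random valid 41-nt window with the central C."""
    chars = rng.choice(list("ACGU"), size=41)
    chars[20] = "C"
    return "".join(chars)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_null_set():
    """60 + 60 motif-free sequences."""
    return generate_dataset(GeneratorConfig(n_pos=60, n_neg=60, seed=3))


@pytest.fixture(scope="session")
def small_motif_set():
    """80 + 80 sequences with a strong planted 21-26 motif."""
    return generate_dataset(
        GeneratorConfig(n_pos=80, n_neg=80, seed=5, motif=MotifSpec(a_delta=0.4, g_delta=0.2))
    )


@pytest.fixture(scope="session")
def tiny_provider():
    return SyntheticEmbeddingProvider(dim=16, seed=7)


@pytest.fixture()
def tiny_config():
    """A minimal dual configuration that trains in seconds."""
    return ModelConfig(
        word_embed_dim=8,
        n_inception_modules=1,
        embed_dim=16,
        transformer_layers=1,
        transformer_heads=4,
        transformer_ffn_dim=32,
        transformer_hidden=32,
        branch_output_dim=32,
        fusion_hidden=16,
        rnn_hidden=16,
        learning_rate=1e-3,
        epochs=2,
        batch_size=32,
    )
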