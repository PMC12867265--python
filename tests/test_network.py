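"""Architecture shapes, determinism and serialization."""

import numpy as np
import pytest

from intrans5hmc.network import (
    InceptionConfig,
    ModelConfig,
    build_inception_module,
    build_model,
    compact_config,
    count_parameters,
    forward,
    load_model,
    save_model,
)
from intrans5hmc.nn import autodiff as ad
from intrans5hmc.nn.layers import Linear
from intrans5hmc.samples import encode_matrix


def _batch(cfg: ModelConfig, n: int, seed: int = 0):
    rng = np.random.default_rng(seed)
    ints = rng.integers(0, 4, (n, 41))
    ints[:, 20] = 1
    emb = rng.standard_normal((n, 41, cfg.embed_dim)).astype(np.float32)
    return ints, emb


class TestInceptionModule:
    def test_channel_sum_and_length_preserved(self):
        module = build_inception_module(32, InceptionConfig((16, 16, 16, 16)), seed=0)
        module.eval()
        x = ad.Tensor(np.random.default_rng(0).standard_normal((2, 32, 41)).astype(np.float32))
        out = module(x)
        assert out.shape == (2, 64, 41)

    def test_four_parallel_paths(self):
        module = build_inception_module(8, InceptionConfig((4, 4, 4, 4)), seed=0)
        assert module.n_paths == 4

    def test_length_preserved_for_odd_lengths(self):
        # every path pads to keep the sequence axis intact
        module = build_inception_module(4, InceptionConfig((2, 2, 2, 2)), seed=1)
        module.eval()
        for length in (7, 41):
            x = ad.Tensor(np.zeros((1, 4, length), dtype=np.float32))
            assert module(x).shape[2] == length

    def test_invalid_channels(self):
        with pytest.raises(ValueError):
            InceptionConfig((0, 4, 4, 4))


class TestModelShapes:
    def test_dual_forward_probabilities(self, tiny_config):
        model = build_model(tiny_config, seed=0)
        ints, emb = _batch(tiny_config, 4)
        probs = forward(model, ints, emb)
        assert probs.shape == (4,)
        assert ((probs > 0) & (probs < 1)).all()

    def test_branch_output_dims(self, tiny_config):
        model = build_model(tiny_config, seed=0)
        d = tiny_config.branch_output_dim
        assert model.branch1.fc.weight.shape[1] == d
        assert model.branch2.fc2.weight.shape[1] == d

    def test_pooled_feature_dim_for_default_embeddings(self):
        # kernel 3, stride 2 over 1280 feature channels
        assert ModelConfig().pooled_feature_dim() == 639

    @pytest.mark.parametrize("mode", ["inception_only", "transformer_only"])
    def test_single_branch_modes(self, tiny_config, mode):
        cfg = ModelConfig(**{**tiny_config.__dict__, "branch_mode": mode})
        model = build_model(cfg, seed=0)
        ints, emb = _batch(cfg, 3)
        probs = forward(model, ints if mode == "inception_only" else None,
                        emb if mode == "transformer_only" else None)
        assert probs.shape == (3,)

    @pytest.mark.parametrize("b1,b2", [("lstm", "transformer"), ("rnn", "rnn"),
                                       ("inception", "lstm"), ("transformer", "inception")])
    def test_branch_type_combinations(self, tiny_config, b1, b2):
        cfg = ModelConfig(**{**tiny_config.__dict__, "branch1_type": b1, "branch2_type": b2})
        model = build_model(cfg, seed=0)
        ints, emb = _batch(cfg, 2)
        assert forward(model, ints, emb).shape == (2,)

    def test_unsupported_mode_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(branch_mode="both")

    def test_missing_input_raises(self, tiny_config):
        model = build_model(tiny_config, seed=0)
        ints, emb = _batch(tiny_config, 2)
        with pytest.raises(ValueError, match="branch 2"):
            model.forward(ints, None)


class TestDeterminism:
    def test_eval_forward_is_deterministic(self, tiny_config):
        model = build_model(tiny_config, seed=0)
        ints, emb = _batch(tiny_config, 4)
        np.testing.assert_array_equal(forward(model, ints, emb), forward(model, ints, emb))

    def test_duplicate_sample_same_output(self, tiny_config):
        model = build_model(tiny_config, seed=0)
        ints, emb = _batch(tiny_config, 2)
        ints[1], emb[1] = ints[0], emb[0]
        probs = forward(model, ints, emb)
        assert probs[0] == probs[1]

    def test_batch_permutation_equivariance(self, tiny_config):
        model = build_model(tiny_config, seed=0)
        ints, emb = _batch(tiny_config, 6)
        perm = np.random.default_rng(1).permutation(6)
        probs = forward(model, ints, emb)
        probs_perm = forward(model, ints[perm], emb[perm])
        np.testing.assert_allclose(probs_perm, probs[perm], atol=1e-6)

    def test_same_seed_same_parameters(self, tiny_config):
        a = build_model(tiny_config, seed=5)
        b = build_model(tiny_config, seed=5)
        assert count_parameters(a) == count_parameters(b)
        for (_, pa), (_, pb) in zip(a.named_parameters(), b.named_parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestParameterCount:
    def test_hand_counted_linear(self):
        lin = Linear(2, 3, np.random.default_rng(0))
        assert sum(p.data.size for p in lin.parameters()) == 9

    def test_dual_exceeds_single_branch(self, tiny_config):
        dual = build_model(tiny_config, seed=0)
        single = build_model(
            ModelConfig(**{**tiny_config.__dict__, "branch_mode": "transformer_only"}), seed=0)
        assert count_parameters(dual) > count_parameters(single)


class TestSerialization:
    def test_save_load_bit_exact(self, tmp_path, tiny_config):
        model = build_model(tiny_config, seed=3)
        ints, emb = _batch(tiny_config, 3)
        before = forward(model, ints, emb)
        path = tmp_path / "model.npz"
        save_model(model, path)
        reloaded = load_model(path)
        np.testing.assert_array_equal(forward(reloaded, ints, emb), before)

    def test_config_json_round_trip(self):
        cfg = compact_config(epochs=7, dropout_other=0.4)
        back = ModelConfig.from_json(cfg.to_json())
        assert back == cfg
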