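"""Positional profiles, enrichment statistics, attribution, A/G classifier."""

import numpy as np
import pytest

from intrans5hmc.metrics import METRIC_NAMES
from intrans5hmc.network import ModelConfig, build_model
from intrans5hmc.neighbourhood import (
    DEFAULT_RANGES,
    RegionSpec,
    ag_counts,
    ag_region_classifier,
    positional_profile,
    range_attribution,
    region_counts,
    two_sample_enrichment,
)
from intrans5hmc.samples import RnaSample, SampleSet
from intrans5hmc.simulate import GeneratorConfig, MotifSpec, generate_dataset, generate_split_bundle
from intrans5hmc.training import TrainedModel, train


def _toy_set() -> SampleSet:
    flank = "A" * 20
    samples = [
        RnaSample("p1", flank + "C" + "G" * 20, 1),
        RnaSample("p2", flank + "C" + "U" * 20, 1),
        RnaSample("n1", flank + "C" + "G" * 20, 0),
    ]
    return SampleSet(samples)


class TestProfiles:
    def test_constant_flank(self):
        prof = positional_profile(_toy_set(), 1)
        assert prof.freq[:20, 0].tolist() == [1.0] * 20  # all A upstream

    def test_center_is_always_c(self, small_motif_set):
        for label in (0, 1):
            prof = positional_profile(small_motif_set, label)
            assert prof.freq[20, 1] == 1.0

    def test_hand_tally(self):
        prof = positional_profile(_toy_set(), 1)
        # downstream of the two positives: one all-G, one all-U
        np.testing.assert_allclose(prof.freq[25], [0.0, 0.0, 0.5, 0.5])

    def test_rows_sum_to_one(self, small_null_set):
        prof = positional_profile(small_null_set, 0)
        np.testing.assert_allclose(prof.freq.sum(axis=1), 1.0)

    def test_empty_class_rejected(self):
        only_pos = SampleSet([RnaSample("p", "A" * 20 + "C" + "G" * 20, 1)])
        with pytest.raises(ValueError):
            positional_profile(only_pos, 0)


class TestRegions:
    def test_additivity(self, small_motif_set):
        prof = positional_profile(small_motif_set, 1)
        table = region_counts(prof)
        np.testing.assert_allclose(
            table.loc["upstream"] + table.loc["center"] + table.loc["downstream"],
            table.loc["full"], atol=1e-12)

    def test_upstream_spans_twenty_positions(self):
        spec = RegionSpec()
        assert spec.upstream == (0, 20)
        prof = positional_profile(_toy_set(), 1)
        assert region_counts(prof, spec).loc["upstream"].sum() == pytest.approx(20.0)

    def test_hand_arithmetic(self):
        table = region_counts(positional_profile(_toy_set(), 1))
        assert table.loc["upstream", "A"] == pytest.approx(20.0)
        assert table.loc["downstream", "G"] == pytest.approx(10.0)
        assert table.loc["motif", "G"] == pytest.approx(3.0)  # 6 positions, half G

    def test_out_of_bounds_region(self):
        with pytest.raises(ValueError):
            RegionSpec(motif=(21, 42))


class TestEnrichment:
    def test_null_case(self, small_null_set):
        prof = positional_profile(small_null_set, 0)
        out = two_sample_enrichment(prof, prof)
        np.testing.assert_allclose(out.difference, 0.0)
        np.testing.assert_allclose(out.p_value, 1.0)

    def test_planted_delta_detected(self):
        data = generate_dataset(
            GeneratorConfig(n_pos=500, n_neg=500, seed=42, motif=MotifSpec(a_delta=0.3)))
        pos = positional_profile(data, 1)
        neg = positional_profile(data, 0)
        out = two_sample_enrichment(pos, neg)
        a = 0  # column of nucleotide A
        assert (out.difference[21:27, a] > 0).all()
        assert (out.p_value[21:27, a] < 0.05).all()

    def test_differences_sum_to_zero_per_position(self, small_motif_set):
        pos = positional_profile(small_motif_set, 1)
        neg = positional_profile(small_motif_set, 0)
        out = two_sample_enrichment(pos, neg)
        np.testing.assert_allclose(out.difference.sum(axis=1), 0.0, atol=1e-12)

    def test_bh_adjustment_monotone(self, small_motif_set):
        pos = positional_profile(small_motif_set, 1)
        neg = positional_profile(small_motif_set, 0)
        raw = two_sample_enrichment(pos, neg, adjust=False)
        adj = two_sample_enrichment(pos, neg, adjust=True)
        assert (adj.p_value >= raw.p_value - 1e-12).all()

    def test_zero_sample_size_rejected(self, small_null_set):
        prof = positional_profile(small_null_set, 0)
        with pytest.raises(ValueError):
            two_sample_enrichment(prof, prof, n_pos=0, n_neg=10)


@pytest.fixture(scope="module")
def trained_tiny():
    data = generate_dataset(
        GeneratorConfig(n_pos=60, n_neg=60, seed=8, motif=MotifSpec(a_delta=0.5)))
    cfg = ModelConfig(branch_mode="inception_only", learning_rate=1e-3,
                      epochs=6, batch_size=32)
    return train(data, None, cfg, seed=0), data


class TestRangeAttribution:
    def test_constant_model_attributes_nothing(self, small_null_set):
        cfg = ModelConfig(branch_mode="inception_only", epochs=1)
        model = build_model(cfg, seed=0)
        model.head2.weight.data[:] = 0.0  # force a constant output
        model.head2.bias.data[:] = 0.0
        trained = TrainedModel(model=model, config=cfg, history=[0.0], seed=0)
        out = range_attribution(trained, small_null_set.subset(range(4)),
                                n_permutations=4, seed=0, max_samples=4)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-7)

    def test_output_shape_matches_ranges(self, trained_tiny):
        trained, data = trained_tiny
        out = range_attribution(trained, data, ranges=DEFAULT_RANGES,
                                n_permutations=4, seed=1, max_samples=6)
        assert out.values.shape == (len(DEFAULT_RANGES),)
        assert (out.values >= 0).all()

    def test_grad_input_method(self, trained_tiny):
        trained, data = trained_tiny
        out = range_attribution(trained, data.subset(range(8)), method="grad_input")
        assert out.values.shape == (len(DEFAULT_RANGES),)
        assert out.method == "grad_input"

    def test_invalid_range_rejected(self, trained_tiny):
        trained, data = trained_tiny
        with pytest.raises(ValueError):
            range_attribution(trained, data, ranges=((0, 50),))

    def test_transformer_only_model_rejected(self, tiny_config, small_null_set,
                                             tiny_provider):
        cfg = ModelConfig(**{**tiny_config.__dict__, "branch_mode": "transformer_only",
                             "epochs": 1})
        trained = train(small_null_set, tiny_provider, cfg, seed=0)
        with pytest.raises(ValueError, match="sequence branch"):
            range_attribution(trained, small_null_set)


class TestAgClassifier:
    def test_feature_bounds(self, small_motif_set):
        feats = ag_counts(small_motif_set)
        assert feats.shape == (len(small_motif_set), 2)
        assert (feats.sum(axis=1) <= 6).all()
        assert (feats >= 0).all()

    def test_recovers_planted_signal(self):
        cfg = GeneratorConfig(n_pos=500, n_neg=500, seed=17, motif=MotifSpec(a_delta=0.3))
        train_set, test_set, _ = generate_split_bundle(cfg, 0.8)
        report = ag_region_classifier(train_set, test_set, seed=0)
        assert report.BACC > 0.6
        assert all(0 <= getattr(report, m) <= 1 for m in METRIC_NAMES if m != "MCC")

    def test_overlap_guard(self, small_motif_set):
        with pytest.raises(ValueError, match="overlap"):
            ag_region_classifier(small_motif_set, small_motif_set)

    def test_invalid_region(self, small_motif_set):
        with pytest.raises(ValueError):
            ag_counts(small_motif_set, region=(40, 45))
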