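"""Descriptor dimensionalities, worked examples and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_sequence
from intrans5hmc import descriptors as D
from intrans5hmc.samples import SequenceValidationError

COMPOSITION = ["NAC", "DNC", "TNC", "Kmer", "RCKmer", "PseDNC", "PCPseDNC"]

seq41 = st.builds(
    lambda chars: "".join(chars[:20]) + "C" + "".join(chars[20:]),
    st.lists(st.sampled_from("ACGU"), min_size=40, max_size=40),
)


class TestRegistry:
    def test_exactly_fourteen_descriptors(self):
        assert len(D.descriptor_registry()) == 14

    @pytest.mark.parametrize(
        "name, length",
        [("ANF", 41), ("binary", 164), ("DAC", 12), ("DNC", 16), ("EIIP", 41),
         ("ENAC", 148), ("Kmer", 16), ("NAC", 4), ("NCP", 123), ("PCPseDNC", 18),
         ("PseDNC", 18), ("PseEIIP", 64), ("RCKmer", 10), ("TNC", 64)],
    )
    def test_expected_lengths(self, name, length, rng):
        func, expected = D.descriptor_registry()[name]
        assert expected == length
        out = func(random_sequence(rng))
        assert out.shape == (length,)
        assert np.isfinite(out).all()
        assert len(D.component_names(name)) == length

    @given(seq41)
    @settings(max_examples=25, deadline=None)
    def test_composition_descriptors_sum_to_one(self, seq):
        for name in COMPOSITION:
            func, _ = D.descriptor_registry()[name]
            assert abs(func(seq).sum() - 1.0) < 1e-9, name


class TestKmerComposition:
    def test_uniform_toy(self):
        assert D.kmer_composition("ACGU", 1).tolist() == [0.25, 0.25, 0.25, 0.25]

    def test_single_kmer_toy(self):
        out = D.kmer_composition("AAAA", 2)
        assert out[0] == 1.0 and out[1:].sum() == 0.0

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            D.kmer_composition("ACGU", 0)


class TestRcKmer:
    def test_ten_classes(self):
        reps, _ = D._rc_classes(2)
        assert len(reps) == 10

    def test_hand_enumeration_aauu(self):
        # dinucleotides AA, AU, UU; classes {AA,UU} and {AU}
        out = D.rc_kmer("AAUU")
        reps, _ = D._rc_classes(2)
        assert out[reps.index("AA")] == pytest.approx(2 / 3)
        assert out[reps.index("AU")] == pytest.approx(1 / 3)
        assert out.sum() == pytest.approx(1.0)

    @given(seq41)
    @settings(max_examples=25, deadline=None)
    def test_reverse_complement_invariance(self, seq):
        rc = D.reverse_complement(seq)
        np.testing.assert_allclose(D.rc_kmer(seq), D.rc_kmer(rc), atol=1e-12)


class TestPositionalDescriptors:
    def test_one_hot_blocks(self, rng):
        seq = random_sequence(rng)
        out = D.one_hot_binary(seq).reshape(41, 4)
        assert (out.sum(axis=1) == 1.0).all()
        assert out[0].tolist() == [1.0 if seq[0] == c else 0.0 for c in "ACGU"]

    def test_anf_hand_enumeration(self):
        np.testing.assert_allclose(D.anf("AACA"), [1, 1, 1 / 3, 3 / 4])

    def test_anf_constant_sequence(self):
        assert D.anf("AAAA").tolist() == [1, 1, 1, 1]

    @given(seq41)
    @settings(max_examples=25, deadline=None)
    def test_anf_first_element_is_one(self, seq):
        assert D.anf(seq)[0] == 1.0

    def test_eiip_lookup_prefix(self):
        np.testing.assert_allclose(D.eiip_profile("ACGU"), [0.1260, 0.1340, 0.0806, 0.1335])

    def test_eiip_all_positive(self, rng):
        assert (D.eiip_profile(random_sequence(rng)) > 0).all()

    def test_pse_eiip_poly_a(self):
        out = D.pse_eiip("AAAAAA")
        assert out[0] == pytest.approx(3 * 0.1260)
        assert out[1:].sum() == 0.0

    def test_ncp_codes_distinct(self):
        codes = {nt: tuple(D.ncp(nt * 2)[:3]) for nt in "ACGU"}
        assert len(set(codes.values())) == 4
        assert codes["A"] == (1, 1, 1)

    def test_enac_blocks(self, rng):
        out = D.enac(random_sequence(rng)).reshape(37, 4)
        np.testing.assert_allclose(out.sum(axis=1), 1.0)

    def test_enac_poly_a_first_block(self):
        seq = "A" * 20 + "C" + "A" * 20
        assert D.enac(seq)[:4].tolist() == [1.0, 0.0, 0.0, 0.0]


def dac_oracle(seq: str, max_lag: int) -> np.ndarray:
    """Brute-force double loop, written independently of the array code."""
    props = D.dinuc_property_table()
    dinucs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    out = []
    for p in range(len(props.property_names)):
        vals = [props.row(d)[p] for d in dinucs]
        mean_p = sum(vals) / len(vals)
        for g in range(1, max_lag + 1):
            acc = 0.0
            for i in range(len(vals) - g):
                acc += (vals[i] - mean_p) * (vals[i + g] - mean_p)
            out.append(acc / (len(vals) - g))
    return np.array(out)


def pse_dnc_oracle(seq: str, lam: int, weight: float, variant: str) -> np.ndarray:
    props = D.dinuc_property_table()
    dinucs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    kmers = ["".join((a, b)) for a in "ACGU" for b in "ACGU"]
    freqs = [dinucs.count(m) / len(dinucs) for m in kmers]
    thetas = []
    for j in range(1, lam + 1):
        acc = 0.0
        for i in range(len(dinucs) - j):
            r1, r2 = props.row(dinucs[i]), props.row(dinucs[i + j])
            if variant == "series":
                corr = sum((a - b) ** 2 for a, b in zip(r1, r2)) / len(r1)
            else:
                corr = sum(a * b for a, b in zip(r1, r2)) / len(r1)
            acc += corr
        thetas.append(acc / (len(dinucs) - j))
    denom = 1.0 + weight * sum(thetas)
    return np.array([f / denom for f in freqs] + [weight * t / denom for t in thetas])


class TestPropertyCorrelationOracles:
    @pytest.mark.parametrize("seq", ["ACGUAC", "GGCCAUU", "AUCGAUCGAU"])
    @pytest.mark.parametrize("max_lag", [1, 2])
    def test_dac_matches_brute_force(self, seq, max_lag):
        np.testing.assert_allclose(D.dac(seq, max_lag=max_lag), dac_oracle(seq, max_lag),
                                   atol=1e-9)

    @pytest.mark.parametrize("seq", ["ACGUACGU", "AAGGCCUU"])
    @pytest.mark.parametrize("variant", ["series", "parallel"])
    def test_pse_dnc_matches_brute_force(self, seq, variant):
        np.testing.assert_allclose(
            D.pse_dnc(seq, lam=1, weight=0.05, variant=variant),
            pse_dnc_oracle(seq, 1, 0.05, variant), atol=1e-9)

    def test_zero_weight_limit(self, rng):
        seq = random_sequence(rng)
        out = D.pse_dnc(seq, lam=2, weight=0.0)
        np.testing.assert_allclose(out[:16], D.dnc(seq), atol=1e-12)
        assert out[16:].tolist() == [0.0, 0.0]

    def test_dac_zero_variance_property(self):
        # all dinucleotides identical -> centered values are 0 -> covariance 0
        seq = "A" * 10
        np.testing.assert_allclose(D.dac(seq, max_lag=2), 0.0, atol=1e-12)

    def test_lag_too_large(self):
        with pytest.raises(ValueError):
            D.dac("ACG", max_lag=2)
        with pytest.raises(ValueError):
            D.pse_dnc("ACG", lam=5)

    def test_series_variant_is_nonnegative(self, rng):
        # squared-difference correlations keep every component >= 0
        out = D.pse_dnc(random_sequence(rng), variant="series")
        assert (out >= 0).all()


class TestPropertyTable:
    def test_columns_standardized(self):
        table = D.dinuc_property_table()
        np.testing.assert_allclose(table.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(table.values.std(axis=0), 1.0, atol=1e-12)

    def test_six_properties(self):
        assert len(D.dinuc_property_table().property_names) == 6


class TestFeaturize:
    def test_unknown_descriptor(self, small_null_set):
        with pytest.raises(KeyError, match="unknown descriptor"):
            D.featurize(small_null_set, "nope")

    def test_transformer_interface(self, small_null_set):
        t = D.DescriptorTransformer(descriptor="ENAC").fit(small_null_set)
        out = t.transform(small_null_set)
        assert out.shape == (len(small_null_set), 148)
        assert list(t.get_feature_names_out()[:1]) == ["win0_A"]

    def test_invalid_character_rejected(self):
        with pytest.raises(SequenceValidationError):
            D.one_hot_binary("ACGN")
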