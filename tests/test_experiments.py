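"""Experiment protocols: benchmarking, comparisons, grid search, statistics."""

import itertools

import numpy as np
import pytest

from intrans5hmc.experiments import (
    EMBEDDING_FEATURE,
    GridSpec,
    ablation_experiment,
    branch_combination_experiment,
    descriptor_benchmark,
    friedman_across_folds,
    grid_search,
    ml_baseline_experiment,
    select_best,
    wilcoxon_compare,
)
from intrans5hmc.metrics import METRIC_NAMES
from intrans5hmc.network import ModelConfig
from intrans5hmc.simulate import GeneratorConfig, MotifSpec, generate_dataset


def wilcoxon_exact_oracle(diff: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = diff[diff != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0  # no ties assumed
    w_obs = ranks[d > 0].sum()
    w_mean = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - w_mean) >= abs(w_obs - w_mean) - 1e-12:
            count += 1
    return count / 2**n


class TestDescriptorBenchmark:
    def test_table_shape(self, small_motif_set):
        table = descriptor_benchmark(small_motif_set, ["NAC", "ENAC", "Kmer"], k=3, seed=0)
        assert list(table.index) == ["NAC", "ENAC", "Kmer"]
        for metric in METRIC_NAMES:
            assert f"{metric}_mean" in table.columns and f"{metric}_std" in table.columns
        assert table.filter(like="_std").ge(0).all().all()
        assert table["BACC_mean"].between(0, 1).all()

    def test_unknown_descriptor(self, small_motif_set):
        with pytest.raises(KeyError):
            descriptor_benchmark(small_motif_set, ["NOPE"], k=2)

    def test_embedding_pseudo_descriptor(self, small_motif_set, tiny_provider):
        table = descriptor_benchmark(small_motif_set, [EMBEDDING_FEATURE], k=3,
                                     seed=0, provider=tiny_provider)
        assert len(table) == 1

    def test_position_aware_descriptor_beats_composition_on_motif(self):
        """ENAC sees where the planted A-enrichment sits; NAC cannot."""
        data = generate_dataset(
            GeneratorConfig(n_pos=150, n_neg=150, seed=21, motif=MotifSpec(a_delta=0.4)))
        means = []
        for seed in range(3):
            table = descriptor_benchmark(data, ["ENAC", "NAC"], k=3, seed=seed)
            means.append(table["BACC_mean"])
        avg = sum(means) / len(means)
        assert avg["ENAC"] > avg["NAC"]


class TestBranchCombinations:
    def test_bookkeeping_and_rerun_equality(self, small_motif_set, tiny_config,
                                            tiny_provider):
        combos = [("rnn", "rnn"), ("lstm", "rnn")]
        t1 = branch_combination_experiment(small_motif_set, combos, cfg=tiny_config,
                                           provider=tiny_provider, seeds=[1, 2])
        t2 = branch_combination_experiment(small_motif_set, combos, cfg=tiny_config,
                                           provider=tiny_provider, seeds=[1, 2])
        assert list(t1.index) == ["rnn+rnn", "lstm+rnn"]
        assert (t1["n_repeats"] == 2).all()
        assert t1.filter(like="_std").ge(0).all().all()
        np.testing.assert_array_equal(t1.values, t2.values)
        assert t1.attrs["manifest"]["seeds"] == [1, 2]

    def test_invalid_branch_type(self, small_motif_set, tiny_config, tiny_provider):
        with pytest.raises(ValueError):
            branch_combination_experiment(small_motif_set, [("cnn", "rnn")],
                                          cfg=tiny_config, provider=tiny_provider,
                                          seeds=[1])


class TestMlBaselines:
    def test_roster_and_sanity(self, tiny_provider):
        data = generate_dataset(
            GeneratorConfig(n_pos=80, n_neg=80, seed=13, motif=MotifSpec(a_delta=0.5,
                                                                         g_delta=0.2)))
        table = ml_baseline_experiment(data, tiny_provider, seeds=[1, 2, 3])
        assert sorted(table.index) == ["KNN", "LogisticRegression", "SVM", "XGBoost"]
        # mean-pooled synthetic embeddings carry the motif signal
        assert (table["BACC_mean"] > 0.5).all()


class TestAblation:
    def test_rows_and_overlap_guard(self, small_motif_set, tiny_config, tiny_provider):
        train = small_motif_set.subset(range(0, 120))
        test = small_motif_set.subset(range(120, 160))
        table = ablation_experiment(train, test, tiny_provider, cfg=tiny_config, seeds=[1])
        assert list(table.index) == ["inception_only", "transformer_only", "dual"]
        with pytest.raises(ValueError, match="overlap"):
            ablation_experiment(train, train, tiny_provider, cfg=tiny_config, seeds=[1])


class TestGridSearch:
    def test_single_cell_grid(self, small_motif_set, tiny_config, tiny_provider):
        grid = GridSpec(epochs=(2,), dropout_inception=(0.5,), dropout_other=(0.3,))
        best, scores = grid_search(small_motif_set, grid, provider=tiny_provider,
                                   cfg=tiny_config, seed=0)
        assert len(scores) == 1
        assert (best.epochs, best.dropout_inception, best.dropout_other) == (2, 0.5, 0.3)

    def test_full_grid_enumerates_27(self):
        assert len(GridSpec().combinations()) == 27

    def test_selection_is_pure_function_of_table(self, small_motif_set, tiny_config,
                                                 tiny_provider):
        grid = GridSpec(epochs=(1, 2), dropout_inception=(0.3,), dropout_other=(0.3, 0.5))
        best, scores = grid_search(small_motif_set, grid, provider=tiny_provider,
                                   cfg=tiny_config, seed=1)
        reselected = select_best(scores)
        assert reselected["epochs"] == best.epochs
        assert reselected["dropout_other"] == best.dropout_other
        # returned config is an element of the grid
        assert best.epochs in grid.epochs
        assert best.dropout_other in grid.dropout_other

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(epochs=())


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        out = wilcoxon_compare(np.ones(6), np.ones(6))
        assert out["p_value"] == 1.0 and out["degenerate"]

    def test_all_pairs_greater_exact_p(self):
        a = np.arange(10) + 1.0
        b = np.arange(10) * 0.5
        out = wilcoxon_compare(a, b)
        assert out["p_value"] == pytest.approx(2 / 1024)
        assert out["direction"] == "a>b"

    def test_swap_flips_direction_same_p(self):
        rng = np.random.default_rng(3)
        a = rng.random(8) + 0.5
        b = rng.random(8)
        ab = wilcoxon_compare(a, b)
        ba = wilcoxon_compare(b, a)
        assert ab["p_value"] == pytest.approx(ba["p_value"])
        assert {ab["direction"], ba["direction"]} == {"a>b", "a<b"}

    @pytest.mark.parametrize("n", [6, 9, 12])
    def test_matches_exact_enumeration(self, n):
        rng = np.random.default_rng(n)
        a = rng.random(n)
        b = rng.random(n)
        out = wilcoxon_compare(a, b)
        assert out["p_value"] == pytest.approx(wilcoxon_exact_oracle(a - b), abs=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            wilcoxon_compare(np.ones(3), np.zeros(3))


class TestFriedman:
    def test_identical_columns(self):
        m = np.tile(np.random.default_rng(0).random(10)[:, None], (1, 3))
        out = friedman_across_folds(m)
        assert out["p_value"] == 1.0 and out["degenerate"]

    def test_dominating_condition_significant(self):
        rng = np.random.default_rng(1)
        base = rng.random((10, 3))
        base[:, 0] += 2.0  # strictly dominates in every fold
        out = friedman_across_folds(base)
        assert out["p_value"] < 0.05

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        m = rng.random((8, 4))
        a = friedman_across_folds(m)
        b = friedman_across_folds(np.exp(3 * m))
        assert a["statistic"] == pytest.approx(b["statistic"])
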