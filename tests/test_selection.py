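import math

import numpy as np
import pandas as pd
import pytest

from cooctex.config import GAParams
from cooctex.errors import ValidationError
from cooctex.selection import (
    CfsEvaluator,
    cfs_merit,
    genetic_search,
    info_gain,
    mdl_discretize,
    merit_from_correlations,
    select_union,
    symmetrical_uncertainty,
)
from helpers import exhaustive_cfs_optimum


def make_table(rng, n=60, informative=1, noise=5, gap=4.0):
    """Two-class table: `informative` shifted-mean columns plus pure noise."""
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    cols = {}
    for i in range(informative):
        shift = np.where(y == "a", 0.0, gap)
        cols[f"inf{i}"] = rng.normal(0, 1, n) + shift
    for i in range(noise):
        cols[f"noise{i}"] = rng.normal(0, 1, n)
    df = pd.DataFrame(cols)
    df["class"] = y
    return df


class TestMdlDiscretize:
    def test_separated_classes_single_cut_near_zero(self, rng):
        values = np.concatenate([rng.uniform(-2, -0.5, 30), rng.uniform(0.5, 2, 30)])
        classes = np.array(["a"] * 30 + ["b"] * 30)
        cuts = mdl_discretize(values, classes)
        assert len(cuts) == 1
        assert -0.5 <= cuts[0] <= 0.5

    def test_class_independent_noise_has_no_cuts(self, rng):
        values = rng.uniform(0, 1, 80)
        classes = rng.choice(["a", "b"], 80)
        assert len(mdl_discretize(values, classes)) == 0

    def test_constant_column_single_bin(self):
        cuts = mdl_discretize(np.zeros(10), np.array(list("ababababab")))
        assert len(cuts) == 0

    def test_two_clusters_three_classes_gets_cut(self, rng):
        # cluster 1 holds class a, cluster 2 holds classes b and c
        values = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(5, 0.1, 40)])
        classes = np.array(["a"] * 20 + ["b"] * 20 + ["c"] * 20)
        assert len(mdl_discretize(values, classes)) >= 1

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            mdl_discretize(np.arange(3), np.array(["a", "b", "a"]))


class TestSymmetricalUncertainty:
    def test_identical_columns_give_one(self):
        a = np.array([0, 1, 0, 1, 2, 2])
        assert symmetrical_uncertainty(a, a) == 1.0

    def test_constant_column_gives_zero(self):
        assert symmetrical_uncertainty(np.zeros(10), np.arange(10)) == 0.0
        assert symmetrical_uncertainty(np.zeros(10), np.zeros(10)) == 0.0

    def test_independent_coins_approach_zero(self):
        rng = np.random.default_rng(12345)
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        assert symmetrical_uncertainty(a, b) < 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            symmetrical_uncertainty(np.zeros(3), np.zeros(4))

    def test_su_zero_iff_info_gain_zero(self, rng):
        for _ in range(10):
            a = rng.integers(0, 3, 40)
            b = rng.integers(0, 3, 40)
            su = symmetrical_uncertainty(a, b)
            ig = info_gain(a, b)
            assert (su == 0.0) == (ig == 0.0)


class TestInfoGain:
    def test_attr_identical_to_class_gives_class_entropy(self):
        cls = np.array(["a"] * 5 + ["b"] * 15)
        attr = (cls == "a").astype(int)
        h_c = -(0.25 * math.log2(0.25) + 0.75 * math.log2(0.75))
        assert info_gain(attr, cls) == pytest.approx(h_c, abs=1e-12)

    def test_constant_attr_gives_zero(self):
        assert info_gain(np.zeros(10), np.array(list("ababababab"))) == 0.0

    def test_printed_contingency_hand_value(self):
        # contingency {A: (8, 2), B: (2, 8)}: H(C) = 1 bit,
        # H(C|A) = -(0.8 log2 0.8 + 0.2 log2 0.2) = 0.721928..., IG = 0.278072
        attr = np.array([0] * 10 + [1] * 10)
        cls = np.array(["A"] * 8 + ["B"] * 2 + ["A"] * 2 + ["B"] * 8)
        assert info_gain(attr, cls) == pytest.approx(0.27807190511263774, abs=1e-12)


class TestCfsMerit:
    def test_singleton_reduces_to_su(self, rng):
        df = make_table(rng, n=40, informative=1, noise=2)
        evaluator = CfsEvaluator(df)
        assert evaluator.merit(["inf0"]) == pytest.approx(
            evaluator.su_class["inf0"], abs=1e-12
        )

    def test_zero_redundancy_identity(self):
        # r_ff = 0  =>  Merit = sqrt(k) * r_cf
        assert merit_from_correlations(4, 0.3, 0.0) == pytest.approx(2 * 0.3)
        assert merit_from_correlations(1, 0.7, 0.0) == pytest.approx(0.7)

    def test_three_feature_hand_substitution(self, rng):
        df = make_table(rng, n=50, informative=2, noise=1)
        evaluator = CfsEvaluator(df)
        names = ["inf0", "inf1", "noise0"]
        r_cf = np.mean([evaluator.su_class[n] for n in names])
        r_ff = np.mean(
            [
                evaluator.su_pair("inf0", "inf1"),
                evaluator.su_pair("inf0", "noise0"),
                evaluator.su_pair("inf1", "noise0"),
            ]
        )
        by_hand = 3 * r_cf / math.sqrt(3 + 3 * 2 * r_ff)
        assert cfs_merit(names, df) == pytest.approx(by_hand, abs=1e-12)

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValidationError):
            cfs_merit([], make_table(rng))


class TestGeneticSearch:
    def test_defaults_match_reference_parameters(self):
        ga = GAParams()
        assert ga.population_size == 20
        assert ga.generations == 20
        assert ga.crossover_prob == 0.6
        assert ga.mutation_prob == 0.033
        assert ga.seed == 1

    def test_recovers_predictive_feature(self, rng):
        df = make_table(rng, n=60, informative=1, noise=9, gap=6.0)
        subset, merit = genetic_search(df)
        assert "inf0" in subset
        oracle_subset, oracle_merit = exhaustive_cfs_optimum(df)
        assert merit == pytest.approx(oracle_merit, abs=1e-12)

    def test_deterministic_under_fixed_seed(self, rng):
        df = make_table(rng, n=40, informative=2, noise=4)
        assert genetic_search(df) == genetic_search(df)

    def test_never_worse_than_best_singleton(self, rng):
        df = make_table(rng, n=40, informative=2, noise=6)
        evaluator = CfsEvaluator(df)
        _, merit = genetic_search(df, evaluator=evaluator)
        best_single = max(evaluator.merit([n]) for n in evaluator.feature_names)
        assert merit >= best_single - 1e-12


class TestSelectUnion:
    def test_union_rule(self, rng):
        df = make_table(rng, n=60, informative=2, noise=8, gap=5.0)
        result = select_union(df, ig_top_k=3)
        assert set(result.final_set) == set(result.cfs_subset) | set(result.ig_selected)
        assert "inf0" in result.final_set and "inf1" in result.final_set

    def test_zero_topk_reduces_to_cfs(self, rng):
        df = make_table(rng, n=60, informative=1, noise=4, gap=5.0)
        result = select_union(df, ig_top_k=0)
        assert set(result.final_set) == set(result.cfs_subset)

    def test_topk_capped_at_feature_count(self, rng):
        df = make_table(rng, n=40, informative=1, noise=2)
        result = select_union(df, ig_top_k=50)
        assert result.ig_top_k == 3  # capped at the feature count

    def test_all_noise_table_small_set_low_merit(self, rng):
        df = make_table(rng, n=60, informative=0, noise=8)
        result = select_union(df, ig_top_k=0)
        _, oracle_merit = exhaustive_cfs_optimum(df)
        assert result.cfs_merit == pytest.approx(oracle_merit, abs=1e-12)
        assert result.cfs_merit <= 0.05
        assert len(result.final_set) >= 1  # never empty

    def test_json_roundtrip(self, rng, tmp_path):
        from cooctex.selection import SelectionResult

        df = make_table(rng, n=40, informative=1, noise=3)
        result = select_union(df, ig_top_k=2)
        path = tmp_path / "sel.json"
        result.to_json(path)
        back = SelectionResult.from_json(path)
        assert back == result
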