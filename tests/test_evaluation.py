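"""Metric definitions, oracle cross-checks, and experiment protocols."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, strategies as st

from nutrigraph import (
    ETLConfig,
    GeneratorConfig,
    MetricConfig,
    RankingConfig,
    Target,
    UserProfile,
    ValidationError,
    ablation_experiment,
    balance_variance,
    coverage_score,
    dv_deviation,
    evaluate_ranking,
    gen_tables,
    label_relevance,
    ndcg_at_k,
    perturbation_experiment,
    precision_at_k,
    rank_foods,
    rank_stability,
    run_etl,
    score_candidates,
)
from nutrigraph.ranking import CappedVector, ScoredFood, TraceEntry


def _scored(pct_dvs):
    nutrients = tuple(f"n{i}" for i in range(len(pct_dvs)))
    return ScoredFood(
        code="X",
        name="x",
        score=0.0,
        vector=CappedVector(
            nutrients, tuple(min(p / 100.0, 1.0) for p in pct_dvs)
        ),
        trace=tuple(
            TraceEntry("d", n, 100.0, "mg", p, p)
            for n, p in zip(nutrients, pct_dvs)
        ),
    )


class TestRelevanceAndPrecision:
    def test_two_of_three_thresholds_is_relevant(self):
        assert label_relevance(_scored([25, 30, 22]), {}, MetricConfig()) == 1
        assert label_relevance(_scored([50, 5, 2]), {}, MetricConfig()) == 0
        assert label_relevance(_scored([0, 0, 0]), {}, MetricConfig()) == 0

    @pytest.mark.parametrize(
        "labels, k, expected",
        [([1, 1, 1, 1, 0], 5, 0.8), ([1, 0, 0, 0, 0], 5, 0.2), ([1, 1, 1], 3, 1.0)],
    )
    def test_precision_examples(self, labels, k, expected):
        assert precision_at_k(labels, k) == pytest.approx(expected)

    def test_k_beyond_list_rejected(self):
        with pytest.raises(ValidationError):
            precision_at_k([1, 0], 5)


class TestNdcg:
    def test_single_relevant_at_rank_one_is_ideal(self):
        assert ndcg_at_k([1, 0, 0, 0, 0], 5) == pytest.approx(1.0)

    def test_single_relevant_at_rank_five(self):
        expected = (1 / math.log2(6)) / (1 / math.log2(2))
        assert ndcg_at_k([0, 0, 0, 0, 1], 5) == pytest.approx(expected)
        assert expected == pytest.approx(0.3869, abs=1e-4)

    def test_no_relevant_items_scores_zero(self):
        assert ndcg_at_k([0, 0, 0, 0, 0], 5) == 0.0

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValidationError):
            ndcg_at_k([0, 2, 0], 3)

    @given(
        labels=st.lists(st.integers(0, 1), min_size=2, max_size=8),
        i=st.integers(0, 7),
        j=st.integers(0, 7),
    )
    def test_promoting_a_relevant_item_never_hurts(self, labels, i, j):
        i, j = sorted((i % len(labels), j % len(labels)))
        if labels[j] != 1 or labels[i] == labels[j]:
            return
        promoted = list(labels)
        promoted[i], promoted[j] = promoted[j], promoted[i]
        k = len(labels)
        assert ndcg_at_k(promoted, k) >= ndcg_at_k(labels, k)


class TestRankStability:
    def test_identity_and_reversal(self):
        assert rank_stability(list("abc"), list("abc")) == pytest.approx(1.0)
        assert rank_stability(list("abc"), list("cba")) == pytest.approx(-1.0)

    def test_full_shuffle_drops_below_half(self):
        rss = rank_stability(["f1", "f2", "f3"], ["f3", "f1", "f2"])
        assert rss == pytest.approx(-0.5)
        assert rss < 0.5

    def test_symmetry(self):
        a, b = ["w", "x", "y", "z"], ["y", "w", "z", "x"]
        assert rank_stability(a, b) == pytest.approx(rank_stability(b, a))

    def test_item_set_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            rank_stability(["a", "b"], ["a", "c"])

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_brute_force_oracle_all_permutations(self, n):
        """Eq-form result equals rank-vector Pearson correlation (scipy)."""
        base = [f"f{i}" for i in range(n)]
        for perm in itertools.permutations(base):
            ranks_a = [base.index(x) + 1 for x in base]
            ranks_b = [list(perm).index(x) + 1 for x in base]
            expected = scipy.stats.spearmanr(ranks_a, ranks_b).statistic
            assert rank_stability(base, list(perm)) == pytest.approx(expected)


class TestNutritionalMetrics:
    @pytest.mark.parametrize(
        "values, expected", [([90], 10.0), ([15], 85.0), ([150], 0.0)]
    )
    def test_dv_deviation_examples(self, values, expected):
        assert dv_deviation(values) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "values, expected",
        [([50, 5, 2], 1 / 3), ([25, 30, 22], 1.0), ([1, 2, 3], 0.0)],
    )
    def test_coverage_examples(self, values, expected):
        assert coverage_score(values, tau_cov=20.0) == pytest.approx(expected)

    def test_balance_variance_examples(self):
        assert balance_variance([0.5, 0.5, 0.5]) == 0.0
        assert balance_variance([1.0, 0.05]) == pytest.approx(0.225625)

    @given(
        values=st.lists(st.floats(0, 300, allow_nan=False), min_size=1, max_size=10)
    )
    def test_metric_ranges(self, values):
        assert 0.0 <= dv_deviation(values) <= 100.0
        assert 0.0 <= coverage_score(values) <= 1.0
        capped = [min(v / 300.0, 1.0) for v in values]
        assert balance_variance(capped) >= 0.0

    def test_empty_inputs_rejected(self):
        for fn in (dv_deviation, coverage_score, balance_variance):
            with pytest.raises(ValidationError):
                fn([])


class TestPerturbation:
    def test_zero_delta_is_perfectly_stable(self, walkthrough):
        graph, profile = walkthrough
        out = perturbation_experiment(
            graph, "Iron Deficiency Anemia", profile, delta=0.0
        )
        assert out["rss"] == pytest.approx(1.0)
        assert out["top_k_overlap"] == 1.0

    def test_uniform_scaling_invariance_without_caps(self, walkthrough, adult_female):
        """Scaling every RDA leaves the cosine order unchanged when no cap binds."""
        graph, _ = walkthrough
        targets = {
            n: Target(t.amount * 10, t.unit)  # inflate so no component caps
            for n, t in {
                "Iron": Target(29.0, "mg"),
                "Vitamin C": Target(65.0, "mg"),
                "Folic Acid": Target(570.0, "mcg"),
            }.items()
        }
        scaled = {n: Target(t.amount * 1.7, t.unit) for n, t in targets.items()}
        order_a = [f.code for f in score_candidates(graph, "Anemia", targets)]
        order_b = [f.code for f in score_candidates(graph, "Anemia", scaled)]
        assert order_a == order_b

    def test_synthetic_graph_is_stable_under_ten_percent(self):
        tables = gen_tables(GeneratorConfig(n_foods=50, seed=42))
        graph = run_etl(tables, ETLConfig(impute=False)).graph
        profile = UserProfile(age=30, gender="female", query_text="q")
        disease = next(iter(graph.diseases))
        out = perturbation_experiment(graph, disease, profile, delta=0.10)
        assert out["rss"] >= 0.9


class TestAblation:
    def test_capping_lowers_topk_variance(self, synthetic_graph, adult_female):
        disease = next(iter(synthetic_graph.diseases))
        out = ablation_experiment(
            synthetic_graph, [disease], [adult_female], RankingConfig(top_k=5)
        )
        assert out["cosine_capped"] < out["summation_uncapped"]

    def test_single_food_graph_identical_top1(self, tiny_tables):
        from nutrigraph import build_graph

        food = tiny_tables.food.iloc[[0]]
        graph = build_graph(
            tiny_tables.disease, food, tiny_tables.rda, tiny_tables.abbrev
        )
        profile = UserProfile(age=25, gender="female", query_text="q")
        for mode in ("cosine_capped", "summation_uncapped"):
            ranked = rank_foods(
                graph, "Anemia", profile, RankingConfig(top_k=1, mode=mode)
            )
            assert ranked[0].code == "S01"


class TestReport:
    def test_all_six_fields_within_declared_ranges(self, synthetic_graph, adult_female):
        disease = next(iter(synthetic_graph.diseases))
        report = evaluate_ranking(synthetic_graph, disease, adult_female)
        d = report.as_dict()
        assert 0.0 <= d["precision_at_k"] <= 1.0
        assert 0.0 <= d["ndcg_at_k"] <= 1.0
        assert -1.0 <= d["rank_stability"] <= 1.0
        assert 0.0 <= d["mean_dv_deviation"] <= 100.0
        assert 0.0 <= d["coverage"] <= 1.0
        assert d["balance_variance"] >= 0.0
        assert d["provenance"]["disease"] == disease
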