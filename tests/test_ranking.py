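"""RDA capping, cosine scoring, ranking order, and aggregate coverage."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nutrigraph import (
    CappedVector,
    FoodNode,
    RankingConfig,
    Target,
    UserProfile,
    ValidationError,
    aggregate_requirement_met,
    build_food_vector,
    cosine_score,
    rank_foods,
    resolve_targets,
    score_candidates,
    summation_score,
)

PREGNANCY_TARGETS = {
    "Iron": Target(27.0, "mg"),
    "Vitamin C": Target(65.0, "mg"),
    "Folic Acid": Target(570.0, "mcg"),
}

MORINGA = FoodNode(
    code="B002",
    name="Drumstick Leaves (Moringa)",
    category="Vegetables",
    composition={"Iron": 4.56, "Vitamin C": 108.0, "Folic Acid": 57.0},
)


class TestCappedVector:
    def test_component_caps_at_one_when_amount_exceeds_rda(self):
        vector = build_food_vector(MORINGA, PREGNANCY_TARGETS)
        by_name = dict(zip(vector.nutrients, vector.values))
        assert by_name["Vitamin C"] == 1.0  # 108 mg against a 65 mg target

    def test_moringa_components_match_display_rounding(self):
        vector = build_food_vector(MORINGA, PREGNANCY_TARGETS)
        by_name = dict(zip(vector.nutrients, vector.values))
        assert by_name["Iron"] == pytest.approx(0.1689, abs=1e-4)
        assert round(by_name["Iron"], 2) == 0.17
        assert by_name["Folic Acid"] == pytest.approx(0.10)

    def test_food_without_target_nutrients_is_all_zero(self):
        rice = FoodNode("R", "Rice", "Cereals", {"Protein": 2.7})
        vector = build_food_vector(rice, PREGNANCY_TARGETS)
        assert vector.values == (0.0, 0.0, 0.0)

    def test_invalid_rda_rejected(self):
        with pytest.raises(ValidationError):
            build_food_vector(MORINGA, {"Iron": Target(0.0, "mg")})

    @given(
        amounts=st.lists(st.floats(0, 200, allow_nan=False), min_size=2, max_size=6),
        bump=st.floats(0.1, 50),
        index=st.integers(0, 5),
    )
    def test_monotone_and_saturating(self, amounts, bump, index):
        index %= len(amounts)
        targets = {f"n{i}": Target(50.0, "mg") for i in range(len(amounts))}
        food = FoodNode("F", "f", "c", {f"n{i}": a for i, a in enumerate(amounts)})
        more = dict(food.composition)
        more[f"n{index}"] += bump
        v1 = build_food_vector(food, targets).values
        v2 = build_food_vector(FoodNode("F", "f", "c", more), targets).values
        assert all(b >= a for a, b in zip(v1, v2))
        for i, amount in enumerate(more.values()):
            assert (v2[i] == 1.0) == (amount >= 50.0)


class TestCosineScore:
    def test_all_ones_is_perfect(self):
        vec = CappedVector(("a", "b", "c"), (1.0, 1.0, 1.0))
        assert cosine_score(vec) == pytest.approx(1.0)

    def test_one_hot_closed_form(self):
        vec = CappedVector(("a", "b", "c"), (1.0, 0.0, 0.0))
        assert cosine_score(vec) == pytest.approx(1 / math.sqrt(3), abs=1e-4)

    def test_printed_leafy_green_vector(self):
        # the balanced leafy-green example: components 0.10 / 0.46 / 0.25
        vec = CappedVector(("a", "b", "c"), (0.10, 0.46, 0.25))
        assert cosine_score(vec) == pytest.approx(0.877, abs=1e-3)

    def test_zero_vector_scores_zero(self):
        assert cosine_score(CappedVector(("a",), (0.0,))) == 0.0

    @given(
        values=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8)
    )
    def test_bounds_and_uniform_iff_one(self, values):
        vec = CappedVector(
            tuple(f"n{i}" for i in range(len(values))), tuple(values)
        )
        score = cosine_score(vec)
        assert 0.0 <= score <= 1.0 + 1e-12
        if values[0] > 0 and all(v == values[0] for v in values):
            assert score == pytest.approx(1.0)

    @given(n=st.integers(2, 12), b=st.floats(0.01, 1.0))
    def test_uniform_always_beats_one_hot(self, n, b):
        uniform = CappedVector(
            tuple(f"n{i:02d}" for i in range(n)), (b,) * n
        )
        one_hot = CappedVector(
            tuple(f"n{i:02d}" for i in range(n)), (1.0,) + (0.0,) * (n - 1)
        )
        assert cosine_score(uniform) > cosine_score(one_hot)
        assert cosine_score(one_hot) == pytest.approx(1 / math.sqrt(n))


class TestSummationScore:
    def test_hand_sum_for_moringa(self):
        # 4.56/27 + 108/65 + 57/570, uncapped
        expected = 4.56 / 27 + 108 / 65 + 0.10
        assert summation_score(MORINGA, PREGNANCY_TARGETS) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(1.930, abs=1e-3)

    def test_zero_food_scores_zero(self):
        rice = FoodNode("R", "Rice", "Cereals", {})
        assert summation_score(rice, PREGNANCY_TARGETS) == 0.0

    def test_food_exactly_at_rda_scores_n(self):
        food = FoodNode(
            "E", "e", "c", {"Iron": 27.0, "Vitamin C": 65.0, "Folic Acid": 570.0}
        )
        assert summation_score(food, PREGNANCY_TARGETS) == pytest.approx(3.0)


class TestRankFoods:
    def test_walkthrough_order_is_deterministic(self, walkthrough):
        graph, profile = walkthrough
        first = rank_foods(graph, "Iron Deficiency Anemia", profile)
        second = rank_foods(graph, "Iron Deficiency Anemia", profile)
        assert [f.code for f in first] == [f.code for f in second]
        # balanced leafy greens on top, one-hot foods tied below in code order
        assert [f.code for f in first] == ["B001", "B002", "A003", "B003", "C001"]

    def test_tied_scores_break_by_ascending_code(self, walkthrough):
        graph, profile = walkthrough
        ranked = rank_foods(graph, "Iron Deficiency Anemia", profile)
        tied = [f for f in ranked if f.score == pytest.approx(1 / math.sqrt(3))]
        assert [f.code for f in tied] == sorted(f.code for f in tied)

    def test_balanced_beats_superfood_in_cosine_mode(self, synthetic_graph, adult_female):
        disease = next(iter(synthetic_graph.diseases))
        ranked = rank_foods(
            synthetic_graph, disease, adult_female, RankingConfig(top_k=3)
        )
        assert all(f.code.startswith("BAL") for f in ranked)

    def test_superfood_wins_under_uncapped_summation(self, synthetic_graph, adult_female):
        disease = next(iter(synthetic_graph.diseases))
        ranked = rank_foods(
            synthetic_graph,
            disease,
            adult_female,
            RankingConfig(top_k=1, mode="summation_uncapped"),
        )
        assert ranked[0].code.startswith("SUP")

    def test_trace_covers_every_required_nutrient(self, walkthrough):
        graph, profile = walkthrough
        for item in rank_foods(graph, "Iron Deficiency Anemia", profile):
            assert {e.nutrient for e in item.trace} == {
                "Iron",
                "Vitamin C",
                "Folic Acid",
            }
            assert all(e.disease == "Iron Deficiency Anemia" for e in item.trace)

    def test_brute_force_order_oracle(self, walkthrough, adult_female):
        """Order equals an independent score-then-sort on a small graph."""
        graph, _ = walkthrough
        targets = resolve_targets(graph, "Anemia", adult_female)
        expected = []
        for code, food in graph.foods.items():
            fractions = [
                min(food.composition.get(n, 0.0) / t.amount, 1.0)
                for n, t in sorted(targets.items())
            ]
            if not any(food.composition.get(n, 0.0) > 0 for n in targets):
                continue
            norm = math.sqrt(sum(f * f for f in fractions))
            score = sum(fractions) / (math.sqrt(len(fractions)) * norm) if norm else 0.0
            expected.append((-round(score, 12), code))
        expected = [code for _, code in sorted(expected)]
        ranked = score_candidates(graph, "Anemia", targets)
        assert [f.code for f in ranked] == expected


def _scored_iron_food(code, amount, rda=29.0):
    from nutrigraph import CappedVector, ScoredFood, TraceEntry

    vector = CappedVector(("Iron",), (min(amount / rda, 1.0),))
    trace = (
        TraceEntry(
            disease="Anemia",
            nutrient="Iron",
            rda=rda,
            unit="mg",
            amount=amount,
            pct_dv=100.0 * amount / rda,
        ),
    )
    return ScoredFood(code=code, name=code, score=0.0, vector=vector, trace=trace)


class TestAggregateRequirement:
    def test_printed_iron_aggregate(self):
        # top foods supplying 47.04 mg of iron against a 29 mg target
        targets = {"Iron": Target(29.0, "mg")}
        ranked = [
            _scored_iron_food(f"F{i}", amount)
            for i, amount in enumerate([20.0, 15.0, 12.04])
        ]
        pct = aggregate_requirement_met(ranked, "Iron", targets)
        assert round(pct, 1) == 162.2

    def test_single_food_at_rda_is_100(self, walkthrough):
        graph, profile = walkthrough
        ranked = rank_foods(graph, "Iron Deficiency Anemia", profile)
        guava = [f for f in ranked if f.code == "C001"]
        assert (
            aggregate_requirement_met(
                guava, "Vitamin C", {"Vitamin C": Target(214.0, "mg")}
            )
            == pytest.approx(100.0)
        )

    def test_unknown_nutrient_rejected(self, walkthrough):
        graph, profile = walkthrough
        ranked = rank_foods(graph, "Iron Deficiency Anemia", profile)
        with pytest.raises(ValidationError):
            aggregate_requirement_met(ranked, "Zinc", PREGNANCY_TARGETS)
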