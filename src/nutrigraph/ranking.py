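"""RDA-capped nutrient vectors and cosine ranking of candidate foods.

For a disease with required nutrients ``N_req`` and a profile-resolved
target map ``RDA_user``, each candidate food f gets the capped vector

    V_f[i] = min(Amount_f,i / RDA_user,i, 1.0)

and is scored by cosine similarity to the ideal all-ones target. Capping
means one extreme nutrient cannot dominate: a uniform vector (b, ..., b)
always scores 1 while a one-hot vector scores 1/sqrt(n), so balanced foods
outrank single-nutrient "superfoods". The uncapped summation score
``sum_i Amount_i / RDA_i`` is kept as the ablation baseline that exhibits
exactly that superfood bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Tuple

import numpy as np

from .errors import NoCandidatesError, ValidationError
from .graph_store import FoodNode, KnowledgeGraph, candidate_foods, required_nutrients
from .profile_matching import TargetMap, UserProfile, resolve_targets

MODES = ("cosine_capped", "summation_uncapped", "cosine_magnitude")


@dataclass(frozen=True)
class CappedVector:
    """Values in [0, 1] over a lexicographically ordered nutrient axis."""

    nutrients: Tuple[str, ...]
    values: Tuple[float, ...]

    def __post_init__(self):
        if tuple(sorted(self.nutrients)) != self.nutrients:
            raise ValidationError("nutrient axis must be sorted")
        if any(not (0.0 <= v <= 1.0) for v in self.values):
            raise ValidationError("capped components must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


class TraceEntry(NamedTuple):
    """One Disease -> Nutrient -> Food explanation step."""

    disease: str
    nutrient: str
    rda: float
    unit: str
    amount: float
    pct_dv: float  # uncapped percent of the daily target


@dataclass
class ScoredFood:
    code: str
    name: str
    score: float
    vector: CappedVector
    trace: Tuple[TraceEntry, ...]


@dataclass
class RankingConfig:
    top_k: int = 10
    mode: str = "cosine_capped"
    score_decimals: int = 2  # display only; scores kept at full precision

    def __post_init__(self):
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if self.mode not in MODES:
            raise ValidationError(f"unknown ranking mode {self.mode!r}")


def build_food_vector(food: FoodNode, targets: TargetMap) -> CappedVector:
    """Capped per-nutrient fractions of the daily target; absent -> 0."""
    if not targets:
        raise ValidationError("target map is empty")
    axis = tuple(sorted(targets))
    values = []
    for nutrient in axis:
        rda = targets[nutrient].amount
        if not (rda > 0 and math.isfinite(rda)):
            raise ValidationError(f"invalid RDA target for {nutrient!r}: {rda}")
        amount = food.composition.get(nutrient, 0.0)
        values.append(min(amount / rda, 1.0))
    return CappedVector(nutrients=axis, values=tuple(values))


def cosine_score(vector: CappedVector) -> float:
    """Cosine similarity to the all-ones ideal; the zero vector scores 0."""
    v = vector.as_array()
    norm = np.linalg.norm(v)
    if norm == 0.0:
        return 0.0
    return float(v.sum() / (math.sqrt(v.size) * norm))


def summation_score(food: FoodNode, targets: TargetMap) -> float:
    """Uncapped sum of amount/RDA fractions (the ablation baseline)."""
    if not targets:
        raise ValidationError("target map is empty")
    total = 0.0
    for nutrient, target in targets.items():
        if not (target.amount > 0 and math.isfinite(target.amount)):
            raise ValidationError(f"invalid RDA target for {nutrient!r}")
        total += food.composition.get(nutrient, 0.0) / target.amount
    return total


def _score(food: FoodNode, vector: CappedVector, targets: TargetMap, mode: str) -> float:
    if mode == "cosine_capped":
        return cosine_score(vector)
    if mode == "summation_uncapped":
        return summation_score(food, targets)
    if mode == "cosine_magnitude":
        return cosine_score(vector) * float(vector.as_array().sum())
    raise ValidationError(f"unknown ranking mode {mode!r}")


def score_candidates(
    graph: KnowledgeGraph,
    disease_id: str,
    targets: TargetMap,
    config: Optional[RankingConfig] = None,
) -> List[ScoredFood]:
    """Score and sort every candidate food (no top-k truncation).

    Candidates are exactly the foods with at least one CONTAINS_NUTRIENT
    edge into the required set. Sorting is descending by score with ties
    broken ascending by food code, so the ordering is fully deterministic.
    """
    config = config or RankingConfig()
    n_req = required_nutrients(graph, disease_id)
    codes = candidate_foods(graph, n_req)
    if not codes:
        raise NoCandidatesError(
            f"no food contains any of {list(n_req)} for disease {disease_id!r}"
        )
    scored: List[ScoredFood] = []
    for code in sorted(codes):
        food = graph.foods[code]
        vector = build_food_vector(food, targets)
        trace = tuple(
            TraceEntry(
                disease=disease_id,
                nutrient=nutrient,
                rda=targets[nutrient].amount,
                unit=targets[nutrient].unit,
                amount=food.composition.get(nutrient, 0.0),
                pct_dv=100.0
                * food.composition.get(nutrient, 0.0)
                / targets[nutrient].amount,
            )
            for nutrient in vector.nutrients
        )
        scored.append(
            ScoredFood(
                code=code,
                name=food.name,
                score=_score(food, vector, targets, config.mode),
                vector=vector,
                trace=trace,
            )
        )
    # round the sort key so float-noise "ties" (e.g. two one-hot vectors at
    # 1/sqrt(n) computed from different amounts) break by code, not by ulp
    scored.sort(key=lambda s: (-round(s.score, 12), s.code))
    return scored


def rank_foods(
    graph: KnowledgeGraph,
    disease_id: str,
    profile: UserProfile,
    config: Optional[RankingConfig] = None,
) -> List[ScoredFood]:
    """Top-k ranking for a profile, with a full explanation trace per item."""
    config = config or RankingConfig()
    targets = resolve_targets(graph, disease_id, profile)
    return score_candidates(graph, disease_id, targets, config)[: config.top_k]


def aggregate_requirement_met(
    ranked: List[ScoredFood], nutrient_id: str, targets: TargetMap
) -> float:
    """Percent of the daily target met by the ranked list in aggregate.

    ``100 * (sum of the nutrient over the ranked foods) / RDA`` -- not
    capped, so values above 100 indicate a safety margin.
    """
    if not ranked:
        raise ValidationError("ranked list is empty")
    if nutrient_id not in targets:
        raise ValidationError(f"nutrient {nutrient_id!r} is not a target")
    total = sum(
        entry.amount
        for item in ranked
        for entry in item.trace
        if entry.nutrient == nutrient_id
    )
    return 100.0 * total / targets[nutrient_id].amount
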