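"""Ranking-quality and nutritional-balance metrics, plus experiment protocols.

Six metrics are implemented:

* Precision@k -- fraction of the top k that are nutritionally relevant,
  where a food is relevant iff it meets at least ``min_satisfied`` of the
  disease's nutrient requirements at >= ``tau_cov`` percent of the daily
  value (%DV);
* NDCG@k with binary gains (2^rel - 1) / log2(i + 1), normalized by the
  ideal ordering (0 when no item is relevant);
* Rank Stability Score -- Spearman rank correlation between two rankings
  of the same foods, 1 - 6 * sum(d_i^2) / (n (n^2 - 1)), with average
  ranks on ties;
* mean %DV deviation -- mean of |min(%DV, 100) - 100| over nutrients;
* nutrient coverage -- fraction of required nutrients at >= tau %DV;
* balance variance -- population variance of the capped [0, 1] components,
  low for proportionally balanced foods.

Two protocols exercise the ranking engine: an RDA perturbation experiment
(rank stability under +-10% target shifts) and a capping ablation
(balance variance of the top k under capped-cosine vs uncapped-summation
scoring).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .graph_store import KnowledgeGraph
from .profile_matching import Target, TargetMap, UserProfile, resolve_targets
from .ranking import (
    RankingConfig,
    ScoredFood,
    rank_foods,
    score_candidates,
)


@dataclass
class MetricConfig:
    k: int = 5
    tau_cov: float = 20.0  # %DV threshold for "counts toward the requirement"
    min_satisfied: int = 2  # requirements met for a food to be relevant

    def __post_init__(self):
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if not (0 < self.tau_cov <= 100):
            raise ValidationError("tau_cov must lie in (0, 100]")
        if self.min_satisfied < 1:
            raise ValidationError("min_satisfied must be >= 1")


@dataclass
class MetricsReport:
    precision_at_k: float
    ndcg_at_k: float
    rank_stability: float
    mean_dv_deviation: float
    coverage: float
    balance_variance: float
    provenance: Dict = field(default_factory=dict)

    def as_dict(self) -> Dict:
        return {
            "precision_at_k": self.precision_at_k,
            "ndcg_at_k": self.ndcg_at_k,
            "rank_stability": self.rank_stability,
            "mean_dv_deviation": self.mean_dv_deviation,
            "coverage": self.coverage,
            "balance_variance": self.balance_variance,
            "provenance": self.provenance,
        }


def label_relevance(
    food: ScoredFood, targets: TargetMap, config: Optional[MetricConfig] = None
) -> int:
    """1 iff the food meets >= min_satisfied requirements at >= tau_cov %DV."""
    config = config or MetricConfig()
    satisfied = sum(1 for entry in food.trace if entry.pct_dv >= config.tau_cov)
    return 1 if satisfied >= config.min_satisfied else 0


def precision_at_k(relevance_list: Sequence[int], k: int) -> float:
    if k < 1 or k > len(relevance_list):
        raise ValidationError(
            f"k={k} out of range for a list of {len(relevance_list)}"
        )
    return float(sum(relevance_list[:k])) / k


def ndcg_at_k(relevance_list: Sequence[int], k: int) -> float:
    """Binary-gain NDCG; 0 when the ideal DCG is 0 (no relevant item)."""
    if k < 1 or k > len(relevance_list):
        raise ValidationError(
            f"k={k} out of range for a list of {len(relevance_list)}"
        )
    if any(r not in (0, 1) for r in relevance_list):
        raise ValidationError("relevance labels must be binary")

    def dcg(labels: Sequence[int]) -> float:
        return sum(
            (2 ** rel - 1) / math.log2(i + 1)
            for i, rel in enumerate(labels[:k], start=1)
        )

    ideal = dcg(sorted(relevance_list, reverse=True))
    if ideal == 0.0:
        return 0.0
    return dcg(list(relevance_list)) / ideal


def _average_ranks(order: Sequence, scores: Optional[Dict] = None) -> Dict:
    """Rank positions 1..n; equal-score items share the average rank."""
    ranks = {item: i + 1.0 for i, item in enumerate(order)}
    if scores:
        by_score: Dict[float, List] = {}
        for item in order:
            by_score.setdefault(scores[item], []).append(item)
        for items in by_score.values():
            if len(items) > 1:
                mean_rank = sum(ranks[i] for i in items) / len(items)
                for i in items:
                    ranks[i] = mean_rank
    return ranks


def rank_stability(rank_a: Sequence, rank_b: Sequence) -> float:
    """Spearman rank correlation of two orderings of the same item set."""
    if set(rank_a) != set(rank_b):
        raise ValidationError("rankings must cover the same item set")
    n = len(rank_a)
    if n < 2 or len(set(rank_a)) != n:
        raise ValidationError("need >= 2 distinct items")
    ranks_a = _average_ranks(rank_a)
    ranks_b = _average_ranks(rank_b)
    d2 = sum((ranks_a[item] - ranks_b[item]) ** 2 for item in rank_a)
    return 1.0 - 6.0 * d2 / (n * (n ** 2 - 1))


def dv_deviation(pct_dv_list: Sequence[float]) -> float:
    """Mean absolute deviation from the 100 %DV target, surplus capped."""
    if not len(pct_dv_list):
        raise ValidationError("empty %DV list")
    if any(v < 0 for v in pct_dv_list):
        raise ValidationError("%DV values must be >= 0")
    return float(
        np.mean([abs(min(v, 100.0) - 100.0) for v in pct_dv_list])
    )


def coverage_score(pct_dv_list: Sequence[float], tau_cov: float = 20.0) -> float:
    """Fraction of required nutrients with %DV at or above the threshold."""
    if not len(pct_dv_list):
        raise ValidationError("empty %DV list")
    return float(sum(1 for v in pct_dv_list if v >= tau_cov)) / len(pct_dv_list)


def balance_variance(capped_values: Sequence[float]) -> float:
    """Population variance of capped [0, 1] nutrient contributions."""
    if not len(capped_values):
        raise ValidationError("empty value list")
    if any(not (0.0 <= v <= 1.0) for v in capped_values):
        raise ValidationError("capped values must lie in [0, 1]")
    arr = np.asarray(capped_values, dtype=float)
    return float(np.mean((arr - arr.mean()) ** 2))


def perturbation_experiment(
    graph: KnowledgeGraph,
    disease_id: str,
    profile: UserProfile,
    delta: float = 0.10,
    config: Optional[RankingConfig] = None,
) -> Dict[str, float]:
    """Rank stability under a uniform RDA shift of ``delta`` (e.g. +-0.10).

    Both runs rank the full candidate list; the Rank Stability Score is
    computed over the common candidates and the overlap is the fraction of
    the baseline top-k retained in the perturbed top-k.
    """
    if not (-1.0 < delta < 1.0):
        raise ValidationError("delta must lie in (-1, 1)")
    config = config or RankingConfig()
    targets = resolve_targets(graph, disease_id, profile)
    perturbed: TargetMap = {
        nutrient: Target(amount=t.amount * (1.0 + delta), unit=t.unit)
        for nutrient, t in targets.items()
    }
    base = score_candidates(graph, disease_id, targets, config)
    shifted = score_candidates(graph, disease_id, perturbed, config)
    common = {s.code for s in base} & {s.code for s in shifted}
    order_a = [s.code for s in base if s.code in common]
    order_b = [s.code for s in shifted if s.code in common]
    top_a = [s.code for s in base[: config.top_k]]
    top_b = {s.code for s in shifted[: config.top_k]}
    return {
        "rss": rank_stability(order_a, order_b),
        "top_k_overlap": sum(1 for c in top_a if c in top_b) / len(top_a),
    }


def ablation_experiment(
    graph: KnowledgeGraph,
    diseases: Sequence[str],
    profiles: Sequence[UserProfile],
    config: Optional[RankingConfig] = None,
) -> Dict[str, float]:
    """Mean top-k balance variance with and without RDA capping.

    For every (disease, profile) pair the top k is ranked once under
    capped-cosine scoring and once under uncapped summation; the reported
    number per mode is the mean balance variance of the capped vectors of
    the foods each mode ranked on top. Capping should drive the variance
    down (balanced foods surface); summation favours single-nutrient
    spikes and drives it up.
    """
    if not diseases or not profiles:
        raise ValidationError("need at least one disease/profile pair")
    config = config or RankingConfig()
    results: Dict[str, float] = {}
    for mode in ("cosine_capped", "summation_uncapped"):
        mode_config = RankingConfig(
            top_k=config.top_k, mode=mode, score_decimals=config.score_decimals
        )
        variances: List[float] = []
        for disease_id, profile in zip(diseases, profiles):
            ranked = rank_foods(graph, disease_id, profile, mode_config)
            variances.extend(
                balance_variance(item.vector.values) for item in ranked
            )
        results[mode] = float(np.mean(variances))
    return results


def evaluate_ranking(
    graph: KnowledgeGraph,
    disease_id: str,
    profile: UserProfile,
    metric_config: Optional[MetricConfig] = None,
    ranking_config: Optional[RankingConfig] = None,
    perturbation_delta: float = 0.10,
) -> MetricsReport:
    """Run one profile end to end and summarize all six metrics.

    Precision/NDCG use the relevance-labeling rule; %DV deviation,
    coverage and balance variance are averaged over the top-k foods;
    rank stability comes from the RDA perturbation protocol.
    """
    metric_config = metric_config or MetricConfig()
    ranking_config = ranking_config or RankingConfig()
    ranked = rank_foods(graph, disease_id, profile, ranking_config)
    targets = resolve_targets(graph, disease_id, profile)
    k = min(metric_config.k, len(ranked))
    labels = [label_relevance(f, targets, metric_config) for f in ranked]
    stability = perturbation_experiment(
        graph, disease_id, profile, perturbation_delta, ranking_config
    )
    report = MetricsReport(
        precision_at_k=precision_at_k(labels, k),
        ndcg_at_k=ndcg_at_k(labels, k),
        rank_stability=stability["rss"],
        mean_dv_deviation=float(
            np.mean(
                [dv_deviation([e.pct_dv for e in f.trace]) for f in ranked]
            )
        ),
        coverage=float(
            np.mean(
                [
                    coverage_score(
                        [e.pct_dv for e in f.trace], metric_config.tau_cov
                    )
                    for f in ranked
                ]
            )
        ),
        balance_variance=float(
            np.mean([balance_variance(f.vector.values) for f in ranked])
        ),
        provenance={
            "disease": disease_id,
            "profile": {
                "age": profile.age,
                "gender": profile.gender,
                "state": profile.state,
            },
            "k": k,
            "tau_cov": metric_config.tau_cov,
            "min_satisfied": metric_config.min_satisfied,
            "mode": ranking_config.mode,
            "top_k": ranking_config.top_k,
            "perturbation_delta": perturbation_delta,
            "n_ranked": len(ranked),
        },
    )
    return report
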