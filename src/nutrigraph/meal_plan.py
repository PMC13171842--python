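"""Deterministic Thali meal-plan formatting and the hallucination guard.

A generative model, when used at all, is restricted to formatting the
ranked graph output. This module provides the deterministic reference
formatter (round-robin assignment of ranked foods to meal slots, with
rationales templated strictly from the explanation trace) and the
mechanical whitelist validator: every food in a plan must come from the
ranked list and every number cited in a rationale must come from that
food's trace. Any plug-in text generator must pass :func:`validate_plan`
before its output is shown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .errors import ValidationError
from .ranking import ScoredFood

DEFAULT_SLOTS = ("breakfast", "lunch", "snack", "dinner")


@dataclass(frozen=True)
class Fact:
    """One (nutrient, amount, %DV) citation taken from a trace entry."""

    nutrient: str
    amount: float
    unit: str
    pct_dv: float


@dataclass
class MealEntry:
    code: str
    name: str
    rationale: str
    facts: Tuple[Fact, ...]


@dataclass
class MealPlan:
    slots: Dict[str, List[MealEntry]]

    def foods(self) -> List[str]:
        return [entry.code for entries in self.slots.values() for entry in entries]


def _rationale(item: ScoredFood, facts: Sequence[Fact]) -> str:
    parts = [
        f"{fact.amount:g} {fact.unit} {fact.nutrient} per 100 g "
        f"({fact.pct_dv:.1f}% of the daily target)"
        for fact in facts
    ]
    return f"{item.name} provides " + "; ".join(parts) + "."


def format_meal_plan(
    ranked: Sequence[ScoredFood], slots: Sequence[str] = DEFAULT_SLOTS
) -> MealPlan:
    """Round-robin the ranked foods into meal slots, preserving rank order.

    Food at rank i goes to slot ``i mod len(slots)``, so the top-10 over
    four slots yields sizes 3/3/2/2. Rationales cite only trace values.
    """
    if not ranked:
        raise ValidationError("ranked list is empty")
    if not slots:
        raise ValidationError("need at least one meal slot")
    plan = MealPlan(slots={slot: [] for slot in slots})
    for i, item in enumerate(ranked):
        facts = tuple(
            Fact(
                nutrient=entry.nutrient,
                amount=entry.amount,
                unit=entry.unit,
                pct_dv=entry.pct_dv,
            )
            for entry in item.trace
            if entry.amount > 0
        )
        if not facts:  # a ranked candidate always contains >= 1 target nutrient
            raise ValidationError(f"food {item.code} has an empty trace")
        plan.slots[slots[i % len(slots)]].append(
            MealEntry(
                code=item.code,
                name=item.name,
                rationale=_rationale(item, facts),
                facts=facts,
            )
        )
    return plan


def validate_plan(
    plan: MealPlan, ranked: Sequence[ScoredFood]
) -> Tuple[bool, List[str]]:
    """Whitelist check: pass iff every plan food and cited number is traced.

    Returns ``(ok, violations)``. A violation is recorded when a plan food
    is not in the ranked list, or when a rationale cites a
    (nutrient, amount, %DV) triple that does not appear verbatim in that
    food's trace.
    """
    by_code = {item.code: item for item in ranked}
    violations: List[str] = []
    for slot, entries in plan.slots.items():
        for entry in entries:
            item = by_code.get(entry.code)
            if item is None:
                violations.append(
                    f"{slot}: food {entry.code!r} is not in the ranked list"
                )
                continue
            traced = {
                (t.nutrient, t.amount, t.pct_dv) for t in item.trace
            }
            for fact in entry.facts:
                if (fact.nutrient, fact.amount, fact.pct_dv) not in traced:
                    violations.append(
                        f"{slot}: {entry.code} cites untraced value "
                        f"({fact.nutrient}, {fact.amount}, {fact.pct_dv})"
                    )
    return (not violations, violations)
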