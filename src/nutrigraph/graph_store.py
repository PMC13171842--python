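"""In-memory property graph for the disease-nutrient-food schema.

The graph mirrors a Neo4j-style schema with three node labels and three
relationship types::

    (:Disease)-[:REQUIRES]->(:Nutrient)
    (:Food)-[:CONTAINS_NUTRIENT]->(:Nutrient)
    (:Symptom)-[:INDICATES]->(:Disease)

Nutrient nodes carry demographic-specific RDA (Recommended Dietary
Allowance) values keyed by gender, an inclusive age band and an optional
physiological state. The backend is a set of insertion-ordered dicts --
no database server is involved; ``export_cypher`` produces statements for
an optional Neo4j deployment.
"""

from __future__ import annotations

import difflib
import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .errors import LinkageError, NotFoundError, ResolutionError, SchemaError

GENDERS = ("male", "female")
STATES = ("none", "pregnant", "lactating")
UNITS = ("g", "mg", "mcg")

#: metadata columns of the food composition table; every other column is a
#: nutrient amount per 100 g edible portion
FOOD_META_COLUMNS = ("code", "name", "category")


@dataclass(frozen=True)
class DemographicKey:
    """One row of the RDA table: gender x inclusive age band x state."""

    gender: str
    age_lo: int
    age_hi: int
    state: str = "none"

    def __post_init__(self):
        if self.gender not in GENDERS:
            raise SchemaError(f"unknown gender {self.gender!r}")
        if self.state not in STATES:
            raise SchemaError(f"unknown physiological state {self.state!r}")
        if not (0 <= self.age_lo <= self.age_hi <= 120):
            raise SchemaError(
                f"invalid age band [{self.age_lo}, {self.age_hi}]"
            )

    def covers(self, gender: str, age: int) -> bool:
        return gender == self.gender and self.age_lo <= age <= self.age_hi

    def label(self) -> str:
        tail = "" if self.state == "none" else f"_{self.state}"
        return f"rda_{self.gender}_{self.age_lo}_{self.age_hi}{tail}"


@dataclass
class NutrientNode:
    id: str
    unit: str
    synonyms: Tuple[str, ...] = ()
    rda_table: Dict[DemographicKey, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.id:
            raise SchemaError("nutrient id must be non-empty")
        if self.unit not in UNITS:
            raise SchemaError(f"nutrient {self.id}: unknown unit {self.unit!r}")
        for key, amount in self.rda_table.items():
            if not (amount > 0 and math.isfinite(amount)):
                raise SchemaError(
                    f"nutrient {self.id}: RDA for {key.label()} must be > 0"
                )
        self._check_band_overlap()

    def _check_band_overlap(self):
        by_group: Dict[Tuple[str, str], List[DemographicKey]] = {}
        for key in self.rda_table:
            by_group.setdefault((key.gender, key.state), []).append(key)
        for (gender, state), keys in by_group.items():
            keys = sorted(keys, key=lambda k: k.age_lo)
            for prev, cur in zip(keys, keys[1:]):
                if cur.age_lo <= prev.age_hi:
                    raise SchemaError(
                        f"nutrient {self.id}: overlapping age bands for "
                        f"({gender}, {state}): [{prev.age_lo},{prev.age_hi}] "
                        f"and [{cur.age_lo},{cur.age_hi}]"
                    )


@dataclass
class FoodNode:
    code: str
    name: str
    category: str
    composition: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for nutrient, amount in self.composition.items():
            if not (amount >= 0 and math.isfinite(amount)):
                raise SchemaError(
                    f"food {self.code}: amount of {nutrient} must be finite "
                    f"and >= 0, got {amount!r}"
                )


@dataclass
class DiseaseNode:
    name: str
    required_nutrients: Tuple[str, ...]
    clinical_notes: str = ""
    symptom_aliases: Tuple[str, ...] = ()

    def __post_init__(self):
        if not self.required_nutrients:
            raise SchemaError(f"disease {self.name}: no required nutrients")


@dataclass
class KnowledgeGraph:
    """Typed node collections plus explicit edge lists (insertion order)."""

    nutrients: Dict[str, NutrientNode] = field(default_factory=dict)
    foods: Dict[str, FoodNode] = field(default_factory=dict)
    diseases: Dict[str, DiseaseNode] = field(default_factory=dict)
    requires_edges: List[Tuple[str, str]] = field(default_factory=list)
    contains_edges: List[Tuple[str, str]] = field(default_factory=list)
    indicates_edges: List[Tuple[str, str]] = field(default_factory=list)

    def stats(self) -> Dict[str, int]:
        return {
            "diseases": len(self.diseases),
            "foods": len(self.foods),
            "nutrients": len(self.nutrients),
            "nodes_total": len(self.diseases) + len(self.foods) + len(self.nutrients),
            "edges_total": len(self.requires_edges)
            + len(self.contains_edges)
            + len(self.indicates_edges),
        }

    def validate(self) -> None:
        """Full referential-integrity scan; raises LinkageError on a dangle."""
        for disease, nutrient in self.requires_edges:
            if disease not in self.diseases or nutrient not in self.nutrients:
                raise LinkageError(f"dangling REQUIRES edge ({disease}, {nutrient})")
        for food, nutrient in self.contains_edges:
            if food not in self.foods or nutrient not in self.nutrients:
                raise LinkageError(
                    f"dangling CONTAINS_NUTRIENT edge ({food}, {nutrient})"
                )
        for _, disease in self.indicates_edges:
            if disease not in self.diseases:
                raise LinkageError(f"dangling INDICATES edge into {disease!r}")
        for food in self.foods.values():
            for nutrient in food.composition:
                if nutrient not in self.nutrients:
                    raise LinkageError(
                        f"food {food.code} lists unknown nutrient {nutrient!r}"
                    )

    def serialize(self) -> str:
        """Deterministic JSON serialization (used for determinism checks)."""
        payload = {
            "nutrients": {
                n.id: {
                    "unit": n.unit,
                    "synonyms": list(n.synonyms),
                    "rda": {k.label(): v for k, v in n.rda_table.items()},
                }
                for n in self.nutrients.values()
            },
            "foods": {
                f.code: {
                    "name": f.name,
                    "category": f.category,
                    "composition": f.composition,
                }
                for f in self.foods.values()
            },
            "diseases": {
                d.name: {
                    "required": list(d.required_nutrients),
                    "notes": d.clinical_notes,
                    "aliases": list(d.symptom_aliases),
                }
                for d in self.diseases.values()
            },
            "edges": {
                "REQUIRES": self.requires_edges,
                "CONTAINS_NUTRIENT": self.contains_edges,
                "INDICATES": self.indicates_edges,
            },
        }
        return json.dumps(payload, sort_keys=True)


def _split_list(value) -> Tuple[str, ...]:
    if isinstance(value, str):
        return tuple(s.strip() for s in value.split(";") if s.strip())
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ()
    return tuple(str(v).strip() for v in value if str(v).strip())


def build_graph(
    disease_table: pd.DataFrame,
    food_table: pd.DataFrame,
    rda_table: pd.DataFrame,
    abbrev_map: pd.DataFrame,
) -> KnowledgeGraph:
    """Assemble the knowledge graph from canonical (post-ETL) tables.

    Expected columns
    ----------------
    disease_table : disease, nutrients (";"-joined), clinical_notes,
        symptom_aliases (";"-joined)
    food_table : code, name, category, then one column per nutrient
        (canonical scientific names), amounts per 100 g; NaN = absent
    rda_table : nutrient, gender, age_lo, age_hi, state, amount
        (amounts already in the nutrient's canonical unit)
    abbrev_map : code, scientific_name, unit, tags -- defines the nutrient
        universe, one node per distinct scientific name

    Raises :class:`SchemaError` for duplicate codes/names and
    :class:`LinkageError` when a disease or RDA row references a nutrient
    outside the universe.
    """
    graph = KnowledgeGraph()

    # Nutrient universe comes from the semantic map, in row order.
    synonyms: Dict[str, List[str]] = {}
    units: Dict[str, str] = {}
    for row in abbrev_map.itertuples(index=False):
        name = str(row.scientific_name).strip()
        if not name:
            raise SchemaError("abbreviation map: empty scientific_name")
        units.setdefault(name, str(row.unit).strip())
        tags = _split_list(getattr(row, "tags", ""))
        synonyms.setdefault(name, []).extend(
            t for t in (str(row.code).strip(),) + tags if t
        )

    rda_by_nutrient: Dict[str, Dict[DemographicKey, float]] = {}
    for row in rda_table.itertuples(index=False):
        nutrient = str(row.nutrient).strip()
        if nutrient not in units:
            raise LinkageError(
                f"RDA table references unknown nutrient {nutrient!r}"
            )
        key = DemographicKey(
            gender=str(row.gender).strip(),
            age_lo=int(row.age_lo),
            age_hi=int(row.age_hi),
            state=str(getattr(row, "state", "none")).strip() or "none",
        )
        rda_by_nutrient.setdefault(nutrient, {})[key] = float(row.amount)

    for name in units:
        graph.nutrients[name] = NutrientNode(
            id=name,
            unit=units[name],
            synonyms=tuple(dict.fromkeys(synonyms.get(name, ()))),
            rda_table=rda_by_nutrient.get(name, {}),
        )

    # Foods + CONTAINS_NUTRIENT edges, one per non-missing composition cell.
    nutrient_columns = [
        c for c in food_table.columns if c not in FOOD_META_COLUMNS
    ]
    for col in nutrient_columns:
        if col not in graph.nutrients:
            raise LinkageError(
                f"food table column {col!r} is not a known nutrient"
            )
    for row in food_table.to_dict("records"):
        code = str(row["code"]).strip()
        if code in graph.foods:
            raise SchemaError(f"duplicate food code {code!r}")
        composition = {}
        for col in nutrient_columns:
            value = row[col]
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue
            composition[col] = float(value)
        graph.foods[code] = FoodNode(
            code=code,
            name=str(row["name"]).strip(),
            category=str(row["category"]).strip(),
            composition=composition,
        )
        for nutrient in composition:
            graph.contains_edges.append((code, nutrient))

    # Diseases + REQUIRES and INDICATES edges.
    for row in disease_table.itertuples(index=False):
        name = str(row.disease).strip()
        if name in graph.diseases:
            raise SchemaError(f"duplicate disease name {name!r}")
        required = _split_list(row.nutrients)
        for nutrient in required:
            if nutrient not in graph.nutrients:
                raise LinkageError(
                    f"disease {name!r} requires unknown nutrient {nutrient!r}"
                )
        aliases = _split_list(getattr(row, "symptom_aliases", ""))
        notes = getattr(row, "clinical_notes", "")
        graph.diseases[name] = DiseaseNode(
            name=name,
            required_nutrients=required,
            clinical_notes="" if pd.isna(notes) else str(notes),
            symptom_aliases=aliases,
        )
        for nutrient in required:
            graph.requires_edges.append((name, nutrient))
        for alias in aliases:
            graph.indicates_edges.append((alias, name))

    graph.validate()
    return graph


def required_nutrients(graph: KnowledgeGraph, disease_id: str) -> Tuple[str, ...]:
    """Targets of the disease's REQUIRES edges, in insertion order."""
    disease = graph.diseases.get(disease_id)
    if disease is None:
        nearest = difflib.get_close_matches(
            disease_id, list(graph.diseases), n=3, cutoff=0.0
        )
        raise NotFoundError(
            f"unknown disease {disease_id!r}; nearest: {', '.join(nearest)}"
        )
    return disease.required_nutrients


def candidate_foods(graph: KnowledgeGraph, nutrient_ids: Iterable[str]) -> set:
    """Codes of foods with at least one CONTAINS_NUTRIENT edge into the set."""
    wanted = set(nutrient_ids)
    for nutrient in wanted:
        if nutrient not in graph.nutrients:
            raise NotFoundError(f"unknown nutrient {nutrient!r}")
    return {
        food.code
        for food in graph.foods.values()
        if wanted & food.composition.keys()
    }


def rda_lookup(graph: KnowledgeGraph, nutrient_id: str, profile) -> float:
    """Resolve the daily allowance for ``profile`` (age/gender/state).

    Physiological-state keys (pregnant/lactating), when present for the
    nutrient, take precedence over plain age/gender bands.
    """
    nutrient = graph.nutrients.get(nutrient_id)
    if nutrient is None:
        raise NotFoundError(f"unknown nutrient {nutrient_id!r}")
    state = getattr(profile, "state", "none") or "none"
    if state != "none":
        hits = [
            (key, amount)
            for key, amount in nutrient.rda_table.items()
            if key.state == state and key.covers(profile.gender, profile.age)
        ]
        if hits:
            return hits[0][1]
    hits = [
        (key, amount)
        for key, amount in nutrient.rda_table.items()
        if key.state == "none" and key.covers(profile.gender, profile.age)
    ]
    if hits:
        return hits[0][1]
    available = ", ".join(k.label() for k in nutrient.rda_table) or "none"
    raise ResolutionError(
        f"no RDA band for {nutrient_id!r} covers ({profile.gender}, "
        f"age {profile.age}, state {state}); available: {available}"
    )


def _q(text: str) -> str:
    return "'" + str(text).replace("\\", "\\\\").replace("'", "\\'") + "'"


def export_cypher(graph: KnowledgeGraph) -> str:
    """Emit one CREATE/MERGE statement per node and per edge.

    The statement count therefore equals ``nodes_total + edges_total`` of
    :meth:`KnowledgeGraph.stats`; symptom nodes are merged inline within
    their INDICATES statements and are not counted as graph nodes.
    """
    lines: List[str] = []
    for n in graph.nutrients.values():
        props = [f"id: {_q(n.id)}", f"unit: {_q(n.unit)}"]
        props += [f"{k.label()}: {v}" for k, v in n.rda_table.items()]
        lines.append(f"CREATE (:Nutrient {{{', '.join(props)}}});")
    for f in graph.foods.values():
        lines.append(
            f"CREATE (:Food {{code: {_q(f.code)}, name: {_q(f.name)}, "
            f"category: {_q(f.category)}}});"
        )
    for d in graph.diseases.values():
        lines.append(
            f"CREATE (:Disease {{name: {_q(d.name)}, "
            f"clinical_notes: {_q(d.clinical_notes)}}});"
        )
    for disease, nutrient in graph.requires_edges:
        lines.append(
            f"MATCH (d:Disease {{name: {_q(disease)}}}), "
            f"(n:Nutrient {{id: {_q(nutrient)}}}) "
            f"CREATE (d)-[:REQUIRES]->(n);"
        )
    for food, nutrient in graph.contains_edges:
        amount = graph.foods[food].composition[nutrient]
        lines.append(
            f"MATCH (f:Food {{code: {_q(food)}}}), "
            f"(n:Nutrient {{id: {_q(nutrient)}}}) "
            f"CREATE (f)-[:CONTAINS_NUTRIENT {{amount_per_100g: {amount}}}]->(n);"
        )
    for alias, disease in graph.indicates_edges:
        lines.append(
            f"MATCH (d:Disease {{name: {_q(disease)}}}) "
            f"MERGE (s:Symptom {{name: {_q(alias)}}}) "
            f"MERGE (s)-[:INDICATES]->(d);"
        )
    return "\n".join(lines)
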