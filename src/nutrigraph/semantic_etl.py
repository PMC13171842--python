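"""Semantic ETL: normalize units, resolve vocabulary, impute, build the graph.

The pipeline turns four raw CSV-shaped tables (disease-nutrient mapping,
food composition per 100 g, demographic RDA table, nutrient abbreviation
map) into a validated :class:`~nutrigraph.graph_store.KnowledgeGraph`:

1. food-table nutrient columns are mapped from technical codes (e.g.
   ``protcnt``) to canonical scientific names, first by exact dictionary
   hit, then by embedding cosine similarity above a threshold tau;
2. disease and RDA nutrient references are resolved the same way;
3. RDA amounts are rescaled to each nutrient's canonical unit;
4. missing composition cells are filled by k-NN imputation within food
   categories;
5. the graph is assembled and validated.

Every fuzzy resolution decision is logged (term, candidate, similarity,
accepted) so the ingest is auditable; the whole pipeline is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import (
    ImputationError,
    LinkageError,
    UnitError,
    ValidationError,
)
from .graph_store import FOOD_META_COLUMNS, KnowledgeGraph, build_graph

# conversion factors expressed in micrograms
_UNIT_IN_MCG = {"g": 1_000_000.0, "mg": 1_000.0, "mcg": 1.0}


def normalize_unit(amount: float, from_unit: str, to_unit: str) -> float:
    """Exact power-of-1000 rescaling among g / mg / mcg."""
    if from_unit not in _UNIT_IN_MCG:
        raise UnitError(f"unknown unit {from_unit!r}")
    if to_unit not in _UNIT_IN_MCG:
        raise UnitError(f"unknown unit {to_unit!r}")
    if not (math.isfinite(amount) and amount >= 0):
        raise ValidationError(f"amount must be finite and >= 0, got {amount!r}")
    return amount * (_UNIT_IN_MCG[from_unit] / _UNIT_IN_MCG[to_unit])


def map_code(code: str, abbrev_map: Dict[str, str]) -> Optional[str]:
    """Exact dictionary lookup of a technical code; None when unresolved."""
    return abbrev_map.get(code)


def resolve_term(
    term: str,
    vocabulary: Sequence[str],
    embedder=None,
    tau_sim: float = 0.5,
) -> Optional[Tuple[str, float]]:
    """Best cosine match of ``term`` in ``vocabulary`` if it clears ``tau_sim``.

    Returns ``(canonical_name, similarity)`` for the argmax entry when the
    similarity is strictly above the threshold, else ``None``. Ties are
    broken by lexicographic canonical name.
    """
    if not term or not term.strip():
        raise ValidationError("cannot resolve an empty term")
    if embedder is None:
        from .profile_matching import LexicalEmbedder

        embedder = LexicalEmbedder()
    query = embedder.embed(term)
    best: Optional[Tuple[str, float]] = None
    for entry in sorted(vocabulary):
        sim = float(np.dot(query, embedder.embed(entry)))
        if best is None or sim > best[1]:
            best = (entry, sim)
    if best is not None and best[1] > tau_sim:
        return best
    return None


def impute_missing(
    food_table: pd.DataFrame,
    k: int = 5,
    units: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Fill missing composition cells by category-restricted k-NN means.

    For a missing (food, nutrient) cell the donors are the ``k`` nearest
    same-category foods that observe the nutrient, by Euclidean distance
    over the nutrients observed in both foods (after rescaling each column
    to mg so magnitudes are comparable). Fewer than ``k`` donors: use all;
    no same-category donor: global mean of the nutrient. Observed cells are
    never altered.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    units = units or {}
    out = food_table.copy()
    if out.empty:
        return out
    nutrient_cols = [c for c in out.columns if c not in FOOD_META_COLUMNS]
    for col in nutrient_cols:
        out[col] = pd.to_numeric(out[col], errors="coerce")

    # distance space: every nutrient column rescaled to mg
    scaled = out[nutrient_cols].copy()
    for col in nutrient_cols:
        factor = _UNIT_IN_MCG.get(units.get(col, "mg"), 1_000.0) / 1_000.0
        scaled[col] = scaled[col] * factor

    for col in nutrient_cols:
        if out[col].isna().all():
            raise ImputationError(
                f"nutrient {col!r} is missing for every food; cannot impute"
            )

    values = scaled.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    categories = out["category"].astype(str).to_numpy()
    col_index = {c: j for j, c in enumerate(nutrient_cols)}

    for col in nutrient_cols:
        j = col_index[col]
        global_mean = float(out[col].mean())
        for i in np.flatnonzero(out[col].isna().to_numpy()):
            donors = [
                d
                for d in range(len(out))
                if d != i and categories[d] == categories[i] and observed[d, j]
            ]
            if not donors:
                out.iat[i, out.columns.get_loc(col)] = global_mean
                continue
            dists = []
            for d in donors:
                shared = observed[i] & observed[d]
                shared[j] = False
                if shared.any():
                    diff = values[i, shared] - values[d, shared]
                    dist = float(np.sqrt(np.sum(diff * diff)))
                else:
                    dist = math.inf  # no common evidence; used only as fallback
                dists.append((dist, d))
            dists.sort(key=lambda t: (t[0], t[1]))
            chosen = [d for _, d in dists[:k]]
            out.iat[i, out.columns.get_loc(col)] = float(
                out[col].iloc[chosen].mean()
            )
    return out


@dataclass
class ETLConfig:
    tau_sim: float = 0.5
    imputation_k: int = 5
    #: disable for sparse tables where a blank cell means "nutrient absent"
    #: (no CONTAINS_NUTRIENT edge) rather than "measurement missing"
    impute: bool = True
    embedder: object = None  # defaults to the lexical embedder


@dataclass
class RawTables:
    """The four raw inputs, as parsed CSV DataFrames."""

    disease: pd.DataFrame
    food: pd.DataFrame
    rda: pd.DataFrame
    abbrev: pd.DataFrame


@dataclass
class ETLResult:
    graph: KnowledgeGraph
    log: List[Dict] = field(default_factory=list)

    def log_jsonl(self) -> str:
        import json

        return "\n".join(json.dumps(entry, sort_keys=True) for entry in self.log)


def _resolve_name(
    term: str,
    code_map: Dict[str, str],
    vocabulary: Sequence[str],
    config: ETLConfig,
    log: List[Dict],
    stage: str,
) -> Optional[str]:
    term = term.strip()
    if term in vocabulary:
        return term
    hit = map_code(term, code_map)
    if hit is not None:
        return hit
    resolved = resolve_term(term, vocabulary, config.embedder, config.tau_sim)
    log.append(
        {
            "stage": stage,
            "term": term,
            "candidate": resolved[0] if resolved else None,
            "similarity": round(resolved[1], 6) if resolved else None,
            "accepted": resolved is not None,
        }
    )
    return resolved[0] if resolved else None


def run_etl(raw_tables: RawTables, config: Optional[ETLConfig] = None) -> ETLResult:
    """Full pipeline: resolve vocabulary, normalize units, impute, build."""
    config = config or ETLConfig()
    log: List[Dict] = []

    abbrev = raw_tables.abbrev.copy()
    code_map = {
        str(r.code).strip(): str(r.scientific_name).strip()
        for r in abbrev.itertuples(index=False)
    }
    units = {
        str(r.scientific_name).strip(): str(r.unit).strip()
        for r in abbrev.itertuples(index=False)
    }
    vocabulary = list(dict.fromkeys(code_map.values()))

    # 1. food table: resolve column headers, drop the irrecoverable ones
    food = raw_tables.food.copy()
    renames, drops = {}, []
    for col in food.columns:
        if col in FOOD_META_COLUMNS:
            continue
        name = _resolve_name(col, code_map, vocabulary, config, log, "food_column")
        if name is None:
            drops.append(col)
        elif name != col:
            renames[col] = name
    food = food.drop(columns=drops).rename(columns=renames)

    # 2. disease nutrient references must resolve
    disease = raw_tables.disease.copy()
    resolved_lists = []
    for row in disease.itertuples(index=False):
        names = []
        for term in str(row.nutrients).split(";"):
            term = term.strip()
            if not term:
                continue
            name = _resolve_name(
                term, code_map, vocabulary, config, log, "disease_nutrient"
            )
            if name is None:
                raise LinkageError(
                    f"disease {row.disease!r}: cannot resolve nutrient {term!r}"
                )
            names.append(name)
        resolved_lists.append(";".join(dict.fromkeys(names)))
    disease["nutrients"] = resolved_lists

    # 3. RDA table: resolve nutrient names and convert amounts to the
    #    nutrient's canonical unit
    rda = raw_tables.rda.copy()
    names, amounts = [], []
    for row in rda.itertuples(index=False):
        name = _resolve_name(
            str(row.nutrient), code_map, vocabulary, config, log, "rda_nutrient"
        )
        if name is None:
            raise LinkageError(f"RDA row: cannot resolve nutrient {row.nutrient!r}")
        row_unit = str(getattr(row, "unit", "") or units[name]).strip()
        names.append(name)
        amounts.append(normalize_unit(float(row.amount), row_unit, units[name]))
    rda["nutrient"] = names
    rda["amount"] = amounts
    if "unit" in rda.columns:
        rda = rda.drop(columns=["unit"])

    # 4. impute missing composition cells
    if config.impute:
        food = impute_missing(food, k=config.imputation_k, units=units)

    graph = build_graph(disease, food, rda, abbrev)
    return ETLResult(graph=graph, log=log)
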