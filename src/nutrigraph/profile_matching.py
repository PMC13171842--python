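"""User profiles, deterministic text embedding, and disease matching.

Free-text queries ("my hemoglobin is low") are projected onto the graph's
disease space by maximizing cosine similarity between embeddings of the
query and of disease labels plus their symptom aliases. The default
embedder is a fully deterministic lexical model: character 3-grams hashed
into a fixed-dimension vector and L2-normalized. It fulfils the same
contract as a sentence-transformer (text -> unit vector) without any model
download; transformer embedders can be plugged in behind the same
interface.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Dict, NamedTuple, Optional, Tuple

import numpy as np

from .errors import NoMatchError, ValidationError
from .graph_store import (
    GENDERS,
    STATES,
    KnowledgeGraph,
    rda_lookup,
    required_nutrients,
)

DEFAULT_DIMENSION = 384  # matches the MiniLM-class sentence encoders
_HASH_SEED = 17


@dataclass
class UserProfile:
    """Demographics plus the free-text query the user typed."""

    age: int
    gender: str
    state: str = "none"
    query_text: str = ""

    def __post_init__(self):
        if not (0 < self.age <= 120):
            raise ValidationError(f"age out of range: {self.age}")
        if self.gender not in GENDERS:
            raise ValidationError(f"unknown gender {self.gender!r}")
        if self.state not in STATES:
            raise ValidationError(f"unknown physiological state {self.state!r}")


class LexicalEmbedder:
    """Hashed character-3-gram embedder: deterministic, dependency-free.

    Text is lowercased, punctuation-stripped and whitespace-collapsed; the
    padded character 3-grams are hashed (keyed blake2b, fixed seed) into
    ``dimension`` bins and the count vector is L2-normalized. Empty text
    maps to the zero vector.
    """

    def __init__(self, dimension: int = DEFAULT_DIMENSION, seed: int = _HASH_SEED):
        if dimension < 1:
            raise ValidationError("dimension must be >= 1")
        self.dimension = dimension
        self.seed = seed
        self._cache: Dict[str, np.ndarray] = {}

    @staticmethod
    def _normalize(text: str) -> str:
        text = re.sub(r"[^\w\s]", " ", text.lower())
        return re.sub(r"\s+", " ", text).strip()

    def _bin(self, gram: str) -> int:
        digest = hashlib.blake2b(
            f"{self.seed}|{gram}".encode(), digest_size=8
        ).digest()
        return int.from_bytes(digest, "big") % self.dimension

    def embed(self, text: str) -> np.ndarray:
        cached = self._cache.get(text)
        if cached is not None:
            return cached
        norm = self._normalize(text)
        vec = np.zeros(self.dimension)
        if norm:
            padded = f" {norm} "
            grams = (
                [padded[i : i + 3] for i in range(len(padded) - 2)]
                if len(padded) >= 3
                else [padded]
            )
            for gram in grams:
                vec[self._bin(gram)] += 1.0
            vec /= np.linalg.norm(vec)
        self._cache[text] = vec
        return vec

    __call__ = embed


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


class MatchResult(NamedTuple):
    disease_id: str
    similarity: float


class Target(NamedTuple):
    amount: float
    unit: str


#: per-nutrient resolved daily targets for one profile
TargetMap = Dict[str, Target]


def match_disease(
    query_text: str,
    graph: KnowledgeGraph,
    embedder: Optional[LexicalEmbedder] = None,
    tau_sim: float = 0.5,
) -> MatchResult:
    """Argmax-cosine disease for a free-text query.

    Disease labels and symptom aliases are both embedded; an alias hit maps
    to its disease. Returned only when similarity is strictly above
    ``tau_sim``; ties break to the lexicographically smaller disease name.
    """
    if not query_text or not query_text.strip():
        raise ValidationError("query text must be non-empty")
    if not graph.diseases:
        raise ValidationError("graph has no diseases")
    embedder = embedder or LexicalEmbedder()
    query = embedder.embed(query_text)

    best: Dict[str, float] = {}
    for disease in graph.diseases.values():
        labels = (disease.name,) + disease.symptom_aliases
        sim = max(float(np.dot(query, embedder.embed(t))) for t in labels)
        best[disease.name] = sim
    ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
    name, sim = ranked[0]
    if sim <= tau_sim:
        raise NoMatchError(
            f"no disease matches {query_text!r} above tau={tau_sim}",
            nearest=ranked[:3],
        )
    return MatchResult(disease_id=name, similarity=sim)


def resolve_targets(
    graph: KnowledgeGraph, disease_id: str, profile: UserProfile
) -> TargetMap:
    """One RDA lookup per required nutrient of the disease."""
    targets: TargetMap = {}
    for nutrient in required_nutrients(graph, disease_id):
        amount = rda_lookup(graph, nutrient, profile)
        targets[nutrient] = Target(amount=amount, unit=graph.nutrients[nutrient].unit)
    return targets
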