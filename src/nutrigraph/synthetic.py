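"""Synthetic fixtures: IFCT-shaped tables with planted ranking structure.

The generator emits the four raw tables the ETL expects (disease-nutrient
mapping, food composition per 100 g, demographic RDA bands, nutrient
abbreviation map) with controlled statistical structure:

* regular food amounts are log-normal per nutrient with category-level
  shifts, keeping compositions positive and heavy-tailed;
* ``superfood_count`` foods spike one required nutrient at 3-10x its adult
  reference RDA and carry zero of the other required nutrients -- the
  classic single-nutrient "superfood" that uncapped summation scoring
  over-ranks;
* ``balanced_count`` foods provide 40-80% of the reference RDA for every
  required nutrient of the first disease, the profile capped-cosine
  ranking should put on top;
* missing cells are injected at rate (1 - density) to exercise k-NN
  imputation.

Everything is driven by one numpy Generator seed, so identical configs
produce byte-identical tables.

``anemia_walkthrough`` is a small hand-curated fixture (pregnancy +
iron-deficiency anemia) whose amounts follow published food-composition
values; its folate amounts are synthetic reconstructions chosen to give
round capped-vector components and are flagged as such below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .graph_store import KnowledgeGraph, build_graph
from .profile_matching import UserProfile
from .semantic_etl import RawTables

# name, technical code, unit, reference RDA (adult female 19-30), tags
_CATALOGUE: List[Tuple[str, str, str, float, str]] = [
    ("Iron", "fe", "mg", 29.0, "mineral haemoglobin blood"),
    ("Vitamin C", "vitc", "mg", 65.0, "ascorbic acid antioxidant"),
    ("Protein", "protcnt", "g", 46.0, "total essential proximate macronutrient"),
    ("Dietary fiber", "fibtg", "g", 25.0, "total fiber roughage bulk indigestible"),
    ("Folic Acid", "folsum", "mcg", 220.0, "folate vitamin b9"),
    ("Zinc", "zn", "mg", 13.0, "mineral trace immune"),
    ("Calcium", "ca", "mg", 1000.0, "mineral bone"),
    ("Vitamin D", "vitd", "mcg", 15.0, "calciferol sunshine vitamin"),
    ("Potassium (K)", "k", "mg", 3500.0, "electrolyte mineral"),
    ("Magnesium", "mg", "mg", 370.0, "mineral electrolyte"),
    ("Vitamin A", "vita", "mcg", 840.0, "retinol carotene vision"),
    ("Vitamin B12", "vitb12", "mcg", 2.2, "cobalamin vitamin"),
    ("Sodium", "na", "mg", 2000.0, "electrolyte salt"),
    ("Selenium", "se", "mcg", 40.0, "mineral trace antioxidant"),
    ("Copper", "cu", "mg", 1.7, "mineral trace"),
    ("Thiamine", "thia", "mg", 1.4, "vitamin b1"),
    ("Riboflavin", "ribf", "mg", 2.0, "vitamin b2"),
    ("Niacin", "nia", "mg", 12.0, "vitamin b3"),
    ("Vitamin B6", "vitb6", "mg", 1.9, "pyridoxine vitamin"),
    ("Vitamin E", "vite", "mg", 7.5, "tocopherol antioxidant"),
    ("Phosphorus", "p", "mg", 700.0, "mineral bone"),
    ("Iodine", "iod", "mcg", 140.0, "mineral thyroid"),
    ("Cis ω-3 Fatty acids", "facn3", "g", 1.0, "omega 3 healthy fat"),
    ("Carbohydrates", "choavldf", "g", 130.0, "available carbohydrate energy"),
]

_CATEGORIES = ("Cereals", "Pulses", "Vegetables", "Fruits", "Dairy")
_AGE_BANDS = ((1, 18), (19, 30), (31, 50), (51, 120))


@dataclass
class GeneratorConfig:
    n_foods: int = 50
    n_nutrients: int = 12
    n_diseases: int = 5
    nutrients_per_disease: Tuple[int, int] = (3, 5)
    composition_density: float = 1.0
    superfood_count: int = 3
    balanced_count: int = 3
    sigma: float = 1.0  # log-normal shape of regular amounts
    seed: int = 0

    def __post_init__(self):
        if min(self.n_foods, self.n_nutrients, self.n_diseases) < 1:
            raise ValidationError("counts must be >= 1")
        if not (0 < self.composition_density <= 1):
            raise ValidationError("density must lie in (0, 1]")
        if self.superfood_count + self.balanced_count > self.n_foods:
            raise ValidationError("more planted foods than foods")
        lo, hi = self.nutrients_per_disease
        if not (1 <= lo <= hi <= self.n_nutrients):
            raise ValidationError("invalid nutrients_per_disease range")

    def as_dict(self) -> dict:
        return asdict(self)


def _nutrient_catalogue(n: int):
    rows = list(_CATALOGUE[:n])
    for i in range(len(rows), n):
        rows.append(
            (f"Nutrient {i + 1:03d}", f"nutr{i + 1:03d}", "mg", 10.0, "synthetic")
        )
    return rows


def gen_tables(config: GeneratorConfig) -> RawTables:
    """Generate the four raw tables; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    catalogue = _nutrient_catalogue(config.n_nutrients)
    names = [c[0] for c in catalogue]
    codes = [c[1] for c in catalogue]
    units = [c[2] for c in catalogue]
    ref_rda = {c[0]: c[3] for c in catalogue}

    abbrev = pd.DataFrame(
        {
            "code": codes,
            "scientific_name": names,
            "unit": units,
            "tags": [c[4] for c in catalogue],
        }
    )

    # RDA bands per nutrient x gender, plus pregnancy/lactation overrides
    rda_rows = []
    for name, unit in zip(names, units):
        base = ref_rda[name]
        for gender in ("male", "female"):
            gender_factor = 1.0 if gender == "female" else float(
                rng.uniform(0.85, 1.2)
            )
            for (lo, hi), band_factor in zip(_AGE_BANDS, (0.6, 1.0, 1.02, 0.95)):
                rda_rows.append(
                    {
                        "nutrient": name,
                        "gender": gender,
                        "age_lo": lo,
                        "age_hi": hi,
                        "state": "none",
                        "amount": round(base * gender_factor * band_factor, 4),
                        "unit": unit,
                    }
                )
        for state, factor in (("pregnant", 1.2), ("lactating", 1.3)):
            rda_rows.append(
                {
                    "nutrient": name,
                    "gender": "female",
                    "age_lo": 0,
                    "age_hi": 120,
                    "state": state,
                    "amount": round(base * factor, 4),
                    "unit": unit,
                }
            )
    rda = pd.DataFrame(rda_rows)

    # diseases; the first disease anchors the planted structure
    disease_rows = []
    required_first: Tuple[str, ...] = ()
    lo, hi = config.nutrients_per_disease
    for d in range(config.n_diseases):
        n_req = int(rng.integers(lo, hi + 1))
        required = list(rng.choice(names, size=n_req, replace=False))
        if d == 0:
            required_first = tuple(required)
        disease_rows.append(
            {
                "disease": f"Disease {d + 1:02d}",
                "nutrients": ";".join(required),
                "clinical_notes": f"Synthetic condition {d + 1}.",
                "symptom_aliases": f"signs of disease {d + 1:02d}",
            }
        )
    disease = pd.DataFrame(disease_rows)

    # food composition: planted balanced foods, planted superfoods, regulars
    category_shift = {
        (cat, name): float(rng.lognormal(0.0, 0.3))
        for cat in _CATEGORIES
        for name in names
    }
    food_rows = []
    n_regular = config.n_foods - config.superfood_count - config.balanced_count
    for b in range(config.balanced_count):
        row = {
            "code": f"BAL{b + 1:02d}",
            "name": f"Balanced food {b + 1:02d}",
            "category": _CATEGORIES[b % len(_CATEGORIES)],
        }
        for name in names:
            if name in required_first:
                row[codes[names.index(name)]] = round(
                    float(rng.uniform(0.4, 0.8)) * ref_rda[name], 4
                )
            else:
                row[codes[names.index(name)]] = round(
                    float(rng.uniform(0.01, 0.05)) * ref_rda[name], 4
                )
        food_rows.append(row)
    for s in range(config.superfood_count):
        spike = required_first[s % len(required_first)]
        row = {
            "code": f"SUP{s + 1:02d}",
            "name": f"Superfood {s + 1:02d}",
            "category": _CATEGORIES[s % len(_CATEGORIES)],
        }
        for name in names:
            if name == spike:
                row[codes[names.index(name)]] = round(
                    float(rng.uniform(3.0, 10.0)) * ref_rda[name], 4
                )
            elif name in required_first:
                row[codes[names.index(name)]] = 0.0
            else:
                row[codes[names.index(name)]] = round(
                    float(rng.uniform(0.0, 0.02)) * ref_rda[name], 4
                )
        food_rows.append(row)
    for f in range(n_regular):
        cat = _CATEGORIES[f % len(_CATEGORIES)]
        row = {
            "code": f"F{f + 1:03d}",
            "name": f"Food {f + 1:03d}",
            "category": cat,
        }
        for name, code in zip(names, codes):
            amount = (
                ref_rda[name]
                * 0.15
                * category_shift[(cat, name)]
                * float(rng.lognormal(0.0, config.sigma))
            )
            row[code] = round(amount, 4)
        food_rows.append(row)
    food = pd.DataFrame(food_rows)

    # inject missing cells into the regular foods only, so the planted
    # capped-vector structure survives imputation-free runs at density 1
    if config.composition_density < 1.0:
        planted = config.superfood_count + config.balanced_count
        mask = rng.random((n_regular, len(codes))) > config.composition_density
        for i in range(n_regular):
            for j, code in enumerate(codes):
                if mask[i, j]:
                    food.loc[planted + i, code] = np.nan

    return RawTables(disease=disease, food=food, rda=rda, abbrev=abbrev)


def gen_profiles(n: int, seed: int = 0) -> List[UserProfile]:
    """Deterministic profiles stratified over gender x age band x state."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    strata = [
        ("male", "none"),
        ("female", "none"),
        ("female", "pregnant"),
        ("male", "none"),
        ("female", "lactating"),
    ]
    bands = ((19, 30), (31, 50), (51, 70))
    profiles = []
    for i in range(n):
        gender, state = strata[i % len(strata)]
        lo, hi = bands[(i // len(strata)) % len(bands)]
        if state != "none":
            lo, hi = 20, 40  # physiological states drawn at reproductive ages
        profiles.append(
            UserProfile(
                age=int(rng.integers(lo, hi + 1)),
                gender=gender,
                state=state,
                query_text="",
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# hand-curated walkthrough fixture: pregnancy + iron-deficiency anemia
# ---------------------------------------------------------------------------

#: Folate amounts below are SYNTHETIC reconstructions (57 mcg for moringa,
#: 142.5 mcg for spinach): no measured folate value is bundled, these were
#: chosen so the capped components against the 570 mcg pregnancy target come
#: out at 0.10 and 0.25 exactly.
_WALKTHROUGH_FOODS = [
    # code, name, category, Iron mg, Vitamin C mg, Folic Acid mcg, Protein g,
    # Zinc mg, Vitamin D mcg
    ("A003", "Bajra (Pearl Millet)", "Cereals", 6.42, None, None, 10.96, None, None),
    ("B001", "Spinach (Palak)", "Vegetables", 2.9, 30.0, 142.5, 2.0, None, None),
    ("B002", "Drumstick Leaves (Moringa)", "Vegetables", 4.56, 108.0, 57.0, None, None, None),
    ("B003", "Fenugreek Leaves (Methi)", "Vegetables", 5.7, None, None, 4.4, None, None),
    ("C001", "Guava", "Fruits", None, 214.0, None, None, None, None),
    ("D001", "Paneer", "Dairy", None, None, None, 18.3, 2.0, None),
]


def anemia_walkthrough_tables() -> RawTables:
    """Canonical-form tables for the pregnancy/anemia walkthrough fixture."""
    disease = pd.DataFrame(
        [
            {
                "disease": "Iron Deficiency Anemia",
                "nutrients": "Iron;Vitamin C;Folic Acid",
                "clinical_notes": "Vitamin C is required to enhance Iron absorption.",
                "symptom_aliases": "hemoglobin low;low hemoglobin;feeling dizzy and weak",
            },
            {
                "disease": "Anemia",
                "nutrients": "Iron;Vitamin C;Folic Acid",
                "clinical_notes": "Vitamin C is required to enhance Iron absorption.",
                "symptom_aliases": "pale skin and fatigue",
            },
            {
                "disease": "Common Cold",
                "nutrients": "Vitamin C;Zinc;Protein;Vitamin D",
                "clinical_notes": "Supportive nutrition to maintain hydration.",
                "symptom_aliases": "runny nose and sneezing",
            },
        ]
    )
    columns = ["Iron", "Vitamin C", "Folic Acid", "Protein", "Zinc", "Vitamin D"]
    food = pd.DataFrame(
        [dict(zip(["code", "name", "category"] + columns, row)) for row in _WALKTHROUGH_FOODS]
    )
    rda_rows = [
        ("Iron", "female", 19, 30, "none", 29.0, "mg"),
        ("Iron", "male", 19, 30, "none", 19.0, "mg"),
        ("Iron", "female", 0, 120, "pregnant", 27.0, "mg"),
        ("Vitamin C", "female", 19, 30, "none", 65.0, "mg"),
        ("Vitamin C", "male", 19, 30, "none", 80.0, "mg"),
        ("Vitamin C", "female", 0, 120, "pregnant", 65.0, "mg"),
        ("Folic Acid", "female", 19, 30, "none", 220.0, "mcg"),
        ("Folic Acid", "male", 19, 30, "none", 220.0, "mcg"),
        ("Folic Acid", "female", 0, 120, "pregnant", 570.0, "mcg"),
        ("Protein", "male", 19, 30, "none", 54.0, "g"),
        ("Protein", "female", 19, 30, "none", 46.0, "g"),
        ("Zinc", "female", 19, 30, "none", 13.0, "mg"),
        ("Zinc", "male", 19, 30, "none", 17.0, "mg"),
        ("Vitamin D", "female", 19, 30, "none", 15.0, "mcg"),
        ("Vitamin D", "male", 19, 30, "none", 15.0, "mcg"),
    ]
    rda = pd.DataFrame(
        rda_rows,
        columns=["nutrient", "gender", "age_lo", "age_hi", "state", "amount", "unit"],
    )
    abbrev = pd.DataFrame(
        [
            ("fe", "Iron", "mg", "mineral haemoglobin blood"),
            ("vitc", "Vitamin C", "mg", "ascorbic acid antioxidant"),
            ("folsum", "Folic Acid", "mcg", "folate vitamin b9"),
            ("protcnt", "Protein", "g", "total essential proximate macronutrient"),
            ("zn", "Zinc", "mg", "mineral trace immune"),
            ("vitd", "Vitamin D", "mcg", "calciferol sunshine vitamin"),
        ],
        columns=["code", "scientific_name", "unit", "tags"],
    )
    return RawTables(disease=disease, food=food, rda=rda, abbrev=abbrev)


def anemia_walkthrough() -> Tuple[KnowledgeGraph, UserProfile]:
    """Pregnancy/anemia end-to-end fixture: small graph + matching profile."""
    tables = anemia_walkthrough_tables()
    graph = build_graph(tables.disease, tables.food, tables.rda, tables.abbrev)
    profile = UserProfile(
        age=28,
        gender="female",
        state="pregnant",
        query_text="dizzy hemoglobin low",
    )
    return graph, profile
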