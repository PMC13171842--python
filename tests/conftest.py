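import pandas as pd
import pytest
from hypothesis import settings

from nutrigraph import (
    ETLConfig,
    GeneratorConfig,
    RawTables,
    UserProfile,
    anemia_walkthrough,
    build_graph,
    gen_tables,
    run_etl,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def _tiny_frames(use_codes: bool = False):
    """3 diseases / 6 foods / 4 nutrients with hand-countable cells.

    Non-missing composition cells: 10; REQUIRES edges: 6; INDICATES: 2.
    """
    abbrev = pd.DataFrame(
        [
            ("fe", "Iron", "mg", "mineral blood"),
            ("vitc", "Vitamin C", "mg", "ascorbic acid"),
            ("zn", "Zinc", "mg", "mineral trace"),
            ("protcnt", "Protein", "g", "total essential proximate macronutrient"),
        ],
        columns=["code", "scientific_name", "unit", "tags"],
    )
    cols = (
        ["fe", "vitc", "zn", "protcnt"]
        if use_codes
        else ["Iron", "Vitamin C", "Zinc", "Protein"]
    )
    food = pd.DataFrame(
        [
            ("S01", "Spinach", "Vegetables", 2.9, 30.0, None, None),
            ("S02", "Bajra", "Cereals", 6.42, None, None, 10.96),
            ("S03", "Guava", "Fruits", None, 214.0, None, None),
            ("S04", "Paneer", "Dairy", None, None, 2.0, 18.3),
            ("S05", "Lentil", "Pulses", None, None, 1.3, 9.0),
            ("S06", "Rice", "Cereals", None, None, None, 2.7),
        ],
        columns=["code", "name", "category"] + cols,
    )
    disease = pd.DataFrame(
        [
            ("Anemia", "Iron;Vitamin C", "Iron absorption note.", "low hemoglobin"),
            ("Common Cold", "Vitamin C;Zinc;Protein", "Hydration note.", ""),
            ("Marasmus", "Protein", "Severe malnutrition.", "severe undernutrition"),
        ],
        columns=["disease", "nutrients", "clinical_notes", "symptom_aliases"],
    )
    rda = pd.DataFrame(
        [
            ("Iron", "female", 19, 30, "none", 29.0, "mg"),
            ("Iron", "male", 19, 30, "none", 19.0, "mg"),
            ("Iron", "female", 0, 120, "pregnant", 27.0, "mg"),
            ("Vitamin C", "female", 19, 30, "none", 65.0, "mg"),
            ("Vitamin C", "male", 19, 30, "none", 80.0, "mg"),
            ("Zinc", "female", 19, 30, "none", 13.0, "mg"),
            ("Zinc", "male", 19, 30, "none", 17.0, "mg"),
            ("Protein", "female", 19, 30, "none", 46.0, "g"),
            ("Protein", "male", 19, 30, "none", 54.0, "g"),
        ],
        columns=["nutrient", "gender", "age_lo", "age_hi", "state", "amount", "unit"],
    )
    return RawTables(disease=disease, food=food, rda=rda, abbrev=abbrev)


@pytest.fixture
def tiny_tables():
    return _tiny_frames(use_codes=False)


@pytest.fixture
def tiny_raw_tables():
    """Same fixture but with technical codes as food-table column headers."""
    return _tiny_frames(use_codes=True)


@pytest.fixture
def tiny_graph(tiny_tables):
    return build_graph(
        tiny_tables.disease, tiny_tables.food, tiny_tables.rda, tiny_tables.abbrev
    )


@pytest.fixture(scope="session")
def walkthrough():
    """Pregnancy + iron-deficiency anemia end-to-end fixture."""
    return anemia_walkthrough()


@pytest.fixture(scope="session")
def synthetic_graph():
    tables = gen_tables(GeneratorConfig(seed=3))
    return run_etl(tables, ETLConfig(impute=False)).graph


@pytest.fixture
def adult_female():
    return UserProfile(age=25, gender="female", query_text="check-up")
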