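"""CSV round-tripping of the four raw tables (UTF-8, decimal point)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .semantic_etl import RawTables

FILENAMES = {
    "disease": "disease_nutrients.csv",
    "food": "food_composition.csv",
    "rda": "rda_table.csv",
    "abbrev": "nutrient_map.csv",
}

_REQUIRED_COLUMNS = {
    "disease": {"disease", "nutrients"},
    "food": {"code", "name", "category"},
    "rda": {"nutrient", "gender", "age_lo", "age_hi", "state", "amount"},
    "abbrev": {"code", "scientific_name", "unit"},
}


def write_tables(tables: RawTables, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, filename in FILENAMES.items():
        getattr(tables, attr).to_csv(directory / filename, index=False)


def read_tables(directory) -> RawTables:
    directory = Path(directory)
    frames = {}
    for attr, filename in FILENAMES.items():
        path = directory / filename
        if not path.exists():
            raise SchemaError(f"missing input table {path}")
        frame = pd.read_csv(path)
        missing = _REQUIRED_COLUMNS[attr] - set(frame.columns)
        if missing:
            raise SchemaError(
                f"{filename}: missing columns {sorted(missing)}"
            )
        frames[attr] = frame
    return RawTables(**frames)


def write_manifest(directory, config: dict) -> None:
    path = Path(directory) / "manifest.json"
    path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")
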