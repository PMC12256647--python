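"""CSV/JSON read–write helpers with frozen column orders."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .segmentation import OBJECT_TABLE_COLUMNS

__all__ = [
    "write_object_table",
    "read_object_table",
    "write_summaries",
    "write_json",
    "read_soma_csv",
]

SOMA_COLUMNS = ["area_um2", "lamina", "gaba_status"]
SUMMARY_COLUMNS = [
    "image_id",
    "group",
    "n_candidate",
    "n_reference",
    "pct_candidate_coloc",
    "pct_reference_coloc",
    "ci",
]


def write_object_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=OBJECT_TABLE_COLUMNS)


def read_object_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(OBJECT_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"object table {path} missing columns: {sorted(missing)}")
    return table[OBJECT_TABLE_COLUMNS]


def write_summaries(summaries, path: str | Path) -> None:
    pd.DataFrame([s.to_row() for s in summaries]).to_csv(
        path, index=False, columns=SUMMARY_COLUMNS
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")


def read_soma_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(SOMA_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"soma table {path} missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError(f"soma table {path} is empty")
    if (table["area_um2"] <= 0).any():
        raise ValueError("soma areas must be positive")
    return table
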