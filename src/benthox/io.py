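"""Tabular output helpers: deterministic, full-precision CSV."""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from pathlib import Path

import pandas as pd

__all__ = ["rows_to_frame", "write_table", "read_table"]


def rows_to_frame(rows) -> pd.DataFrame:
    """Normalise a DataFrame / column mapping / list of dicts or dataclasses
    to a DataFrame."""
    if isinstance(rows, pd.DataFrame):
        return rows
    if isinstance(rows, dict):
        return pd.DataFrame(rows)
    rows = list(rows)
    if rows and is_dataclass(rows[0]):
        rows = [asdict(r) for r in rows]
    return pd.DataFrame(rows)


def write_table(rows, path) -> None:
    """Write tabular results as UTF-8 CSV with a header row.

    Column order follows the input; floats are written with ``repr``
    round-trip precision; an empty input is an error and creates no file.
    """
    frame = rows_to_frame(rows)
    if frame.empty:
        raise ValueError(f"refusing to write an empty table to {path}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
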