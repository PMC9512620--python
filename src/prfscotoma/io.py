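"""Delimited-text I/O for pRF result tables and curves.

Tables are comma-delimited UTF-8 with a single header row.  Angles are
degrees throughout; a table lacking the required degree-based columns
is rejected with a schema error naming the missing column.  Result
tables round-trip at full floating-point precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import RESULT_COLUMNS

__all__ = [
    "SchemaError",
    "read_result_table",
    "write_result_table",
    "write_curve",
    "read_curve",
]


class SchemaError(ValueError):
    """A table file does not match the expected column schema."""


def write_result_table(table: pd.DataFrame, path) -> Path:
    """Write a pRF result table as CSV (full precision)."""
    path = Path(path)
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"result table missing column(s): {', '.join(missing)}")
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_result_table(path) -> pd.DataFrame:
    """Read a pRF result table, validating the column schema."""
    table = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(
            f"result table {path} missing column(s): {', '.join(missing)}"
        )
    return table


def write_curve(x: np.ndarray, value: np.ndarray, path, value_name="density") -> Path:
    """Write a (x, value) curve as two-column CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"eccentricity_deg": x, value_name: value}).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def read_curve(path) -> pd.DataFrame:
    return pd.read_csv(path)
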