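"""Schema-checked CSV tables for free-fraction and surface-tension data.

Columns are declared up front; reading rejects missing or extra columns,
non-numeric cells (including locale-style decimal commas, which must not
be silently misparsed) and out-of-range values, naming the offending
column and row.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .errors import InvalidInputError


@dataclass(frozen=True)
class TableSchema:
    """Declared columns with optional per-column range validators."""

    name: str
    columns: tuple[str, ...]
    validators: dict  # column -> (predicate, description)


FREE_FRACTION_SCHEMA = TableSchema(
    name="free-fraction",
    columns=("concentration_mM", "free_fraction", "sd", "n_snapshots"),
    validators={
        "concentration_mM": (lambda v: v > 0, "must be positive"),
        "free_fraction": (lambda v: 0 <= v <= 1, "must lie in [0, 1]"),
        "sd": (lambda v: v >= 0, "must be non-negative"),
        "n_snapshots": (lambda v: v >= 1, "must be at least 1"),
    },
)

TENSION_SCHEMA = TableSchema(
    name="surface-tension",
    columns=("concentration_mM", "tension_mN_per_m"),
    validators={
        "concentration_mM": (lambda v: v > 0, "must be positive"),
        "tension_mN_per_m": (lambda v: v > 0, "must be positive"),
    },
)

CMC_TABLE_SCHEMA = TableSchema(
    name="cmc-table",
    columns=("chain", "condition", "cmc_mM"),
    validators={"cmc_mM": (lambda v: v > 0, "must be positive")},
)


def read_table(path: Union[str, Path], schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV against a schema."""
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    got = tuple(df.columns)
    if got != schema.columns:
        raise InvalidInputError(
            f"{schema.name} table header mismatch: expected {list(schema.columns)}, "
            f"got {list(got)}"
        )
    out = {}
    for col in schema.columns:
        if col in ("chain", "condition"):
            out[col] = df[col]
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise InvalidInputError(
                f"{schema.name} table: non-numeric value {df[col][row]!r} in "
                f"column {col!r}, row {row}"
            )
        if parsed.isna().any():
            row = int(parsed.isna().idxmax())
            raise InvalidInputError(
                f"{schema.name} table: missing value in column {col!r}, row {row}"
            )
        out[col] = parsed
    result = pd.DataFrame(out)
    for col, (pred, desc) in schema.validators.items():
        ok = result[col].map(pred)
        if not ok.all():
            row = int((~ok).idxmax())
            raise InvalidInputError(
                f"{schema.name} table: column {col!r} {desc} "
                f"(row {row} holds {result[col][row]!r})"
            )
    return result


def write_table(df: pd.DataFrame, path: Union[str, Path], schema: Optional[TableSchema] = None) -> None:
    """Write a CSV; when a schema is given, enforce its column set first."""
    if schema is not None:
        if tuple(df.columns) != schema.columns:
            raise InvalidInputError(
                f"{schema.name} table columns {list(df.columns)} do not match "
                f"schema {list(schema.columns)}"
            )
    df.to_csv(path, index=False)
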