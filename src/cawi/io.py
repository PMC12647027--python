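"""Panel CSV reading with field-level validation."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .indices import validate_panel
from .simulate import PANEL_COLUMNS

__all__ = ["read_panel_csv", "read_drg_csv"]

_NUMERIC = [c for c in PANEL_COLUMNS if c not in ("institution_id",)]


def _coerce_numeric(df: pd.DataFrame, columns, where: str) -> pd.DataFrame:
    for col in columns:
        raw = df[col]
        out = pd.to_numeric(raw, errors="coerce")
        bad = out.isna() & raw.notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(
                f"{where}: cannot parse field '{col}' on row {row}: {raw[bad].iloc[0]!r}"
            )
        df[col] = out
    return df


def read_panel_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a hospital-year panel CSV.

    The schema is the one written by :func:`cawi.simulate.write_panel_csv`
    (one row per institution-year); unknown columns are preserved but
    ignored downstream.  Schema violations raise ``ValueError`` naming the
    row and field.
    """
    df = pd.read_csv(path, dtype={"institution_id": str})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = _coerce_numeric(df, _NUMERIC, str(path))
    validate_panel(df)
    return df


def read_drg_csv(path: str | Path) -> pd.DataFrame:
    """Read a DRG case table (institution_id, year, relative_weight, case_count)."""
    df = pd.read_csv(path, dtype={"institution_id": str})
    needed = ["institution_id", "year", "relative_weight", "case_count"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return _coerce_numeric(df, ["year", "relative_weight", "case_count"], str(path))
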