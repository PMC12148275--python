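"""CSV readers/writers for the pipeline's interchange schemas.

One interchange format: comma-separated, UTF-8, header row (matching the
cell-table exports of digital-pathology tools). Headers are normalized by
stripping surrounding whitespace and lowercasing; unknown columns are
preserved untouched. Malformed numeric cells are reported with their row
and column. ``read(write(x))`` round-trips exactly up to float formatting.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError

CELL_TABLE_COLUMNS = (
    "participant_id", "core_id", "x_um", "y_um",
    "intensity_hoechst", "intensity_ck", "intensity_cd8", "intensity_foxp3",
)
CELL_NUMERIC_COLUMNS = CELL_TABLE_COLUMNS[2:]
SURVIVAL_COLUMNS = ("participant_id", "time", "event")


def _normalize_headers(df: pd.DataFrame) -> pd.DataFrame:
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _coerce_numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{path}: non-numeric value {df.loc[row, col]!r} in column "
                f"'{col}' at data row {row}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise SchemaError(f"{path}: empty value in column '{col}' at data row {row}")
        df[col] = coerced
    return df


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cell table (one row per segmented cell).

    Required columns: participant_id, core_id, x_um, y_um,
    intensity_{hoechst,ck,cd8,foxp3}. A ``cell_class`` column, if present,
    is kept (tables written by the classifier round-trip). Extra columns
    pass through untouched.
    """
    df = _normalize_headers(pd.read_csv(path))
    _require(df, CELL_TABLE_COLUMNS, path)
    df = _coerce_numeric(df, CELL_NUMERIC_COLUMNS, path)
    neg = [c for c in CELL_NUMERIC_COLUMNS[2:] if (df[c] < 0).any()]
    if neg:
        raise SchemaError(f"{path}: negative intensities in column(s) {neg}")
    df["participant_id"] = df["participant_id"].astype(str)
    df["core_id"] = df["core_id"].astype(str)
    return df


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read per-participant survival records (participant_id, time, event)."""
    df = _normalize_headers(pd.read_csv(path))
    _require(df, SURVIVAL_COLUMNS, path)
    df = _coerce_numeric(df, ("time", "event"), path)
    if not df["event"].isin([0, 1]).all():
        raise SchemaError(f"{path}: event indicator must be 0/1")
    if (df["time"] <= 0).any():
        raise SchemaError(f"{path}: follow-up times must be > 0")
    df["participant_id"] = df["participant_id"].astype(str)
    df["event"] = df["event"].astype(int)
    return df


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read per-participant categorical labels (participant_id + columns)."""
    df = _normalize_headers(pd.read_csv(path))
    _require(df, ("participant_id",), path)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: labels file needs at least one label column")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
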