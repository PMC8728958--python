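"""Readers and schema validators for the delimited claims tables.

All tables are RFC-4180 CSV with ISO-8601 dates.  Validation failures raise
:class:`SchemaError` carrying the file, row (0-based data row) and column so
pipeline callers can report exactly where an input is malformed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "SchemaError",
    "read_persons",
    "read_prescriptions",
    "read_surgeries",
    "read_visits",
    "validate_persons",
    "validate_prescriptions",
    "validate_surgeries",
    "validate_visits",
]


class SchemaError(ValueError):
    """A table violates its documented schema."""

    def __init__(self, file: str, row: Optional[int], column: Optional[str], message: str):
        self.file = file
        self.row = row
        self.column = column
        super().__init__(
            f"{file}"
            + (f", row {row}" if row is not None else "")
            + (f", column {column!r}" if column else "")
            + f": {message}"
        )


def _require_columns(df: pd.DataFrame, cols, file: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(file, None, missing[0], "missing required column")


def _parse_dates(df: pd.DataFrame, cols, file: str, required) -> pd.DataFrame:
    for c in cols:
        parsed = pd.to_datetime(df[c], errors="coerce", format="mixed")
        bad = parsed.isna() & df[c].notna()
        if bad.any():
            raise SchemaError(file, int(bad.idxmax()), c, f"unparseable date {df[c][bad].iloc[0]!r}")
        if c in required and parsed.isna().any():
            raise SchemaError(file, int(parsed.isna().idxmax()), c, "date is required")
        df[c] = parsed
    return df


def validate_persons(df: pd.DataFrame, file: str = "persons") -> pd.DataFrame:
    _require_columns(
        df,
        ["person_id", "sex", "birth_date", "diagnosis_date", "death_date", "emigration_date"],
        file,
    )
    df = df.copy()
    if df["person_id"].duplicated().any():
        raise SchemaError(file, int(df["person_id"].duplicated().idxmax()), "person_id", "duplicate id")
    bad_sex = ~df["sex"].isin(["F", "M"])
    if bad_sex.any():
        raise SchemaError(file, int(bad_sex.idxmax()), "sex", "sex must be 'F' or 'M'")
    df = _parse_dates(
        df,
        ["birth_date", "diagnosis_date", "death_date", "emigration_date"],
        file,
        required={"birth_date", "diagnosis_date"},
    )
    both = df["death_date"].notna() & df["emigration_date"].notna()
    if both.any():
        raise SchemaError(
            file, int(both.idxmax()), "death_date",
            "at most one of death_date/emigration_date may be set",
        )
    return df


def _validate_ids(df, persons: Optional[pd.DataFrame], file: str) -> None:
    if persons is None or df.empty:
        return
    known = set(persons["person_id"])
    bad = ~df["person_id"].isin(known)
    if bad.any():
        raise SchemaError(file, int(bad.idxmax()), "person_id", "unknown person id")


def validate_prescriptions(
    df: pd.DataFrame, persons: Optional[pd.DataFrame] = None, file: str = "prescriptions"
) -> pd.DataFrame:
    _require_columns(df, ["person_id", "drug_code", "dispense_date", "days_supplied"], file)
    df = df.copy()
    df = _parse_dates(df, ["dispense_date"], file, required={"dispense_date"})
    days = pd.to_numeric(df["days_supplied"], errors="coerce")
    bad = days.isna() | (days < 1) | (days != days.round())
    if bad.any():
        raise SchemaError(file, int(bad.idxmax()), "days_supplied", "must be a positive integer")
    df["days_supplied"] = days.astype(int)
    _validate_ids(df, persons, file)
    return df


def validate_surgeries(
    df: pd.DataFrame, persons: Optional[pd.DataFrame] = None, file: str = "surgeries"
) -> pd.DataFrame:
    _require_columns(df, ["person_id", "surgery_date"], file)
    df = _parse_dates(df.copy(), ["surgery_date"], file, required={"surgery_date"})
    _validate_ids(df, persons, file)
    return df


def validate_visits(
    df: pd.DataFrame, persons: Optional[pd.DataFrame] = None, file: str = "visits"
) -> pd.DataFrame:
    _require_columns(df, ["person_id", "visit_date", "dx"], file)
    df = _parse_dates(df.copy(), ["visit_date"], file, required={"visit_date"})
    bad = ~df["dx"].isin(["CD", "UC"])
    if bad.any():
        raise SchemaError(file, int(bad.idxmax()), "dx", "dx must be 'CD' or 'UC'")
    _validate_ids(df, persons, file)
    return df


def read_persons(path) -> pd.DataFrame:
    return validate_persons(pd.read_csv(path), file=str(path))


def read_prescriptions(path, persons: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    return validate_prescriptions(pd.read_csv(path), persons, file=str(path))


def read_surgeries(path, persons: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        return pd.DataFrame(columns=["person_id", "surgery_date"])
    return validate_surgeries(pd.read_csv(p), persons, file=str(path))


def read_visits(path, persons: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        return pd.DataFrame(columns=["person_id", "visit_date", "dx"])
    return validate_visits(pd.read_csv(p), persons, file=str(path))
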