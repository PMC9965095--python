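"""Cohort table schema and CSV round-trip.

A cohort is a pandas DataFrame with one row per participant carrying the raw
frailty measures (two grip trials, two 4-m walk trials, three questionnaire
responses), anthropometry, the survey weight and the background covariates.
Missing values are encoded as empty strings on disk and as NaN/None in
memory.
"""

from __future__ import annotations

import io
import os

import numpy as np
import pandas as pd

from .errors import SchemaError

SEXES = ("male", "female")
AGE_GROUPS = ("60-69", "70-79", "80+")

EXHAUSTION_LEVELS = (
    "rarely (<1 day)",
    "some (1-2 days)",
    "often (3-4 days)",
    "most (5-7 days)",
)
ACTIVITY_LEVELS = (
    "every day",
    ">1/week",
    "1/week",
    "1-3/month",
    "hardly ever/never",
)
YESNO = ("no", "yes")

COVARIATE_LEVELS = {
    "residence": ("rural", "urban"),
    "marital": ("in_wedlock", "not_in_wedlock"),
    "education": ("none", "primary", "secondary", "higher"),
    "work": ("never_worked", "working", "not_working", "retired"),
    "smoking": YESNO,
    "alcohol": YESNO,
    "adl": YESNO,
    "iadl": YESNO,
}

MEASURE_COLUMNS = (
    "bmi",
    "height",
    "grip_trial1",
    "grip_trial2",
    "walk_trial1",
    "walk_trial2",
)

# raw fields that feed the five frailty components (missingness targets)
FRAILTY_RAW_COLUMNS = (
    "grip_trial1",
    "grip_trial2",
    "walk_trial1",
    "walk_trial2",
    "exhaustion_response",
    "weight_loss_response",
    "activity_frequency",
)

COLUMNS = (
    "id",
    "sex",
    "age_group",
    "weight",
    "bmi",
    "height",
    "grip_trial1",
    "grip_trial2",
    "walk_trial1",
    "walk_trial2",
    "exhaustion_response",
    "weight_loss_response",
    "activity_frequency",
    "residence",
    "marital",
    "education",
    "work",
    "smoking",
    "alcohol",
    "adl",
    "iadl",
)

_CATEGORICAL_LEVELS = {
    "sex": SEXES,
    "age_group": AGE_GROUPS,
    "exhaustion_response": EXHAUSTION_LEVELS,
    "weight_loss_response": YESNO,
    "activity_frequency": ACTIVITY_LEVELS,
    **COVARIATE_LEVELS,
}

# fields that may be missing (raw frailty inputs); everything else must be set
_NULLABLE = set(FRAILTY_RAW_COLUMNS)


def empty_cohort() -> pd.DataFrame:
    """An empty table carrying the full cohort schema."""
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in COLUMNS})
    for c in ("weight", *MEASURE_COLUMNS):
        df[c] = df[c].astype(float)
    return df


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema, dtypes, ranges and id uniqueness; return the table.

    Raises :class:`SchemaError` naming the offending column (and row where
    it can be located).
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in COLUMNS]
    if unknown:
        raise SchemaError(f"unknown column(s): {', '.join(unknown)}")
    df = df.loc[:, list(COLUMNS)].reset_index(drop=True)

    if df["id"].isna().any():
        raise SchemaError("column 'id': missing identifier")
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate id '{dup.iloc[0]}'")

    for col in ("weight", *MEASURE_COLUMNS):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column '{col}': non-numeric value ({exc})") from None

    if len(df):
        for col, ok in [
            ("weight", lambda s: s.notna() & (s > 0)),
            ("bmi", lambda s: s.notna() & (s > 10) & (s < 60)),
            ("height", lambda s: s.notna() & (s > 120) & (s < 200)),
        ]:
            bad = ~ok(df[col])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"column '{col}', row {row}: value {df[col].iloc[row]!r} "
                    f"out of range"
                )
        for col in ("grip_trial1", "grip_trial2"):
            bad = df[col].notna() & (df[col] < 0)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(f"column '{col}', row {row}: negative grip")
        for col in ("walk_trial1", "walk_trial2"):
            bad = df[col].notna() & ~((df[col] > 1) & (df[col] < 120))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"column '{col}', row {row}: walk time outside (1, 120) s"
                )

    for col, levels in _CATEGORICAL_LEVELS.items():
        vals = df[col]
        bad = vals.notna() & ~vals.isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"column '{col}', row {row}: unknown category {vals.iloc[row]!r}"
            )
        if col not in _NULLABLE and vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise SchemaError(f"column '{col}', row {row}: missing value")
    return df


def write_cohort(cohort: pd.DataFrame, path: str | os.PathLike | io.TextIOBase) -> None:
    """Write a cohort as UTF-8 CSV; missing values become empty strings."""
    validate_cohort(cohort).to_csv(path, index=False, na_rep="")


def read_cohort(path: str | os.PathLike | io.TextIOBase) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(
        path,
        dtype={"id": str},
        keep_default_na=False,
        na_values=[""],
    )
    return validate_cohort(df)
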