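"""Reading and writing cohort CSV files with strict validation.

One row per person; documented header names; UTF-8; missing values are
empty cells and are reported as errors (with line numbers) unless the
caller opts into complete-case filtering.  Floats round-trip at full
precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .records import (COMORBIDITY_FLAGS, OUTCOME_LEVELS, RACE_LEVELS,
                      SEX_LEVELS, SMOKING_LEVELS)

__all__ = ["CohortFormatError", "read_cohort", "write_cohort", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = (
    "id", "age", "sex", "race_ethnicity", "education", "bmi",
    "smoking_status", "cigarettes_per_day", "years_smoked", "quit_years",
    "pack_years", "family_history_lc", "calendar_year", "survey_weight",
) + COMORBIDITY_FLAGS

OPTIONAL_COLUMNS = ("follow_up_years", "outcome")

_NUMERIC = ("age", "education", "bmi", "cigarettes_per_day", "years_smoked",
            "quit_years", "pack_years", "family_history_lc", "calendar_year",
            "survey_weight")


class CohortFormatError(ValueError):
    """A cohort file is malformed; the message carries line numbers."""


def _lines(mask: pd.Series) -> list[int]:
    # +2: one for the header row, one for 1-based numbering
    return [int(i) + 2 for i in np.flatnonzero(mask.to_numpy())][:20]


def read_cohort(path: Union[str, Path], complete_cases: bool = False) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    With ``complete_cases`` rows with any missing required value are
    dropped instead of raising; multiple imputation is out of scope.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortFormatError(f"{path}: missing required column(s) {missing_cols}")

    incomplete = df[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    if incomplete.any():
        if complete_cases:
            df = df[~incomplete].reset_index(drop=True)
        else:
            raise CohortFormatError(
                f"{path}: missing values in required fields at line(s) "
                f"{_lines(incomplete)} (use complete_cases=True to drop)")

    errors = []
    def check(mask: pd.Series, what: str) -> None:
        if mask.any():
            errors.append(f"{what} at line(s) {_lines(mask)}")

    check(~df["race_ethnicity"].isin(RACE_LEVELS),
          f"race_ethnicity not in {RACE_LEVELS}")
    check(~df["sex"].isin(SEX_LEVELS), f"sex not in {SEX_LEVELS}")
    check(~df["smoking_status"].isin(SMOKING_LEVELS),
          f"smoking_status not in {SMOKING_LEVELS}")
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        check(coerced.isna() & df[col].notna(), f"non-numeric {col}")
        df[col] = coerced
    check((df["age"] < 40) | (df["age"] > 80), "age outside [40, 80]")
    check(~df["education"].isin([1, 2, 3, 4, 5, 6]), "education outside 1..6")
    check(df["bmi"] <= 0, "bmi must be positive")
    check(~df["family_history_lc"].isin([0, 1, 2]), "family_history_lc outside 0..2")
    check(df["survey_weight"] < 0, "negative survey_weight")
    check((df["smoking_status"] == "current") & (df["quit_years"] != 0),
          "current smoker with nonzero quit_years")
    if "outcome" in df.columns:
        known = df["outcome"].isna() | df["outcome"].isin(OUTCOME_LEVELS)
        check(~known, f"outcome not in {OUTCOME_LEVELS}")
    if errors:
        raise CohortFormatError(f"{path}: " + "; ".join(errors))

    for flag in COMORBIDITY_FLAGS:
        df[flag] = df[flag].astype(bool)
    df["age"] = df["age"].astype(int)
    df["education"] = df["education"].astype(int)
    df["family_history_lc"] = df["family_history_lc"].astype(int)
    df["calendar_year"] = df["calendar_year"].astype(int)
    return df


def write_cohort(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a cohort CSV (full float precision, comorbidities as 0/1)."""
    out = df.copy()
    for flag in COMORBIDITY_FLAGS:
        if flag in out.columns:
            out[flag] = out[flag].astype(int)
    cols = [c for c in REQUIRED_COLUMNS if c in out.columns]
    cols += [c for c in OPTIONAL_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False, float_format="%.17g")
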