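"""Covariate coding schemes for the two survival submodels.

Each scheme turns raw covariates into a named vector of real-valued model
terms: log terms, ordinal trends, one-hot category dummies and binary
indicators.  Terms are stored *raw* (e.g. the education trend for a
bachelor's degree is 5, the log-BMI term for BMI 17 is ``log(17)``); the
linear predictor is evaluated relative to a fixed reference profile so that
the reference record contributes exactly zero.

Two schemes exist:

``lcdrat``
    Lung-cancer death risk: log age, sex, race/ethnicity, education trend,
    low-BMI indicator plus log BMI, pack-year categories, log quit-years,
    log years smoked, more-than-a-pack-a-day indicator, family-history
    trend, emphysema, and a (held at zero) screening indicator.

``acm``
    All-cause mortality, with age as the time scale: sex, race/ethnicity,
    education trend, calendar year, BMI categories, square-root pack-years,
    log quit-years, log cigarettes/day, and thirteen comorbidity
    indicators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import COMORBIDITY_FLAGS, PersonRecord, MissingFieldError

__all__ = [
    "SCHEMES",
    "scheme_terms",
    "reference_record",
    "reference_terms",
    "encode_covariates",
    "encode_dataframe",
]

_RACE_DUMMIES = {
    "race_african_american": "african_american",
    "race_asian_or_other": "asian_american",
    "race_hispanic": "hispanic_american",
}

LCDRAT_TERMS = (
    "three_annual_ct_screens",
    "log_age",
    "female",
    "race_african_american",
    "race_asian_or_other",
    "race_hispanic",
    "education",
    "bmi_le_18_5",
    "log_bmi",
    "pack_years_30_to_40",
    "pack_years_40_to_50",
    "pack_years_ge_50",
    "log_quit_years",
    "log_years_smoked",
    "gt_1_pack_per_day",
    "family_history_lc",
    "emphysema",
)

ACM_TERMS = (
    "female",
    "race_african_american",
    "race_asian_or_other",
    "race_hispanic",
    "education",
    "calendar_year",
    "bmi_le_18_5",
    "bmi_18_5_to_20",
    "bmi_25_to_30",
    "bmi_30_to_35",
    "bmi_gt_35",
    "sqrt_pack_years",
    "log_quit_years",
    "log_cigarettes_per_day",
) + COMORBIDITY_FLAGS

SCHEMES = ("lcdrat", "acm")

#: Columns a cohort frame must provide for encoding.
_REQUIRED_COLUMNS = (
    "age", "sex", "race_ethnicity", "education", "bmi", "smoking_status",
    "cigarettes_per_day", "years_smoked", "quit_years", "pack_years",
    "family_history_lc", "calendar_year",
)


def scheme_terms(scheme: str) -> tuple[str, ...]:
    if scheme == "lcdrat":
        return LCDRAT_TERMS
    if scheme == "acm":
        return ACM_TERMS
    raise ValueError(f"unknown coding scheme {scheme!r}")


def reference_record() -> PersonRecord:
    """The fixed reference profile: a White male current smoker of one pack
    a day for 20 years (20 pack-years), age 62, BMI 22.5, lowest education
    level, no family history, no comorbidities, assessed in 2015."""
    return PersonRecord(
        age=62, sex="male", race_ethnicity="white", education=1, bmi=22.5,
        smoking_status="current", cigarettes_per_day=20.0, years_smoked=20.0,
        quit_years=0.0, pack_years=20.0, family_history_lc=0,
        calendar_year=2015,
    )


def encode_dataframe(df: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Encode a cohort frame (one row per person) into model terms.

    Missing values in any required column raise :class:`MissingFieldError`
    with the offending column names; nothing is imputed.
    """
    terms = scheme_terms(scheme)  # validates the scheme id
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise MissingFieldError(f"cohort is missing required columns: {missing_cols}")
    na_cols = [c for c in _REQUIRED_COLUMNS if df[c].isna().any()]
    needed_flags = COMORBIDITY_FLAGS if scheme == "acm" else ("emphysema",)
    na_cols += [c for c in needed_flags
                if c in df.columns and df[c].isna().any()]
    na_cols += [c for c in needed_flags if c not in df.columns]
    if na_cols:
        raise MissingFieldError(f"missing values in required fields: {sorted(set(na_cols))}")

    out = pd.DataFrame(index=df.index)
    bmi = df["bmi"].to_numpy(float)
    qy = df["quit_years"].to_numpy(float)
    py = df["pack_years"].to_numpy(float)

    if scheme == "lcdrat":
        out["three_annual_ct_screens"] = 0.0  # screening handled in the life table
        out["log_age"] = np.log(df["age"].to_numpy(float))
        out["bmi_le_18_5"] = (bmi <= 18.5).astype(float)
        out["log_bmi"] = np.log(bmi)
        out["pack_years_30_to_40"] = ((py >= 30) & (py < 40)).astype(float)
        out["pack_years_40_to_50"] = ((py >= 40) & (py < 50)).astype(float)
        out["pack_years_ge_50"] = (py >= 50).astype(float)
        out["log_years_smoked"] = np.log(df["years_smoked"].to_numpy(float))
        out["gt_1_pack_per_day"] = (df["cigarettes_per_day"].to_numpy(float) > 20).astype(float)
        out["family_history_lc"] = df["family_history_lc"].to_numpy(float)
    else:
        out["calendar_year"] = df["calendar_year"].to_numpy(float)
        out["bmi_le_18_5"] = (bmi <= 18.5).astype(float)
        out["bmi_18_5_to_20"] = ((bmi > 18.5) & (bmi < 20)).astype(float)
        out["bmi_25_to_30"] = ((bmi >= 25) & (bmi < 30)).astype(float)
        out["bmi_30_to_35"] = ((bmi >= 30) & (bmi < 35)).astype(float)
        out["bmi_gt_35"] = (bmi >= 35).astype(float)
        out["sqrt_pack_years"] = np.sqrt(py)
        out["log_cigarettes_per_day"] = np.log(df["cigarettes_per_day"].to_numpy(float))
        for flag in COMORBIDITY_FLAGS:
            out[flag] = df[flag].to_numpy(float)

    out["female"] = (df["sex"] == "female").astype(float)
    race = df["race_ethnicity"]
    unknown = ~race.isin(["white"] + list(_RACE_DUMMIES.values()))
    if unknown.any():
        bad = sorted(race[unknown].unique())
        raise ValueError(f"unknown race/ethnicity level(s): {bad}")
    for dummy, level in _RACE_DUMMIES.items():
        out[dummy] = (race == level).astype(float)
    out["education"] = df["education"].to_numpy(float)
    # log of at-least-one quit-year: 0 for current smokers and recent quitters
    out["log_quit_years"] = np.log(np.maximum(qy, 1.0))
    if scheme == "lcdrat":
        out["emphysema"] = df["emphysema"].to_numpy(float)
    return out[list(terms)]


def _record_frame(record: PersonRecord) -> pd.DataFrame:
    row = {name: getattr(record, name)
           for name in _REQUIRED_COLUMNS + COMORBIDITY_FLAGS}
    return pd.DataFrame([row])


def encode_covariates(record: PersonRecord, scheme: str) -> dict[str, float]:
    """Encode a single record; deterministic in the record's fields."""
    frame = encode_dataframe(_record_frame(record), scheme)
    return {name: float(frame.iloc[0][name]) for name in frame.columns}


_REFERENCE_CACHE: dict[str, dict[str, float]] = {}


def reference_terms(scheme: str) -> dict[str, float]:
    """Term values of the reference profile, used to centre the linear
    predictor so the reference record scores exactly zero."""
    if scheme not in _REFERENCE_CACHE:
        _REFERENCE_CACHE[scheme] = encode_covariates(reference_record(), scheme)
    return _REFERENCE_CACHE[scheme]
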