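"""Individual-level input records for the screening-benefit models.

A :class:`PersonRecord` carries the covariates used by the two survival
submodels (lung-cancer death and all-cause mortality): demographics,
education, body-mass index, a detailed smoking history, family history of
lung cancer, and twelve-plus comorbidity flags, together with an optional
survey weight and optional mortality follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional

__all__ = [
    "RACE_LEVELS",
    "SEX_LEVELS",
    "SMOKING_LEVELS",
    "OUTCOME_LEVELS",
    "COMORBIDITY_FLAGS",
    "FollowUp",
    "PersonRecord",
    "RecordError",
    "MissingFieldError",
]

RACE_LEVELS = ("african_american", "asian_american", "hispanic_american", "white")
SEX_LEVELS = ("male", "female")
SMOKING_LEVELS = ("current", "former")
OUTCOME_LEVELS = ("censored", "lung_cancer_death", "other_death")

#: Comorbidity indicator names, in the order they appear in cohort files.
COMORBIDITY_FLAGS = (
    "emphysema",
    "diabetes",
    "kidney_failure",
    "liver_condition",
    "prior_cancer",
    "prior_stroke",
    "prior_heart_attack",
    "coronary_heart_disease",
    "heart_disease",
    "chronic_bronchitis",
    "hypertension",
    "angina",
    "special_equipment",
)


class RecordError(ValueError):
    """A record violates one of its invariants."""


class MissingFieldError(RecordError):
    """A required covariate is absent; values are never imputed silently."""


@dataclass(frozen=True)
class FollowUp:
    """Observed mortality follow-up: time on study and cause of death."""

    years: float
    outcome: str  # censored | lung_cancer_death | other_death

    def __post_init__(self) -> None:
        if self.years < 0:
            raise RecordError(f"follow-up years must be >= 0, got {self.years}")
        if self.outcome not in OUTCOME_LEVELS:
            raise RecordError(f"unknown outcome {self.outcome!r}")


@dataclass(frozen=True)
class PersonRecord:
    """One individual's covariates at assessment.

    ``age`` is the age at entry (40-80); ``pack_years`` should equal
    ``cigarettes_per_day * years_smoked / 20`` when all three are given;
    ``quit_years`` is 0 for current smokers.
    """

    age: int
    sex: str
    race_ethnicity: str
    education: int  # 1 (<12th grade) .. 6 (graduate school)
    bmi: float
    smoking_status: str
    cigarettes_per_day: float
    years_smoked: float
    quit_years: float
    pack_years: float
    family_history_lc: int  # 0, 1, or 2+ first-degree relatives
    calendar_year: int = 2015
    survey_weight: float = 1.0
    emphysema: bool = False
    diabetes: bool = False
    kidney_failure: bool = False
    liver_condition: bool = False
    prior_cancer: bool = False
    prior_stroke: bool = False
    prior_heart_attack: bool = False
    coronary_heart_disease: bool = False
    heart_disease: bool = False
    chronic_bronchitis: bool = False
    hypertension: bool = False
    angina: bool = False
    special_equipment: bool = False
    follow_up: Optional[FollowUp] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("age", "sex", "race_ethnicity", "education", "bmi",
                     "smoking_status", "cigarettes_per_day", "years_smoked",
                     "quit_years", "pack_years", "family_history_lc"):
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise MissingFieldError(f"required field {name!r} is missing")
        if not 40 <= self.age <= 80:
            raise RecordError(f"age must be in [40, 80], got {self.age}")
        if self.sex not in SEX_LEVELS:
            raise RecordError(f"unknown sex {self.sex!r}")
        if self.race_ethnicity not in RACE_LEVELS:
            raise RecordError(f"unknown race/ethnicity {self.race_ethnicity!r}")
        if self.education not in (1, 2, 3, 4, 5, 6):
            raise RecordError(f"education must be 1..6, got {self.education}")
        if not self.bmi > 0:
            raise RecordError(f"bmi must be positive, got {self.bmi}")
        if self.smoking_status not in SMOKING_LEVELS:
            raise RecordError(f"unknown smoking status {self.smoking_status!r}")
        if self.smoking_status == "current" and self.quit_years != 0:
            raise RecordError("current smokers must have quit_years = 0")
        if self.quit_years < 0:
            raise RecordError("quit_years must be >= 0")
        if self.cigarettes_per_day <= 0 or self.years_smoked <= 0:
            raise RecordError("cigarettes_per_day and years_smoked must be positive")
        if self.pack_years <= 0:
            raise RecordError("pack_years must be positive")
        if self.family_history_lc not in (0, 1, 2):
            raise RecordError(f"family_history_lc must be 0, 1 or 2, got "
                              f"{self.family_history_lc}")
        if self.survey_weight < 0:
            raise RecordError("survey_weight must be nonnegative")
        implied = self.cigarettes_per_day * self.years_smoked / 20.0
        if abs(self.pack_years - implied) > max(2.0, 0.2 * implied):
            raise RecordError(
                f"pack_years {self.pack_years:.1f} inconsistent with "
                f"cigarettes_per_day x years_smoked / 20 = {implied:.1f}")

    def with_race(self, race: str) -> "PersonRecord":
        """Return a copy with only the race/ethnicity field substituted."""
        if race == self.race_ethnicity:
            return self
        return replace(self, race_ethnicity=race)

    def comorbidity(self, name: str) -> bool:
        if name not in COMORBIDITY_FLAGS:
            raise KeyError(name)
        return bool(getattr(self, name))


def record_field_names() -> tuple[str, ...]:
    """Covariate field names in canonical cohort-file order."""
    skip = {"follow_up"}
    return tuple(f.name for f in fields(PersonRecord) if f.name not in skip)
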