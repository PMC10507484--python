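"""Annual competing-risk life tables and the screening benefit.

The benefit of attending screening is the difference in life expectancy
between two life tables built from the same pair of submodels: one in which
the lung-cancer death hazard is reduced by the screening effect (hazard
multiplier 0.796, i.e. a 20.4% reduction each year, for 5 annual cycles)
and one without it.  Cycles run from the person's entry age to the 100-year
cap; deaths within a cycle are credited half a year (half-cycle
correction); the difference is reported in days at 365.25 days/year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .records import PersonRecord
from .submodel import (AGE_MAX, SurvivalSubmodel, competing_risk_cycles,
                       other_cause_hazard)

__all__ = [
    "DAYS_PER_YEAR",
    "ScreeningEffect",
    "LifeTable",
    "BenefitResult",
    "build_life_table",
    "life_expectancy",
    "days_gained",
    "cohort_days_gained",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ScreeningEffect:
    """Three annual CT screens: 20.4% lower lung-cancer death hazard each
    year for 5 years."""

    hazard_multiplier: float = 0.796
    duration_years: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.hazard_multiplier <= 1:
            raise ValueError("hazard multiplier must be in (0, 1]")
        if self.duration_years < 0:
            raise ValueError("duration must be nonnegative")


@dataclass(frozen=True)
class LifeTable:
    """Per-cycle hazards, death probabilities and survival from a start age
    to the age cap."""

    start_age: int
    ages: np.ndarray          # cycle start ages
    h_lc: np.ndarray          # lung-cancer hazard per year (effect applied)
    h_oc: np.ndarray          # other-cause hazard per year
    q_lc: np.ndarray
    q_oc: np.ndarray
    q_all: np.ndarray
    survival: np.ndarray      # cumulative survival at cycle start, S[0] = 1
    life_expectancy: float    # years, half-cycle corrected, capped

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age": self.ages, "h_lc": self.h_lc, "h_oc": self.h_oc,
            "q_lc": self.q_lc, "q_oc": self.q_oc, "q_all": self.q_all,
            "survival_start": self.survival,
        })

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class BenefitResult:
    le_no_screen: float
    le_screen: float

    @property
    def days_gained(self) -> float:
        return DAYS_PER_YEAR * (self.le_screen - self.le_no_screen)


def _life_expectancy_from_q(q_all: np.ndarray) -> tuple[float, np.ndarray]:
    surv_start = np.concatenate([[1.0], np.cumprod(1.0 - q_all)[:-1]])
    # survivors of a cycle contribute a full year, within-cycle deaths half
    le = float(np.sum(surv_start * (1.0 - q_all / 2.0)))
    return le, surv_start


def build_life_table(lcdrat: SurvivalSubmodel, acm: SurvivalSubmodel,
                     record: PersonRecord,
                     effect: Optional[ScreeningEffect] = None,
                     age_cap: int = AGE_MAX) -> LifeTable:
    """Build the annual life table for one person.

    The screening effect, when given, multiplies the lung-cancer hazard for
    the first ``duration_years`` cycles; the other-cause hazard (all-cause
    net of the unscreened lung-cancer hazard) is untouched.
    """
    if not 40 <= record.age <= age_cap - 1:
        raise ValueError(f"start age {record.age} outside [40, {age_cap - 1}]")
    ages = np.arange(record.age, age_cap)
    h_lc = lcdrat.baseline(ages) * math.exp(lcdrat.lp_for_record(record))
    h_acm = acm.baseline(ages) * math.exp(acm.lp_for_record(record))
    h_oc = other_cause_hazard(h_acm, h_lc)
    if effect is not None:
        h_lc = h_lc.copy()
        h_lc[:effect.duration_years] *= effect.hazard_multiplier
    q_lc, q_oc, q_all = competing_risk_cycles(h_lc, h_oc)
    le, surv = _life_expectancy_from_q(q_all)
    return LifeTable(start_age=record.age, ages=ages, h_lc=h_lc, h_oc=h_oc,
                     q_lc=q_lc, q_oc=q_oc, q_all=q_all, survival=surv,
                     life_expectancy=le)


def life_expectancy(table: LifeTable) -> float:
    """Years of remaining life expectancy implied by the table."""
    return table.life_expectancy


def days_gained(lcdrat: SurvivalSubmodel, acm: SurvivalSubmodel,
                record: PersonRecord,
                effect: Optional[ScreeningEffect] = ScreeningEffect(),
                age_cap: int = AGE_MAX) -> BenefitResult:
    """Life expectancy with and without attending screening."""
    if effect is None:
        effect = ScreeningEffect()
    le_ns = build_life_table(lcdrat, acm, record, None, age_cap).life_expectancy
    le_s = build_life_table(lcdrat, acm, record, effect, age_cap).life_expectancy
    return BenefitResult(le_no_screen=le_ns, le_screen=le_s)


def _cohort_life_expectancy(lp_lc: np.ndarray, lp_acm: np.ndarray,
                            ages: np.ndarray,
                            lcdrat: SurvivalSubmodel, acm: SurvivalSubmodel,
                            effect: Optional[ScreeningEffect],
                            age_cap: int) -> np.ndarray:
    n = len(ages)
    max_cycles = int(age_cap - ages.min())
    k = np.arange(max_cycles)
    attained = ages[:, None] + k[None, :]
    alive_cycles = attained < age_cap  # cycles actually lived
    att_clipped = np.minimum(attained, age_cap)
    h_lc = lcdrat.baseline(att_clipped) * np.exp(lp_lc)[:, None]
    h_acm = acm.baseline(att_clipped) * np.exp(lp_acm)[:, None]
    h_oc = np.maximum(h_acm - h_lc, 0.0)
    if effect is not None:
        h_lc = h_lc.copy()
        h_lc[:, :effect.duration_years] *= effect.hazard_multiplier
    h_tot = h_lc + h_oc
    q_all = np.where(alive_cycles, -np.expm1(-h_tot), 0.0)
    surv_start = np.cumprod(np.hstack([np.ones((n, 1)), 1.0 - q_all[:, :-1]]),
                            axis=1)
    return np.sum(surv_start * (1.0 - q_all / 2.0) * alive_cycles, axis=1)


def cohort_days_gained(cohort_terms_lc: pd.DataFrame,
                       cohort_terms_acm: pd.DataFrame,
                       ages: np.ndarray,
                       lcdrat: SurvivalSubmodel, acm: SurvivalSubmodel,
                       effect: ScreeningEffect = ScreeningEffect(),
                       age_cap: int = AGE_MAX) -> np.ndarray:
    """Vectorized days of life gained for a cohort.

    ``cohort_terms_lc``/``cohort_terms_acm`` are encoded term frames for
    the two schemes (see :func:`lyfsct.coding.encode_dataframe`); ``ages``
    the integer entry ages.
    """
    ages = np.asarray(ages, dtype=int)
    lp_lc = lcdrat.linear_predictor_frame(cohort_terms_lc)
    lp_acm = acm.linear_predictor_frame(cohort_terms_acm)
    le_ns = _cohort_life_expectancy(lp_lc, lp_acm, ages, lcdrat, acm, None, age_cap)
    le_s = _cohort_life_expectancy(lp_lc, lp_acm, ages, lcdrat, acm, effect, age_cap)
    return DAYS_PER_YEAR * (le_s - le_ns)
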