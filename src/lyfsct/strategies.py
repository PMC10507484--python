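"""Screening-eligibility strategies and population-level accounting.

Five strategies decide who is offered screening at the 16.2-days-of-life-
gained threshold recommended by the American College of Chest Physicians:

``standard``
    Both submodels include race and ethnicity.
``no_race_acm``
    Race removed from the all-cause mortality submodel only.
``no_race``
    Race removed from both submodels.
``counterfactual_acm``
    Race stays in the models; for each person the benefit is also computed
    with White race substituted into the all-cause mortality submodel only,
    and the higher of the two benefits is used.
``counterfactual_full``
    As above but White race is substituted into both submodels.

The counterfactual strategies can only expand eligibility: the benefit used
is a max over the person's own-race benefit, so anyone eligible under the
standard model stays eligible, and White records are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .coding import encode_dataframe
from .lifetable import ScreeningEffect, cohort_days_gained, days_gained
from .records import PersonRecord
from .submodel import SurvivalSubmodel, cohort_five_year_risks

__all__ = [
    "STRATEGIES",
    "EligibilityConfig",
    "ModelSet",
    "benefit_under_strategy",
    "cohort_benefits",
    "decide_eligibility",
    "population_eligibility",
    "preventable_burden",
]

STRATEGIES = ("standard", "no_race_acm", "no_race",
              "counterfactual_acm", "counterfactual_full")


@dataclass(frozen=True)
class EligibilityConfig:
    threshold_days: float = 16.2
    counterfactual_reference_race: str = "white"
    effect: ScreeningEffect = ScreeningEffect()

    def __post_init__(self) -> None:
        if self.threshold_days <= 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class ModelSet:
    """The four submodel variants a strategy comparison needs."""

    lcdrat: SurvivalSubmodel
    lcdrat_norace: SurvivalSubmodel
    acm: SurvivalSubmodel
    acm_norace: SurvivalSubmodel

    @classmethod
    def from_mapping(cls, models: Mapping[str, SurvivalSubmodel]) -> "ModelSet":
        missing = [k for k in ("lcdrat", "lcdrat_norace", "acm", "acm_norace")
                   if k not in models]
        if missing:
            raise KeyError(f"missing model variant(s): {missing}")
        return cls(**{k: models[k] for k in
                      ("lcdrat", "lcdrat_norace", "acm", "acm_norace")})


def _check_strategy(strategy: str) -> None:
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def benefit_under_strategy(record: PersonRecord, strategy: str,
                           models: ModelSet,
                           cfg: EligibilityConfig = EligibilityConfig()) -> float:
    """Days of life gained from attending screening under one strategy."""
    _check_strategy(strategy)
    effect = cfg.effect
    if strategy == "standard":
        return days_gained(models.lcdrat, models.acm, record, effect).days_gained
    if strategy == "no_race_acm":
        return days_gained(models.lcdrat, models.acm_norace, record, effect).days_gained
    if strategy == "no_race":
        return days_gained(models.lcdrat_norace, models.acm_norace, record,
                           effect).days_gained
    own = days_gained(models.lcdrat, models.acm, record, effect).days_gained
    white = record.with_race(cfg.counterfactual_reference_race)
    if strategy == "counterfactual_acm":
        # White race substituted into the ACM submodel only
        sub = _counterfactual_acm_days(record, white, models, effect)
    else:  # counterfactual_full
        sub = days_gained(models.lcdrat, models.acm, white, effect).days_gained
    return max(own, sub)


def _counterfactual_acm_days(record: PersonRecord, white: PersonRecord,
                             models: ModelSet, effect: ScreeningEffect) -> float:
    df = pd.DataFrame([_row(record)])
    df_white = pd.DataFrame([_row(white)])
    terms_lc = encode_dataframe(df, models.lcdrat.coding_scheme)
    terms_acm = encode_dataframe(df_white, models.acm.coding_scheme)
    days = cohort_days_gained(terms_lc, terms_acm, np.array([record.age]),
                              models.lcdrat, models.acm, effect)
    return float(days[0])


def _row(record: PersonRecord) -> dict:
    from .records import record_field_names
    return {name: getattr(record, name) for name in record_field_names()}


def decide_eligibility(benefit_days: float,
                       cfg: EligibilityConfig = EligibilityConfig()) -> bool:
    """Eligible iff the benefit meets the threshold (inclusive at 16.2)."""
    if not np.isfinite(benefit_days):
        raise ValueError("benefit must be finite")
    return bool(benefit_days >= cfg.threshold_days)


# -- vectorized cohort paths ----------------------------------------------

def cohort_benefits(df: pd.DataFrame, strategy: str, models: ModelSet,
                    cfg: EligibilityConfig = EligibilityConfig()) -> np.ndarray:
    """Days gained for every cohort row under one strategy (vectorized)."""
    _check_strategy(strategy)
    effect = cfg.effect
    ages = df["age"].to_numpy(int)
    terms_lc = encode_dataframe(df, models.lcdrat.coding_scheme)
    terms_acm = encode_dataframe(df, models.acm.coding_scheme)
    if strategy == "standard":
        return cohort_days_gained(terms_lc, terms_acm, ages,
                                  models.lcdrat, models.acm, effect)
    if strategy == "no_race_acm":
        return cohort_days_gained(terms_lc, terms_acm, ages,
                                  models.lcdrat, models.acm_norace, effect)
    if strategy == "no_race":
        return cohort_days_gained(terms_lc, terms_acm, ages,
                                  models.lcdrat_norace, models.acm_norace, effect)
    own = cohort_days_gained(terms_lc, terms_acm, ages,
                             models.lcdrat, models.acm, effect)
    df_white = df.assign(race_ethnicity=cfg.counterfactual_reference_race)
    terms_lc_w = encode_dataframe(df_white, models.lcdrat.coding_scheme)
    terms_acm_w = encode_dataframe(df_white, models.acm.coding_scheme)
    if strategy == "counterfactual_acm":
        sub = cohort_days_gained(terms_lc, terms_acm_w, ages,
                                 models.lcdrat, models.acm, effect)
    else:
        sub = cohort_days_gained(terms_lc_w, terms_acm_w, ages,
                                 models.lcdrat, models.acm, effect)
    # White rows substitute into themselves: restore exact equality
    is_ref = (df["race_ethnicity"] == cfg.counterfactual_reference_race).to_numpy()
    sub = np.where(is_ref, own, sub)
    return np.maximum(own, sub)


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    total = weights.sum()
    return float(np.sum(values * weights) / total) if total > 0 else float("nan")


def population_eligibility(df: pd.DataFrame, strategy: str, models: ModelSet,
                           cfg: EligibilityConfig = EligibilityConfig()
                           ) -> pd.DataFrame:
    """Survey-weighted eligibility summary per race/ethnicity and overall.

    Reports, per group: the weighted number and proportion eligible, the
    mean standard-model benefit among the eligible, and — for strategies
    other than ``standard`` — the weighted counts and mean standard-model
    benefit of people whose status changed relative to the standard model
    (newly eligible / newly ineligible).
    """
    _check_strategy(strategy)
    std_days = cohort_benefits(df, "standard", models, cfg)
    days = std_days if strategy == "standard" else \
        cohort_benefits(df, strategy, models, cfg)
    eligible = days >= cfg.threshold_days
    std_eligible = std_days >= cfg.threshold_days
    w = df["survey_weight"].to_numpy(float)
    race = df["race_ethnicity"].to_numpy()

    rows = []
    groups = ["overall"] + sorted(pd.unique(race))
    for group in groups:
        mask = np.ones(len(df), bool) if group == "overall" else race == group
        wm, em = w[mask], eligible[mask]
        newly_in = mask & eligible & ~std_eligible
        newly_out = mask & ~eligible & std_eligible
        rows.append({
            "strategy": strategy,
            "group": group,
            "n": int(mask.sum()),
            "weighted_n": float(wm.sum()),
            "weighted_eligible": float(wm[em].sum()),
            "pct_eligible": 100.0 * _weighted_mean(em.astype(float), wm),
            "mean_std_days_eligible": _weighted_mean(std_days[mask][em], wm[em]),
            "weighted_newly_eligible": float(w[newly_in].sum()),
            "mean_std_days_newly_eligible": _weighted_mean(std_days[newly_in],
                                                           w[newly_in]),
            "weighted_newly_ineligible": float(w[newly_out].sum()),
            "mean_std_days_newly_ineligible": _weighted_mean(std_days[newly_out],
                                                             w[newly_out]),
        })
    return pd.DataFrame(rows)


def preventable_burden(df: pd.DataFrame, strategy: str, models: ModelSet,
                       cfg: EligibilityConfig = EligibilityConfig()
                       ) -> pd.DataFrame:
    """Preventable lung-cancer deaths and gainable life-years among the
    strategy-eligible, valued under the standard (with-race) models.

    Preventable deaths are the weighted sum of the five-year lung-cancer
    death risk difference without vs with the screening effect; gainable
    life is the weighted sum of standard-model days gained, in person-years.
    """
    _check_strategy(strategy)
    days = cohort_benefits(df, strategy, models, cfg)
    std_days = days if strategy == "standard" else \
        cohort_benefits(df, "standard", models, cfg)
    eligible = days >= cfg.threshold_days
    ages = df["age"].to_numpy(int)
    terms_lc = encode_dataframe(df, models.lcdrat.coding_scheme)
    terms_acm = encode_dataframe(df, models.acm.coding_scheme)
    risk_ns, _ = cohort_five_year_risks(terms_lc, terms_acm, ages,
                                        models.lcdrat, models.acm)
    risk_s, _ = cohort_five_year_risks(
        terms_lc, terms_acm, ages, models.lcdrat, models.acm,
        hazard_multiplier=cfg.effect.hazard_multiplier,
        effect_years=cfg.effect.duration_years)
    w = df["survey_weight"].to_numpy(float)
    race = df["race_ethnicity"].to_numpy()
    rows = []
    for group in ["overall"] + sorted(pd.unique(race)):
        mask = np.ones(len(df), bool) if group == "overall" else race == group
        sel = mask & eligible
        rows.append({
            "strategy": strategy,
            "group": group,
            "weighted_eligible": float(w[sel].sum()),
            "preventable_lc_deaths": float(np.sum(w[sel] * (risk_ns[sel] - risk_s[sel]))),
            "gainable_life_years": float(np.sum(w[sel] * std_days[sel]) / 365.25),
        })
    return pd.DataFrame(rows)
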