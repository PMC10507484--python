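"""Synthetic survey-like cohorts for the screening-benefit pipeline.

Generates cohorts whose covariate marginals per race and ethnicity follow
the published weighted characteristics of US ever-smokers aged 50 to 80
(race mix, sex, age bands, smoking status, pack-year and quit-year
categories, BMI classes, emphysema), with outcomes drawn from configurable
"true" submodels by competing-risks simulation on the age scale.  Within
race, covariates are sampled independently given the marginals except for
the deterministic smoking-history consistency links (quit-years are zero
for current smokers; pack-years equal cigarettes/day x years smoked / 20).

Joint distributions, within-category densities and the non-tabulated
covariates (education, family history, most comorbidities, survey-weight
shape) are invented, documented defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .coding import encode_dataframe
from .records import COMORBIDITY_FLAGS, RACE_LEVELS
from .submodel import AGE_MAX, SurvivalSubmodel, other_cause_hazard

__all__ = [
    "CohortConfig",
    "generate_covariates",
    "generate_outcomes",
    "generate_cohort",
    "replicate_five_year_observed",
    "load_config",
]

_RACES = RACE_LEVELS  # african_american, asian_american, hispanic_american, white

# Weighted race shares of US ever-smokers aged 50-80 (row percentages).
DEFAULT_RACE_MIX = {
    "african_american": 4301164 / 44417326,
    "asian_american": 1275950 / 44417326,
    "hispanic_american": 3866398 / 44417326,
    "white": 34973814 / 44417326,
}

_MALE_SHARE = {"african_american": 0.53, "asian_american": 0.75,
               "hispanic_american": 0.61, "white": 0.53}

_AGE_BANDS_50_80 = ((50, 54), (55, 59), (60, 64), (65, 69), (70, 74), (75, 80))
_AGE_PROBS = {
    "african_american": (0.19, 0.22, 0.22, 0.16, 0.11, 0.10),
    "asian_american": (0.22, 0.21, 0.20, 0.16, 0.13, 0.09),
    "hispanic_american": (0.26, 0.23, 0.19, 0.14, 0.11, 0.07),
    "white": (0.18, 0.20, 0.20, 0.18, 0.15, 0.11),
}

_CURRENT_SMOKER = {"african_american": 0.43, "asian_american": 0.33,
                   "hispanic_american": 0.32, "white": 0.31}

_PACK_YEAR_BOUNDS = ((1.0, 20.0), (20.0, 30.0), (30.0, 50.0), (50.0, 70.0),
                     (70.0, 120.0))
_PACK_YEAR_PROBS = {
    "current": {
        "african_american": (0.63, 0.19, 0.12, 0.05, 0.02),
        "asian_american": (0.65, 0.18, 0.13, 0.03, 0.01),
        "hispanic_american": (0.68, 0.16, 0.11, 0.03, 0.02),
        "white": (0.34, 0.19, 0.31, 0.10, 0.05),
    },
    "former": {
        "african_american": (0.65, 0.13, 0.15, 0.04, 0.04),
        "asian_american": (0.68, 0.10, 0.14, 0.04, 0.04),
        "hispanic_american": (0.70, 0.11, 0.13, 0.04, 0.03),
        "white": (0.63, 0.13, 0.15, 0.05, 0.04),
    },
}

_QUIT_BOUNDS = ((0.0, 1.0), (1.0, 5.0), (5.0, 10.0), (10.0, 30.0))
_QUIT_PROBS = {
    "african_american": (0.04, 0.11, 0.11, 0.74),
    "asian_american": (0.02, 0.11, 0.06, 0.81),
    "hispanic_american": (0.02, 0.08, 0.10, 0.80),
    "white": (0.03, 0.09, 0.09, 0.79),
}

_BMI_BOUNDS = ((16.0, 18.5), (18.5, 25.0), (25.0, 30.0), (30.0, 45.0))
_BMI_PROBS = {
    "african_american": (0.01, 0.25, 0.33, 0.41),
    "asian_american": (0.02, 0.45, 0.37, 0.16),
    "hispanic_american": (0.01, 0.21, 0.41, 0.37),
    "white": (0.02, 0.28, 0.37, 0.34),
}

_EMPHYSEMA = {"african_american": 0.04, "asian_american": 0.03,
              "hispanic_american": 0.03, "white": 0.06}

# Invented defaults for covariates without published marginals.
_EDUCATION_PROBS = (0.12, 0.28, 0.10, 0.25, 0.15, 0.10)
_FAMILY_HISTORY_PROBS = (0.88, 0.10, 0.02)
_COMORBIDITY_PREVALENCE = {
    "diabetes": 0.18, "kidney_failure": 0.03, "liver_condition": 0.02,
    "prior_cancer": 0.10, "prior_stroke": 0.06, "prior_heart_attack": 0.07,
    "coronary_heart_disease": 0.08, "heart_disease": 0.12,
    "chronic_bronchitis": 0.05, "hypertension": 0.45, "angina": 0.04,
    "special_equipment": 0.08,
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``age_bands`` of ``None`` uses the published per-race age distribution
    (valid for the 50-80 range only); otherwise supply shared
    ``(low, high, probability)`` bands.  ``outcome_mode`` is ``none``,
    ``five_year`` (exactly five years of follow-up for everyone) or
    ``full`` (administrative horizon with uniform staggered entry).
    """

    n: int
    seed: int
    race_mix: dict = field(default_factory=lambda: dict(DEFAULT_RACE_MIX))
    age_bands: Optional[Sequence[Sequence[float]]] = None
    calendar_years: tuple[int, int] = (2015, 2018)
    weights: str = "gamma"              # "gamma" | "unit"
    outcome_mode: str = "none"          # none | five_year | full
    horizon_years: float = 5.0
    entry_spread_years: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        unknown = set(self.race_mix) - set(_RACES)
        if unknown:
            raise ValueError(f"unknown race level(s) in mix: {sorted(unknown)}")
        total = sum(self.race_mix.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"race mix must sum to 1, sums to {total:.6f}")
        if self.weights not in ("gamma", "unit"):
            raise ValueError("weights must be 'gamma' or 'unit'")
        if self.outcome_mode not in ("none", "five_year", "full"):
            raise ValueError("outcome_mode must be none, five_year or full")
        if self.age_bands is None:
            return
        probs = sum(b[2] for b in self.age_bands)
        if not np.isclose(probs, 1.0, atol=1e-6):
            raise ValueError("age band probabilities must sum to 1")

    def to_json(self, path: Union[str, Path]) -> None:
        payload = asdict(self)
        payload["calendar_years"] = list(self.calendar_years)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, payload: dict) -> "CohortConfig":
        payload = dict(payload)
        if "calendar_years" in payload:
            payload["calendar_years"] = tuple(payload["calendar_years"])
        if payload.get("age_bands") is not None:
            payload["age_bands"] = tuple(tuple(b) for b in payload["age_bands"])
        return cls(**payload)


def load_config(name_or_path: Union[str, Path]) -> CohortConfig:
    """Load a cohort config from JSON, or a bundled fixture config by name
    (``nhis_like_small``, ``plco_like_small``)."""
    name = str(name_or_path)
    bundled = resources.files("lyfsct.data") / "configs" / f"{name}.json"
    if not name.endswith(".json") and bundled.is_file():
        return CohortConfig.from_dict(json.loads(bundled.read_text()))
    return CohortConfig.from_dict(json.loads(Path(name_or_path).read_text()))


def _choice(rng: np.random.Generator, probs: Sequence[float], size: int) -> np.ndarray:
    p = np.asarray(probs, float)
    return rng.choice(len(p), size=size, p=p / p.sum())


def _uniform_in(rng: np.random.Generator, bounds, idx: np.ndarray) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])[idx]
    hi = np.array([b[1] for b in bounds])[idx]
    return rng.uniform(lo, hi)


def generate_covariates(config: CohortConfig) -> pd.DataFrame:
    """Sample a covariate cohort; deterministic given ``config.seed``."""
    ss = np.random.SeedSequence([int(config.seed), 1])
    rng = np.random.default_rng(ss)
    n = config.n
    mix_races = sorted(config.race_mix)
    race_idx = _choice(rng, [config.race_mix[r] for r in mix_races], n)
    race = np.array(mix_races, dtype=object)[race_idx]

    age = np.empty(n, dtype=int)
    sex = np.empty(n, dtype=object)
    smoking = np.empty(n, dtype=object)
    pack_years = np.empty(n)
    quit_years = np.zeros(n)
    bmi = np.empty(n)
    emphysema = np.zeros(n, dtype=bool)

    for r in mix_races:
        mask = race == r
        m = int(mask.sum())
        if m == 0:
            continue
        if config.age_bands is None:
            bands, probs = _AGE_BANDS_50_80, _AGE_PROBS[r]
        else:
            bands = [(b[0], b[1]) for b in config.age_bands]
            probs = [b[2] for b in config.age_bands]
        band_idx = _choice(rng, probs, m)
        lo = np.array([b[0] for b in bands])[band_idx]
        hi = np.array([b[1] for b in bands])[band_idx]
        age[mask] = rng.integers(lo, hi + 1)
        sex[mask] = np.where(rng.random(m) < _MALE_SHARE[r], "male", "female")
        current = rng.random(m) < _CURRENT_SMOKER[r]
        smoking[mask] = np.where(current, "current", "former")
        status = np.where(current, "current", "former")
        py = np.empty(m)
        for st in ("current", "former"):
            sm = status == st
            if sm.any():
                cat = _choice(rng, _PACK_YEAR_PROBS[st][r], int(sm.sum()))
                py[sm] = _uniform_in(rng, _PACK_YEAR_BOUNDS, cat)
        pack_years[mask] = py
        qy = np.zeros(m)
        former = ~current
        if former.any():
            cat = _choice(rng, _QUIT_PROBS[r], int(former.sum()))
            qy[former] = _uniform_in(rng, _QUIT_BOUNDS, cat)
        quit_years[mask] = qy
        bmi_cat = _choice(rng, _BMI_PROBS[r], m)
        bmi[mask] = _uniform_in(rng, _BMI_BOUNDS, bmi_cat)
        emphysema[mask] = rng.random(m) < _EMPHYSEMA[r]

    # smoking-history consistency: duration from start age and quitting,
    # intensity from pack-years, then pack-years recomputed exactly
    start_age = rng.integers(15, 21, size=n)
    quit_years = np.minimum(quit_years, np.maximum(age - start_age - 3.0, 0.0))
    years_smoked = np.maximum(age - start_age - quit_years, 3.0)
    cpd = np.clip(20.0 * pack_years / years_smoked, 2.0, 60.0)
    pack_years = cpd * years_smoked / 20.0

    df = pd.DataFrame({
        "id": np.arange(n),
        "age": age,
        "sex": sex,
        "race_ethnicity": race,
        "education": _choice(rng, _EDUCATION_PROBS, n) + 1,
        "bmi": bmi,
        "smoking_status": smoking,
        "cigarettes_per_day": cpd,
        "years_smoked": years_smoked,
        "quit_years": quit_years,
        "pack_years": pack_years,
        "family_history_lc": _choice(rng, _FAMILY_HISTORY_PROBS, n),
        "calendar_year": rng.integers(config.calendar_years[0],
                                      config.calendar_years[1] + 1, size=n),
    })
    df["emphysema"] = emphysema
    for flag, prev in _COMORBIDITY_PREVALENCE.items():
        df[flag] = rng.random(n) < prev
    if config.weights == "gamma":
        df["survey_weight"] = rng.gamma(shape=4.0, scale=0.25, size=n)
    else:
        df["survey_weight"] = 1.0
    return df


def _cycle_hazards(df: pd.DataFrame, lcdrat: SurvivalSubmodel,
                   acm: SurvivalSubmodel, n_cycles: int):
    """Per-person per-cycle cause-specific hazards on the age scale."""
    ages = df["age"].to_numpy(int)
    attained = np.minimum(ages[:, None] + np.arange(n_cycles)[None, :], AGE_MAX)
    beyond = (ages[:, None] + np.arange(n_cycles)[None, :]) >= AGE_MAX
    lp_lc = lcdrat.linear_predictor_frame(encode_dataframe(df, lcdrat.coding_scheme))
    lp_acm = acm.linear_predictor_frame(encode_dataframe(df, acm.coding_scheme))
    h_lc = lcdrat.baseline(attained) * np.exp(lp_lc)[:, None]
    h_acm = acm.baseline(attained) * np.exp(lp_acm)[:, None]
    h_oc = other_cause_hazard(h_acm, h_lc)
    h_lc = np.where(beyond, 0.0, h_lc)
    h_oc = np.where(beyond, 0.0, h_oc)
    return h_lc, h_oc


def _draw_death(h_lc: np.ndarray, h_oc: np.ndarray, rng: np.random.Generator):
    """Draw (death_time_since_entry, is_lung_cancer, died) per person from
    piecewise-constant annual cause-specific hazards, with the exponential
    within-cycle time split."""
    n, t_max = h_lc.shape
    h_tot = h_lc + h_oc
    q_all = -np.expm1(-h_tot)
    u = rng.random((n, t_max))
    dies = u < q_all
    any_death = dies.any(axis=1)
    cycle = np.where(any_death, dies.argmax(axis=1), t_max)
    idx = np.minimum(cycle, t_max - 1)
    h_cycle = h_tot[np.arange(n), idx]
    h_l = h_lc[np.arange(n), idx]
    # truncated-exponential time within the death cycle
    u2 = rng.random(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(h_cycle > 0,
                        -np.log1p(-u2 * -np.expm1(-h_cycle)) / np.where(h_cycle > 0, h_cycle, 1.0),
                        0.0)
    time = cycle + np.clip(frac, 0.0, 1.0)
    u3 = rng.random(n)
    is_lc = any_death & (u3 < np.where(h_cycle > 0, h_l / np.where(h_cycle > 0, h_cycle, 1.0), 0.0))
    return time, is_lc, any_death


def generate_outcomes(df: pd.DataFrame, lcdrat_truth: SurvivalSubmodel,
                      acm_truth: SurvivalSubmodel,
                      config: CohortConfig) -> pd.DataFrame:
    """Attach simulated follow-up to a covariate cohort.

    Event ages are drawn from the cause-specific hazards of the supplied
    true submodels by annual competing-risks simulation; administrative
    censoring applies the configured horizon, less a uniform entry offset
    in ``full`` mode.  Deterministic given ``config.seed``.
    """
    if config.outcome_mode == "none":
        raise ValueError("config.outcome_mode is 'none'; nothing to simulate")
    horizon = 5.0 if config.outcome_mode == "five_year" else config.horizon_years
    spread = 0.0 if config.outcome_mode == "five_year" else config.entry_spread_years
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    n = len(df)
    ages = df["age"].to_numpy(int)
    n_cycles = int(min(np.ceil(horizon), AGE_MAX - ages.min()))
    h_lc, h_oc = _cycle_hazards(df, lcdrat_truth, acm_truth, n_cycles)
    death_time, is_lc, died = _draw_death(h_lc, h_oc, rng)
    censor = horizon - (rng.uniform(0.0, spread, size=n) if spread > 0 else 0.0)
    censor = np.minimum(censor, (AGE_MAX - ages).astype(float))
    observed_death = died & (death_time <= censor)
    follow = np.where(observed_death, death_time, censor)
    outcome = np.where(observed_death,
                       np.where(is_lc, "lung_cancer_death", "other_death"),
                       "censored")
    out = df.copy()
    out["follow_up_years"] = follow
    out["outcome"] = outcome
    return out


def generate_cohort(config: CohortConfig,
                    lcdrat_truth: Optional[SurvivalSubmodel] = None,
                    acm_truth: Optional[SurvivalSubmodel] = None) -> pd.DataFrame:
    """Covariates, plus outcomes when the config asks for them."""
    df = generate_covariates(config)
    if config.outcome_mode == "none":
        return df
    if lcdrat_truth is None or acm_truth is None:
        raise ValueError("outcome simulation needs both true submodels")
    return generate_outcomes(df, lcdrat_truth, acm_truth, config)


def replicate_five_year_observed(df: pd.DataFrame,
                                 lcdrat_truth: SurvivalSubmodel,
                                 acm_truth: SurvivalSubmodel,
                                 seed: int,
                                 min_events: int = 15000,
                                 max_reps: int = 4000,
                                 group_col: str = "race_ethnicity") -> pd.DataFrame:
    """Average five-year observed event counts over outcome replications.

    Repeatedly draws outcomes for the fixed covariate cohort from the true
    submodels and averages the survey-weighted observed lung-cancer and
    all-cause death counts per group, replicating until every group has
    accumulated ``min_events`` unweighted lung-cancer events (or
    ``max_reps``).  This drives the Monte-Carlo error of an E/O ratio well
    below biological signal sizes, so calibration closure can be checked
    against tight bands.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    w = df["survey_weight"].to_numpy(float)
    race = df[group_col].to_numpy()
    groups = ["overall"] + sorted(pd.unique(race))
    masks = {g: (np.ones(len(df), bool) if g == "overall" else race == g)
             for g in groups}
    h_lc, h_oc = _cycle_hazards(df, lcdrat_truth, acm_truth, 5)
    q_all = -np.expm1(-(h_lc + h_oc))
    h_tot = h_lc + h_oc
    frac_lc = np.where(h_tot > 0, h_lc / np.where(h_tot > 0, h_tot, 1.0), 0.0)

    sums_lc = {g: 0.0 for g in groups}
    sums_all = {g: 0.0 for g in groups}
    events_lc = {g: 0 for g in groups}
    events_all = {g: 0 for g in groups}
    reps = 0
    while reps < max_reps:
        u = rng.random(q_all.shape)
        dies = u < q_all
        died = dies.any(axis=1)
        cycle = np.where(died, dies.argmax(axis=1), 4)
        lc = died & (rng.random(len(df)) < frac_lc[np.arange(len(df)), cycle])
        for g in groups:
            m = masks[g]
            sums_lc[g] += float(w[m & lc].sum())
            sums_all[g] += float(w[m & died].sum())
            events_lc[g] += int((m & lc).sum())
            events_all[g] += int((m & died).sum())
        reps += 1
        if min(events_lc[g] for g in groups) >= min_events:
            break
    return pd.DataFrame([{
        "group": g,
        "replications": reps,
        "mean_observed_lc": sums_lc[g] / reps,
        "mean_observed_all": sums_all[g] / reps,
        "events_lc": events_lc[g],
        "events_all": events_all[g],
    } for g in groups])
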