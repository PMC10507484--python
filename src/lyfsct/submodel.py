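"""Cox-form survival submodels with parametric Gompertz baselines.

A :class:`SurvivalSubmodel` is a coding scheme, a map of term name to
log-hazard-ratio, and an annual Gompertz baseline hazard over ages 40-100.
The annual cause-specific hazard for a person is
``h(age) = h0(age) * exp(lp)`` where the linear predictor ``lp`` is the
coefficient-weighted sum of the person's terms measured from the scheme's
reference profile.  Covariate terms (including the log-age and calendar-year
terms) are frozen at their entry values; attained age acts only through the
baseline, so hazard ratios between people are age-invariant.

Five-year lung-cancer death risk combines the lung-cancer and all-cause
submodels as competing risks in annual cycles: the other-cause hazard is the
all-cause hazard net of the lung-cancer hazard, within-cycle deaths split in
proportion to the cause-specific hazards.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .coding import encode_covariates, reference_terms, scheme_terms
from .records import PersonRecord

__all__ = [
    "AGE_MIN",
    "AGE_MAX",
    "GompertzBaseline",
    "SurvivalSubmodel",
    "linear_predictor",
    "annual_hazard",
    "other_cause_hazard",
    "competing_risk_cycles",
    "five_year_lc_death_risk",
    "five_year_all_death_risk",
    "load_submodel",
    "load_default_submodels",
]

AGE_MIN = 40
AGE_MAX = 100

OUTCOMES = ("lung_cancer_death", "all_cause_mortality", "other_cause_death")

_RACE_TERMS = ("race_african_american", "race_asian_or_other", "race_hispanic")


@dataclass(frozen=True)
class GompertzBaseline:
    """Annual baseline hazard ``h0(age) = level * exp(shape * (age - 40))``."""

    level: float
    shape: float

    def __post_init__(self) -> None:
        if self.level <= 0:
            raise ValueError("Gompertz level must be positive")
        if self.shape < 0:
            raise ValueError("Gompertz shape must be nonnegative (hazard "
                             "nondecreasing in age)")

    def __call__(self, age):
        age = np.asarray(age, dtype=float)
        if np.any(age < AGE_MIN) or np.any(age > AGE_MAX):
            raise ValueError(f"age outside supported range [{AGE_MIN}, {AGE_MAX}]")
        return self.level * np.exp(self.shape * (age - AGE_MIN))


@dataclass(frozen=True)
class SurvivalSubmodel:
    outcome: str
    includes_race: bool
    coding_scheme: str
    coefficients: Mapping[str, float]  # term name -> log hazard ratio
    baseline: GompertzBaseline

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        terms = set(scheme_terms(self.coding_scheme))
        unknown = set(self.coefficients) - terms
        if unknown:
            raise ValueError(f"coefficients reference terms absent from scheme "
                             f"{self.coding_scheme!r}: {sorted(unknown)}")
        has_race = any(t in self.coefficients for t in _RACE_TERMS)
        if has_race != self.includes_race:
            raise ValueError("includes_race flag inconsistent with coefficient set")

    # -- linear predictors -------------------------------------------------
    def linear_predictor(self, terms: Mapping[str, float]) -> float:
        ref = reference_terms(self.coding_scheme)
        lp = 0.0
        for name, coef in self.coefficients.items():
            if name not in terms:
                raise KeyError(f"term {name!r} required by the model is absent "
                               f"from the term vector")
            lp += coef * (float(terms[name]) - ref[name])
        if not math.isfinite(lp):
            raise ValueError("non-finite linear predictor")
        return lp

    def linear_predictor_frame(self, terms: pd.DataFrame) -> np.ndarray:
        """Vectorized linear predictor over an encoded cohort frame."""
        ref = reference_terms(self.coding_scheme)
        names = list(self.coefficients)
        missing = [n for n in names if n not in terms.columns]
        if missing:
            raise KeyError(f"term(s) {missing} required by the model are absent")
        coefs = np.array([self.coefficients[n] for n in names])
        offset = float(np.dot(coefs, [ref[n] for n in names]))
        return terms[names].to_numpy(float) @ coefs - offset

    def lp_for_record(self, record: PersonRecord) -> float:
        return self.linear_predictor(encode_covariates(record, self.coding_scheme))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "includes_race": self.includes_race,
            "coding_scheme": self.coding_scheme,
            "coefficients": dict(self.coefficients),
            "baseline": {"family": "gompertz",
                         "level": self.baseline.level,
                         "shape": self.baseline.shape},
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, payload: dict) -> "SurvivalSubmodel":
        base = payload["baseline"]
        if base.get("family", "gompertz") != "gompertz":
            raise ValueError(f"unsupported baseline family {base.get('family')!r}")
        return cls(
            outcome=payload["outcome"],
            includes_race=bool(payload["includes_race"]),
            coding_scheme=payload["coding_scheme"],
            coefficients={k: float(v) for k, v in payload["coefficients"].items()},
            baseline=GompertzBaseline(float(base["level"]), float(base["shape"])),
        )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SurvivalSubmodel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def linear_predictor(terms: Mapping[str, float], model: SurvivalSubmodel) -> float:
    """Σ coef·(term − reference term); exp of it multiplies per-term HRs."""
    return model.linear_predictor(terms)


def annual_hazard(model: SurvivalSubmodel, record: PersonRecord,
                  attained_age: float) -> float:
    """Annual hazard ``h0(attained_age) * exp(lp(record))``."""
    return float(model.baseline(attained_age)) * math.exp(model.lp_for_record(record))


def other_cause_hazard(h_acm, h_lc):
    """Other-cause hazard: all-cause net of lung cancer, floored at zero."""
    return np.maximum(np.asarray(h_acm, float) - np.asarray(h_lc, float), 0.0)


def competing_risk_cycles(h_lc, h_oc):
    """Annual-cycle death probabilities from cause-specific hazards.

    Returns ``(q_lc, q_oc, q_all)`` with ``q_all = 1 - exp(-(h_lc + h_oc))``
    split between causes in proportion to the hazards (exponential
    within-cycle split).  Where both hazards are zero the probabilities are
    exactly zero.
    """
    h_lc = np.asarray(h_lc, float)
    h_oc = np.asarray(h_oc, float)
    if np.any(h_lc < 0) or np.any(h_oc < 0):
        raise ValueError("hazards must be nonnegative")
    h_tot = h_lc + h_oc
    q_all = -np.expm1(-h_tot)
    safe = np.where(h_tot > 0, h_tot, 1.0)
    q_lc = np.where(h_tot > 0, q_all * h_lc / safe, 0.0)
    return q_lc, q_all - q_lc, q_all


def _hazard_profiles(lcdrat: SurvivalSubmodel, acm: SurvivalSubmodel,
                     record: PersonRecord, n_cycles: int):
    ages = record.age + np.arange(n_cycles)
    h_lc = lcdrat.baseline(ages) * math.exp(lcdrat.lp_for_record(record))
    h_acm = acm.baseline(ages) * math.exp(acm.lp_for_record(record))
    return h_lc, other_cause_hazard(h_acm, h_lc)


def _cumulative_incidence(h_lc: np.ndarray, h_oc: np.ndarray,
                          multiplier: float = 1.0,
                          effect_cycles: int = 0) -> tuple[float, float]:
    """(lung-cancer, total) death probability over the given cycles, with an
    optional lung-cancer hazard multiplier on the first ``effect_cycles``."""
    h_lc = h_lc.copy()
    h_lc[:effect_cycles] *= multiplier
    q_lc, _, q_all = competing_risk_cycles(h_lc, h_oc)
    surv_start = np.concatenate([[1.0], np.cumprod(1.0 - q_all)[:-1]])
    return float(np.sum(surv_start * q_lc)), float(1.0 - np.prod(1.0 - q_all))


def five_year_lc_death_risk(lcdrat: SurvivalSubmodel, acm: SurvivalSubmodel,
                            record: PersonRecord,
                            hazard_multiplier: float = 1.0,
                            effect_years: int = 0) -> float:
    """Five-year cumulative incidence of lung-cancer death under competing
    risks.  ``hazard_multiplier``/``effect_years`` optionally apply the
    screening effect to the lung-cancer hazard."""
    if record.age > 95:
        raise ValueError("five-year risk requires age <= 95 (100-year cap)")
    h_lc, h_oc = _hazard_profiles(lcdrat, acm, record, 5)
    risk, _ = _cumulative_incidence(h_lc, h_oc, hazard_multiplier,
                                    min(effect_years, 5))
    return risk


def five_year_all_death_risk(lcdrat: SurvivalSubmodel, acm: SurvivalSubmodel,
                             record: PersonRecord) -> float:
    """Five-year probability of death from any cause under the same
    cause-specific construction (lung-cancer plus net other-cause hazard)."""
    if record.age > 95:
        raise ValueError("five-year risk requires age <= 95 (100-year cap)")
    h_lc, h_oc = _hazard_profiles(lcdrat, acm, record, 5)
    _, total = _cumulative_incidence(h_lc, h_oc)
    return total


def cohort_five_year_risks(terms_lc: pd.DataFrame, terms_acm: pd.DataFrame,
                           ages, lcdrat: SurvivalSubmodel,
                           acm: SurvivalSubmodel,
                           hazard_multiplier: float = 1.0,
                           effect_years: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized five-year (lung-cancer, any-cause) death risks.

    ``terms_lc``/``terms_acm`` are encoded term frames; ``ages`` integer
    entry ages.  The optional multiplier applies the screening effect to the
    lung-cancer hazard for the first ``effect_years`` cycles.
    """
    ages = np.asarray(ages, dtype=int)
    if np.any(ages > 95):
        raise ValueError("five-year risk requires age <= 95 (100-year cap)")
    k = np.arange(5)
    attained = ages[:, None] + k[None, :]
    lp_lc = lcdrat.linear_predictor_frame(terms_lc)
    lp_acm = acm.linear_predictor_frame(terms_acm)
    h_lc = lcdrat.baseline(attained) * np.exp(lp_lc)[:, None]
    h_acm = acm.baseline(attained) * np.exp(lp_acm)[:, None]
    h_oc = np.maximum(h_acm - h_lc, 0.0)
    h_lc = h_lc.copy()
    h_lc[:, :effect_years] *= hazard_multiplier
    h_tot = h_lc + h_oc
    q_all = -np.expm1(-h_tot)
    with np.errstate(invalid="ignore"):
        q_lc = np.where(h_tot > 0, q_all * h_lc / np.where(h_tot > 0, h_tot, 1.0), 0.0)
    surv_start = np.cumprod(np.hstack([np.ones((len(ages), 1)),
                                       1.0 - q_all[:, :-1]]), axis=1)
    risk_lc = np.sum(surv_start * q_lc, axis=1)
    risk_all = 1.0 - np.prod(1.0 - q_all, axis=1)
    return risk_lc, risk_all


# -- bundled coefficient sets ---------------------------------------------

_DEFAULT_FILES = {
    "lcdrat": "lcdrat.json",
    "lcdrat_norace": "lcdrat_norace.json",
    "acm": "acm.json",
    "acm_norace": "acm_norace.json",
}


def load_submodel(name_or_path: Union[str, Path]) -> SurvivalSubmodel:
    """Load a submodel from a JSON file, or by bundled name
    (``lcdrat``, ``lcdrat_norace``, ``acm``, ``acm_norace``)."""
    name = str(name_or_path)
    if name in _DEFAULT_FILES:
        ref = resources.files("lyfsct.data") / _DEFAULT_FILES[name]
        return SurvivalSubmodel.from_dict(json.loads(ref.read_text()))
    return SurvivalSubmodel.from_json(name_or_path)


def load_default_submodels() -> dict[str, SurvivalSubmodel]:
    """The four bundled coefficient sets (published hazard ratios with the
    package's default Gompertz baselines)."""
    return {key: load_submodel(key) for key in _DEFAULT_FILES}
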