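"""Refit the survival submodels on cohort data, with or without race.

Fits are Cox proportional hazards with *age as the time scale*: subjects
enter risk sets at their entry age (left truncation) and leave at their
death or censoring age.  Ties are handled by the Efron approximation.  The
fitted baseline hazard (Breslow-type) is smoothed to the package's annual
Gompertz form so that the result plugs straight into the life-table
machinery as a :class:`~lyfsct.submodel.SurvivalSubmodel`.

The production fitter is lifelines' ``CoxPHFitter``; an independent
brute-force partial-likelihood oracle for tiny datasets lives in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .coding import encode_dataframe, reference_terms, scheme_terms
from .submodel import GompertzBaseline, SurvivalSubmodel

__all__ = ["FitSpec", "FitResult", "FitError", "fit", "refit_norace"]

_RACE_TERMS = ("race_african_american", "race_asian_or_other", "race_hispanic")

_OUTCOME_EVENTS = {
    "lung_cancer_death": ("lung_cancer_death",),
    "all_cause_mortality": ("lung_cancer_death", "other_death"),
}


class FitError(RuntimeError):
    """Fit failed: non-convergence, separation, or collinearity."""


@dataclass(frozen=True)
class FitSpec:
    outcome: str                      # lung_cancer_death | all_cause_mortality
    include_race: bool
    coding_scheme: str                # lcdrat | acm
    tie_method: str = "efron"
    drop_terms: Sequence[str] = ("three_annual_ct_screens",)
    use_weights: bool = False         # survey weights as frequency weights

    def __post_init__(self) -> None:
        if self.outcome not in _OUTCOME_EVENTS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.tie_method != "efron":
            raise ValueError("only Efron tie handling is supported")
        scheme_terms(self.coding_scheme)  # validates

    def term_names(self) -> list[str]:
        names = [t for t in scheme_terms(self.coding_scheme)
                 if t not in self.drop_terms]
        if not self.include_race:
            names = [t for t in names if t not in _RACE_TERMS]
        return names


@dataclass(frozen=True)
class FitResult:
    spec: FitSpec
    params: pd.DataFrame              # term, coef, se, hr, ci_low, ci_high
    log_likelihood: float
    n: int
    n_events: int
    converged: bool
    baseline: GompertzBaseline
    dropped_constant: tuple[str, ...] = ()

    def coef(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "coef"])

    def to_submodel(self) -> SurvivalSubmodel:
        coefs = dict(zip(self.params["term"], self.params["coef"]))
        # race dummies can drop out as constants (e.g. single-race cohorts)
        has_race = any(t in coefs for t in _RACE_TERMS)
        return SurvivalSubmodel(
            outcome=self.spec.outcome,
            includes_race=has_race,
            coding_scheme=self.spec.coding_scheme,
            coefficients=coefs,
            baseline=self.baseline,
        )


def _design(spec: FitSpec, df: pd.DataFrame):
    terms = encode_dataframe(df, spec.coding_scheme)[spec.term_names()]
    constant = [c for c in terms.columns if terms[c].nunique() <= 1]
    terms = terms.drop(columns=constant)
    x = terms.to_numpy(float)
    centered = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < centered.shape[1]:
        raise FitError(
            f"collinear design: rank {rank} < {centered.shape[1]} columns "
            f"({list(terms.columns)})")
    return terms, tuple(constant)


def fit(spec: FitSpec, df: pd.DataFrame) -> FitResult:
    """Maximize the Efron partial likelihood with left truncation at entry
    age and right censoring at exit age."""
    for col in ("age", "follow_up_years", "outcome"):
        if col not in df.columns:
            raise ValueError(f"cohort is missing required column {col!r}")
    event = df["outcome"].isin(_OUTCOME_EVENTS[spec.outcome]).to_numpy()
    if event.sum() < 1:
        raise FitError("no events in the data")
    terms, constant = _design(spec, df)
    data = terms.copy()
    data["entry_age"] = df["age"].to_numpy(float)
    data["exit_age"] = data["entry_age"] + df["follow_up_years"].to_numpy(float)
    data["event"] = event.astype(int)
    kwargs = {}
    if spec.use_weights and "survey_weight" in df.columns:
        data["survey_weight"] = df["survey_weight"].to_numpy(float)
        kwargs["weights_col"] = "survey_weight"
        kwargs["robust"] = True
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="exit_age", event_col="event",
                entry_col="entry_age",
                fit_options={"precision": 1e-9, "r_precision": 1e-14,
                             "max_steps": 500},
                **kwargs)
    except Exception as exc:  # convergence / separation diagnostics
        raise FitError(f"Cox fit failed: {exc}") from exc
    summary = cph.summary
    params = pd.DataFrame({
        "term": summary.index,
        "coef": summary["coef"].to_numpy(),
        "se": summary["se(coef)"].to_numpy(),
        "hr": summary["exp(coef)"].to_numpy(),
        "ci_low": np.exp(summary["coef lower 95%"].to_numpy()),
        "ci_high": np.exp(summary["coef upper 95%"].to_numpy()),
    }).reset_index(drop=True)
    baseline = _gompertz_baseline(spec, params, data)
    return FitResult(spec=spec, params=params,
                     log_likelihood=float(cph.log_likelihood_),
                     n=len(data), n_events=int(event.sum()), converged=True,
                     baseline=baseline, dropped_constant=constant)


def _gompertz_baseline(spec: FitSpec, params: pd.DataFrame,
                       data: pd.DataFrame) -> GompertzBaseline:
    """Breslow baseline hazard with left-truncated risk sets, on the
    reference-profile scale, least-squares smoothed to the annual Gompertz
    form.

    Risk-set denominators honour delayed entry: a subject contributes at
    age t only when ``entry < t <= exit``.  Computed as suffix sums over
    sorted entry and exit ages, so it stays O(n log n).
    """
    ref = reference_terms(spec.coding_scheme)
    names = list(params["term"])
    coefs = params["coef"].to_numpy()
    x = data[names].to_numpy(float)
    x_ref = np.array([ref[n] for n in names])
    theta = np.exp((x - x_ref) @ coefs)  # partial hazards vs reference

    entry = data["entry_age"].to_numpy(float)
    exit_ = data["exit_age"].to_numpy(float)
    event = data["event"].to_numpy() == 1
    times, counts = np.unique(exit_[event], return_counts=True)
    entry_sorted = np.sort(entry)
    exit_sorted_idx = np.argsort(exit_)
    theta_by_exit = theta[exit_sorted_idx]
    exit_sorted = exit_[exit_sorted_idx]
    # suffix sums: sum of theta over {exit >= t} and over {entry >= t}
    suffix_exit = np.concatenate([np.cumsum(theta_by_exit[::-1])[::-1], [0.0]])
    theta_by_entry = theta[np.argsort(entry)]
    suffix_entry = np.concatenate([np.cumsum(theta_by_entry[::-1])[::-1], [0.0]])
    denom = (suffix_exit[np.searchsorted(exit_sorted, times, side="left")]
             - suffix_entry[np.searchsorted(entry_sorted, times, side="left")])
    increments = counts / np.maximum(denom, 1e-300)

    lo = int(np.floor(times.min()))
    hi = int(np.ceil(times.max()))
    years = np.arange(lo, hi)
    bin_idx = np.clip(np.floor(times).astype(int) - lo, 0, len(years) - 1)
    h_year = np.bincount(bin_idx, weights=increments, minlength=len(years))
    events_per_year = np.bincount(bin_idx, weights=counts, minlength=len(years))
    keep = (h_year > 0) & (events_per_year > 0)
    if keep.sum() < 3:
        # too little age support to identify a slope: flat annual hazard
        level = float(increments.sum() / max(hi - lo, 1))
        return GompertzBaseline(level=max(level, 1e-12), shape=0.0)
    mid_ages = years + 0.5
    # weighted OLS of log annual hazard on age, weights ~ sqrt(events)
    w = np.sqrt(events_per_year[keep])
    slope, intercept = np.polyfit(mid_ages[keep] - 40.0, np.log(h_year[keep]),
                                  deg=1, w=w)
    return GompertzBaseline(level=float(np.exp(intercept)),
                            shape=float(max(slope, 0.0)))


def refit_norace(spec: FitSpec, df: pd.DataFrame
                 ) -> tuple[FitResult, FitResult, pd.DataFrame]:
    """Fit with race, refit without, and tabulate the coefficient shifts.

    Returns ``(fit_with_race, fit_without_race, shifts)`` where ``shifts``
    compares every non-race coefficient across the two fits in units of the
    with-race standard error.
    """
    if not spec.include_race:
        raise ValueError("spec must include race; the no-race variant is derived")
    with_race = fit(spec, df)
    norace_spec = FitSpec(outcome=spec.outcome, include_race=False,
                          coding_scheme=spec.coding_scheme,
                          tie_method=spec.tie_method,
                          drop_terms=tuple(spec.drop_terms),
                          use_weights=spec.use_weights)
    without_race = fit(norace_spec, df)
    a = with_race.params.set_index("term")
    b = without_race.params.set_index("term")
    shared = [t for t in a.index if t in b.index]
    shifts = pd.DataFrame({
        "term": shared,
        "coef_with_race": a.loc[shared, "coef"].to_numpy(),
        "coef_norace": b.loc[shared, "coef"].to_numpy(),
    })
    shifts["shift"] = shifts["coef_norace"] - shifts["coef_with_race"]
    shifts["se_with_race"] = a.loc[shared, "se"].to_numpy()
    shifts["shift_in_se"] = shifts["shift"] / shifts["se_with_race"]
    return with_race, without_race, shifts
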