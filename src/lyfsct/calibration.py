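"""Expected/observed calibration, discrimination and quintile reports.

Calibration is summarized as the ratio of the expected number of events
(the survey-weighted sum of predicted risks) to the observed number (the
weighted count of target events inside the horizon), with a 95% confidence
interval from a log-normal approximation using a Poisson variance on the
unweighted observed count.  Discrimination is the weighted area under the
ROC curve for the event-within-horizon outcome, excluding records censored
before the horizon without an event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "EVENT_LEVELS",
    "CalibrationReport",
    "outcome_frame",
    "expected_observed",
    "auc",
    "quintile_calibration",
    "calibration_by_group",
]


def outcome_frame(df: pd.DataFrame, predicted_risk, target: str) -> pd.DataFrame:
    """Assemble an outcome frame from a followed-up cohort.

    ``target`` is ``lung_cancer_death`` (other deaths become competing
    events) or ``all_cause_mortality`` (any death is a target event).
    """
    outcome = df["outcome"].to_numpy()
    if target == "lung_cancer_death":
        event = np.where(outcome == "lung_cancer_death", "target_event",
                         np.where(outcome == "other_death",
                                  "competing_event", "censored"))
    elif target == "all_cause_mortality":
        event = np.where(outcome == "censored", "censored", "target_event")
    else:
        raise ValueError(f"unknown target {target!r}")
    return pd.DataFrame({
        "predicted_risk": np.asarray(predicted_risk, float),
        "weight": df["survey_weight"].to_numpy(float),
        "follow_up_years": df["follow_up_years"].to_numpy(float),
        "event": event,
        "race_ethnicity": df["race_ethnicity"].to_numpy(),
    })

EVENT_LEVELS = ("target_event", "competing_event", "censored")


@dataclass(frozen=True)
class CalibrationReport:
    group: str
    n: int
    expected_events: float
    observed_events: float          # survey-weighted
    observed_unweighted: int
    eo_ratio: float                 # NaN when no events observed
    eo_ci_low: float
    eo_ci_high: float
    degenerate: bool = False        # set when the ratio or strata are undefined
    auc: float = float("nan")
    quintiles: tuple = ()

    @property
    def defined(self) -> bool:
        return not (self.degenerate or math.isnan(self.eo_ratio))


def _validate(df: pd.DataFrame) -> None:
    required = ("predicted_risk", "weight", "follow_up_years", "event")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"outcome frame missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("outcome frame is empty")
    risk = df["predicted_risk"].to_numpy(float)
    if np.any(risk < 0) or np.any(risk > 1) or np.any(~np.isfinite(risk)):
        raise ValueError("predicted_risk must lie in [0, 1]")
    if np.any(df["follow_up_years"].to_numpy(float) < 0):
        raise ValueError("follow_up_years must be nonnegative")
    bad = set(df["event"].unique()) - set(EVENT_LEVELS)
    if bad:
        raise ValueError(f"unknown event level(s): {sorted(bad)}")


def _observed_mask(df: pd.DataFrame, horizon: float) -> np.ndarray:
    return ((df["event"] == "target_event") &
            (df["follow_up_years"] <= horizon)).to_numpy()


def expected_observed(df: pd.DataFrame, horizon: float = 5.0,
                      group: str = "overall",
                      with_auc: bool = False) -> CalibrationReport:
    """E/O ratio with 95% CI for an outcome frame.

    Expected = Σ w·risk (censoring-invariant); observed = Σ w over target
    events within the horizon.  With no observed events the ratio is
    undefined and flagged rather than raised.
    """
    _validate(df)
    w = df["weight"].to_numpy(float)
    expected = float(np.sum(w * df["predicted_risk"].to_numpy(float)))
    obs_mask = _observed_mask(df, horizon)
    observed = float(np.sum(w[obs_mask]))
    n_events = int(obs_mask.sum())
    if n_events == 0 or observed == 0:
        return CalibrationReport(group=group, n=len(df), expected_events=expected,
                                 observed_events=observed, observed_unweighted=0,
                                 eo_ratio=float("nan"), eo_ci_low=float("nan"),
                                 eo_ci_high=float("nan"), degenerate=True)
    ratio = expected / observed
    # log-normal CI with Poisson variance on the unweighted event count
    se_log = math.sqrt(1.0 / n_events)
    lo = ratio * math.exp(-1.959963984540054 * se_log)
    hi = ratio * math.exp(+1.959963984540054 * se_log)
    report_auc = auc(df, horizon) if with_auc else float("nan")
    return CalibrationReport(group=group, n=len(df), expected_events=expected,
                             observed_events=observed,
                             observed_unweighted=n_events, eo_ratio=ratio,
                             eo_ci_low=lo, eo_ci_high=hi, auc=report_auc)


def auc(df: pd.DataFrame, horizon: float = 5.0) -> float:
    """Weighted AUC of predicted risk for the within-horizon target event.

    Controls are records event-free through the horizon (including
    competing events, which are known non-events for the target cause);
    records censored before the horizon without an event are excluded.
    Returns NaN for degenerate groups with only one outcome class.
    """
    _validate(df)
    is_event = _observed_mask(df, horizon)
    followed = (df["follow_up_years"].to_numpy(float) >= horizon) | \
               (df["event"] != "censored").to_numpy()
    keep = is_event | followed
    y = is_event[keep].astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        return float("nan")
    return float(roc_auc_score(y, df["predicted_risk"].to_numpy(float)[keep],
                               sample_weight=df["weight"].to_numpy(float)[keep]))


def _weighted_quantiles(values: np.ndarray, weights: np.ndarray,
                        probs: Sequence[float]) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order])
    cum = cum / cum[-1]
    return np.array([values[order][np.searchsorted(cum, p)] for p in probs])


def quintile_calibration(df: pd.DataFrame, horizon: float = 5.0,
                         n_bins: int = 5) -> list[CalibrationReport]:
    """Per-quintile E/O reports over weighted risk quintiles.

    Quintile cut points are weighted quantiles of predicted risk; ties that
    span a cut point are resolved by stable rank so the bins partition the
    sample.  When all risks coincide a single degenerate bin is returned,
    flagged as such.
    """
    _validate(df)
    if len(df) < n_bins:
        raise ValueError(f"need at least {n_bins} records for {n_bins} bins")
    risk = df["predicted_risk"].to_numpy(float)
    w = df["weight"].to_numpy(float)
    if np.allclose(risk, risk[0]):
        report = expected_observed(df, horizon, group="quintile_degenerate")
        return [CalibrationReport(**{**report.__dict__, "degenerate": True})]
    order = np.argsort(risk, kind="stable")
    cum = np.cumsum(w[order])
    edges = cum[-1] * np.arange(1, n_bins) / n_bins
    bin_of_sorted = np.searchsorted(edges, cum, side="left")
    bins = np.empty(len(df), dtype=int)
    bins[order] = bin_of_sorted
    reports = []
    for b in range(n_bins):
        sub = df.iloc[np.flatnonzero(bins == b)]
        if len(sub) == 0:
            continue
        reports.append(expected_observed(sub, horizon, group=f"quintile_{b + 1}"))
    return reports


def calibration_by_group(df: pd.DataFrame, horizon: float = 5.0,
                         group_col: str = "race_ethnicity",
                         with_auc: bool = False,
                         with_quintiles: bool = False) -> list[CalibrationReport]:
    """Overall report plus one report per group level present in the data."""
    reports = [expected_observed(df, horizon, "overall", with_auc)]
    if with_quintiles:
        reports[0] = CalibrationReport(
            **{**reports[0].__dict__,
               "quintiles": tuple(quintile_calibration(df, horizon))})
    for level in sorted(df[group_col].unique()):
        sub = df[df[group_col] == level]
        rep = expected_observed(sub, horizon, str(level), with_auc)
        if with_quintiles and len(sub) >= 5:
            rep = CalibrationReport(
                **{**rep.__dict__,
                   "quintiles": tuple(quintile_calibration(sub, horizon))})
        reports.append(rep)
    return reports
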