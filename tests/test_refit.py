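"""Cox refits: oracle agreement, parameter recovery, race removal."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from lyfsct.refit import FitError, FitSpec, fit, refit_norace
from lyfsct.simulate import CohortConfig, generate_cohort
from lyfsct.submodel import GompertzBaseline, SurvivalSubmodel
from tests.test_submodel import make_model


# ---------------------------------------------------------------- oracle --

def efron_partial_loglik(beta, entry, exit_, event, x):
    """Brute-force Efron partial log-likelihood with left truncation,
    by direct enumeration of risk sets (tiny n only)."""
    entry, exit_, event, x = map(np.asarray, (entry, exit_, event, x))
    ll = 0.0
    for t in np.unique(exit_[event == 1]):
        deaths = np.flatnonzero((exit_ == t) & (event == 1))
        at_risk = np.flatnonzero((entry < t) & (exit_ >= t))
        theta_risk = np.exp(beta * x[at_risk]).sum()
        theta_dead = np.exp(beta * x[deaths])
        d = len(deaths)
        ll += beta * x[deaths].sum()
        for j in range(d):
            ll -= math.log(theta_risk - (j / d) * theta_dead.sum())
    return ll


def _acm_only(*keep):
    from lyfsct.coding import ACM_TERMS
    return tuple(t for t in ACM_TERMS if t not in keep)


def _toy_fit_frame(sexes, ages, follow, outcomes):
    n = len(sexes)
    from lyfsct.records import COMORBIDITY_FLAGS
    df = pd.DataFrame({
        "age": ages, "sex": sexes, "race_ethnicity": ["white"] * n,
        "education": [2] * n, "bmi": [25.0] * n,
        "smoking_status": ["current"] * n, "cigarettes_per_day": [20.0] * n,
        "years_smoked": [30.0] * n, "quit_years": [0.0] * n,
        "pack_years": [30.0] * n, "family_history_lc": [0] * n,
        "calendar_year": [2016] * n, "survey_weight": [1.0] * n,
        "follow_up_years": follow, "outcome": outcomes,
    })
    for flag in COMORBIDITY_FLAGS:
        df[flag] = False
    return df


@pytest.mark.parametrize("follow,outcomes", [
    # distinct event times, one death per sex, mixed risk sets
    ([3.0, 3.0, 7.0, 6.0, 4.0],
     ["other_death", "other_death", "censored", "censored", "censored"]),
    # two tied event times exercise the Efron correction
    ([4.0, 3.0, 7.0, 6.0, 4.0],
     ["other_death", "other_death", "censored", "censored", "other_death"]),
])
def test_production_fit_matches_brute_force_oracle(follow, outcomes):
    sexes = ["female", "male", "female", "male", "male"]
    ages = [60, 61, 59, 63, 62]
    df = _toy_fit_frame(sexes, ages, follow, outcomes)
    spec = FitSpec(outcome="all_cause_mortality", include_race=True,
                   coding_scheme="acm", drop_terms=_acm_only("female"))
    result = fit(spec, df)
    entry = np.array(ages, float)
    exit_ = entry + np.array(follow)
    event = (np.array(outcomes) != "censored").astype(int)
    x = (np.array(sexes) == "female").astype(float)
    opt = minimize_scalar(lambda b: -efron_partial_loglik(b, entry, exit_, event, x),
                          bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-12})
    assert result.coef("female") == pytest.approx(opt.x, abs=1e-6)
    assert result.log_likelihood == pytest.approx(
        efron_partial_loglik(result.coef("female"), entry, exit_, event, x),
        abs=1e-8)


def test_optimum_beats_truth_and_zero():
    sexes = ["female", "male", "female", "male", "male", "female"]
    ages = [58, 61, 59, 63, 62, 60]
    follow = [6.0, 3.5, 6.2, 6.0, 4.1, 1.5]
    outcomes = ["other_death", "other_death", "censored", "censored",
                "other_death", "censored"]
    df = _toy_fit_frame(sexes, ages, follow, outcomes)
    spec = FitSpec(outcome="all_cause_mortality", include_race=True,
                   coding_scheme="acm", drop_terms=_acm_only("female"))
    result = fit(spec, df)
    entry = np.array(ages, float)
    exit_ = entry + np.array(follow)
    event = (np.array(outcomes) != "censored").astype(int)
    x = (np.array(sexes) == "female").astype(float)
    ll_hat = efron_partial_loglik(result.coef("female"), entry, exit_, event, x)
    assert ll_hat >= efron_partial_loglik(0.0, entry, exit_, event, x) - 1e-12
    assert ll_hat >= efron_partial_loglik(0.4, entry, exit_, event, x) - 1e-12


@pytest.fixture(scope="module")
def recovery_cohort():
    truth = make_model({"female": math.log(1.48)}, scheme="acm",
                       level=2e-3, shape=0.09, outcome="all_cause_mortality")
    lc_truth = make_model({}, level=1e-5, shape=0.05)
    config = CohortConfig(n=8000, seed=421, age_bands=((40, 80, 1.0),),
                          weights="unit", outcome_mode="full",
                          horizon_years=12.0, entry_spread_years=6.0)
    return generate_cohort(config, lc_truth, truth), truth


def test_binary_log_hr_recovered_within_three_se(recovery_cohort):
    df, truth = recovery_cohort
    spec = FitSpec(outcome="all_cause_mortality", include_race=True,
                   coding_scheme="acm", drop_terms=_acm_only("female"))
    result = fit(spec, df)
    row = result.params.set_index("term").loc["female"]
    assert abs(row["coef"] - math.log(1.48)) < 3 * row["se"]


def test_gompertz_baseline_recovered(recovery_cohort):
    df, truth = recovery_cohort
    spec = FitSpec(outcome="all_cause_mortality", include_race=True,
                   coding_scheme="acm", drop_terms=_acm_only("female"))
    result = fit(spec, df)
    assert result.baseline.shape == pytest.approx(0.09, abs=0.02)
    # level at a mid age within ~25%
    h60_true = 2e-3 * math.exp(0.09 * 20)
    h60_fit = result.baseline.level * math.exp(result.baseline.shape * 20)
    assert h60_fit == pytest.approx(h60_true, rel=0.25)


def test_null_covariate_estimates_near_zero(recovery_cohort):
    """The outcome does not depend on education: its estimate is within 3 SE
    of zero."""
    df, _ = recovery_cohort
    spec = FitSpec(outcome="all_cause_mortality", include_race=True,
                   coding_scheme="acm",
                   drop_terms=_acm_only("female", "education"))
    result = fit(spec, df)
    row = result.params.set_index("term").loc["education"]
    assert abs(row["coef"]) < 3 * row["se"]


def test_single_race_cohort_fits_identically_with_and_without_race(recovery_cohort):
    df, _ = recovery_cohort  # generator config is all-white here? ensure:
    df = df[df["race_ethnicity"] == "white"]
    spec = FitSpec(outcome="all_cause_mortality", include_race=True,
                   coding_scheme="acm",
                   drop_terms=_acm_only("female", "education", "diabetes",
                                        "race_african_american",
                                        "race_asian_or_other", "race_hispanic"))
    with_race, without_race, shifts = refit_norace(spec, df)
    assert set(with_race.dropped_constant) >= {"race_african_american",
                                               "race_asian_or_other",
                                               "race_hispanic"}
    assert np.allclose(shifts["shift"].to_numpy(), 0.0, atol=1e-10)


def test_row_order_invariance(recovery_cohort):
    df, _ = recovery_cohort
    spec = FitSpec(outcome="all_cause_mortality", include_race=True,
                   coding_scheme="acm", drop_terms=_acm_only("female"))
    a = fit(spec, df)
    shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
    b = fit(spec, shuffled)
    assert a.coef("female") == pytest.approx(b.coef("female"), abs=1e-8)


def test_no_events_is_a_fit_error():
    df = _toy_fit_frame(["male", "female"], [60, 61], [2.0, 3.0],
                        ["censored", "censored"])
    spec = FitSpec(outcome="all_cause_mortality", include_race=True,
                   coding_scheme="acm", drop_terms=_acm_only("female"))
    with pytest.raises(FitError, match="no events"):
        fit(spec, df)


def test_fitted_submodel_plugs_into_the_hazard_machinery(recovery_cohort):
    df, _ = recovery_cohort
    spec = FitSpec(outcome="all_cause_mortality", include_race=True,
                   coding_scheme="acm", drop_terms=_acm_only("female"))
    refit_model = fit(spec, df).to_submodel()
    assert isinstance(refit_model, SurvivalSubmodel)
    assert refit_model.coding_scheme == "acm"
    assert float(refit_model.baseline(70)) > float(refit_model.baseline(50))
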