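"""Eligibility strategies: the counterfactual max rule and accounting."""

import numpy as np
import pandas as pd
import pytest

from lyfsct.strategies import (STRATEGIES, EligibilityConfig, ModelSet,
                               benefit_under_strategy, cohort_benefits,
                               decide_eligibility, population_eligibility,
                               preventable_burden)
from tests.conftest import perturb, random_records


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(314)


def test_threshold_is_inclusive_at_16_point_2():
    assert decide_eligibility(16.2)
    assert not decide_eligibility(16.1999)
    assert not decide_eligibility(0.0)
    with pytest.raises(ValueError):
        decide_eligibility(float("nan"))


def test_white_records_are_invariant_under_counterfactual(model_set, reference):
    std = benefit_under_strategy(reference, "standard", model_set)
    for strategy in ("counterfactual_acm", "counterfactual_full"):
        assert benefit_under_strategy(reference, strategy, model_set) == std


def test_counterfactual_is_the_max_of_own_and_substituted(model_set, reference):
    aa = perturb(reference, race_ethnicity="african_american",
                 pack_years=45, years_smoked=45, cigarettes_per_day=20)
    own = benefit_under_strategy(aa, "standard", model_set)
    white_twin = aa.with_race("white")
    sub = benefit_under_strategy(white_twin, "standard", model_set)
    # full substitution changes both submodels, so the max is definitional
    cf = benefit_under_strategy(aa, "counterfactual_full", model_set)
    assert cf == pytest.approx(max(own, sub), rel=1e-12)


def test_counterfactual_acm_raises_african_american_benefit(model_set, rng):
    """White substitution in the mortality submodel lowers the competing
    hazard (ACM HR 1.22 -> 1), raising life expectancy and hence benefit."""
    records = [r.with_race("african_american") for r in random_records(rng, 200)]
    for record in records:
        own = benefit_under_strategy(record, "standard", model_set)
        cf = benefit_under_strategy(record, "counterfactual_acm", model_set)
        assert cf >= own - 1e-12
    # strictly higher for at least most profiles
    diffs = [benefit_under_strategy(r, "counterfactual_acm", model_set) -
             benefit_under_strategy(r, "standard", model_set) for r in records[:50]]
    assert np.mean(np.array(diffs) > 0) > 0.9


def test_no_race_benefits_ignore_the_race_label(model_set, rng):
    records = random_records(rng, 30)
    for record in records[:10]:
        values = {race: benefit_under_strategy(record.with_race(race),
                                               "no_race", model_set)
                  for race in ("white", "african_american", "hispanic_american")}
        assert len({round(v, 12) for v in values.values()}) == 1


def test_unknown_strategy_and_missing_variant_errors(model_set, reference):
    with pytest.raises(ValueError, match="unknown strategy"):
        benefit_under_strategy(reference, "uspstf", model_set)
    with pytest.raises(KeyError, match="missing model variant"):
        ModelSet.from_mapping({"lcdrat": model_set.lcdrat})


def test_cohort_benefits_match_scalar_path(model_set, small_cohort):
    df = small_cohort.head(30)
    from lyfsct.records import PersonRecord
    for strategy in STRATEGIES:
        vec = cohort_benefits(df, strategy, model_set)
        for i in (0, 17, 29):
            row = df.iloc[i]
            record = PersonRecord(**{
                k: (int(row[k]) if k in ("age", "education", "family_history_lc",
                                         "calendar_year") else row[k])
                for k in row.index if k not in ("id",)})
            scalar = benefit_under_strategy(record, strategy, model_set)
            assert vec[i] == pytest.approx(scalar, rel=1e-10, abs=1e-10)


def _toy_cohort(benefits, races, weights):
    """Covariate-light frame for accounting tests driven by fixed benefits."""
    n = len(benefits)
    base = {
        "age": [60] * n, "sex": ["male"] * n, "race_ethnicity": races,
        "education": [2] * n, "bmi": [25.0] * n,
        "smoking_status": ["current"] * n, "cigarettes_per_day": [20.0] * n,
        "years_smoked": [40.0] * n, "quit_years": [0.0] * n,
        "pack_years": [40.0] * n, "family_history_lc": [0] * n,
        "calendar_year": [2016] * n, "survey_weight": weights,
    }
    from lyfsct.records import COMORBIDITY_FLAGS
    for flag in COMORBIDITY_FLAGS:
        base[flag] = [False] * n
    return pd.DataFrame(base)


def test_population_eligibility_weighted_hand_tally(model_set, monkeypatch):
    """Six-person weighted cohort with hand-assigned benefits."""
    benefits = np.array([20.0, 10.0, 16.2, 5.0, 30.0, 16.1])
    races = ["white", "white", "african_american", "african_american",
             "hispanic_american", "hispanic_american"]
    weights = [2.0, 1.0, 3.0, 1.0, 0.5, 0.5]
    df = _toy_cohort(benefits, races, weights)

    import lyfsct.strategies as strat
    monkeypatch.setattr(strat, "cohort_benefits",
                        lambda df_, s, m, c=None: benefits)
    out = strat.population_eligibility(df, "standard", model_set)
    overall = out[out["group"] == "overall"].iloc[0]
    # eligible: persons 0 (w2), 2 (w3), 4 (w0.5) -> 5.5 of 8 total weight
    assert overall["weighted_eligible"] == pytest.approx(5.5)
    assert overall["pct_eligible"] == pytest.approx(100 * 5.5 / 8.0)
    assert overall["mean_std_days_eligible"] == pytest.approx(
        (2 * 20.0 + 3 * 16.2 + 0.5 * 30.0) / 5.5)
    hisp = out[out["group"] == "hispanic_american"].iloc[0]
    assert hisp["pct_eligible"] == pytest.approx(50.0)


def test_all_eligible_gives_proportion_one(model_set, monkeypatch):
    df = _toy_cohort([20.0] * 4, ["white", "white", "asian_american",
                                  "asian_american"], [1.0] * 4)
    import lyfsct.strategies as strat
    monkeypatch.setattr(strat, "cohort_benefits",
                        lambda df_, s, m, c=None: np.full(4, 20.0))
    out = strat.population_eligibility(df, "standard", model_set)
    assert np.allclose(out["pct_eligible"], 100.0)


def test_newly_eligible_only_in_nonwhite_groups(model_set, small_cohort):
    out = population_eligibility(small_cohort, "counterfactual_acm", model_set)
    white = out[out["group"] == "white"].iloc[0]
    assert white["weighted_newly_eligible"] == 0.0
    assert white["weighted_newly_ineligible"] == 0.0
    assert np.all(out["weighted_newly_ineligible"].to_numpy() == 0.0)


def test_preventable_burden_toy_brute_force(model_set, small_cohort):
    df = small_cohort.head(3)
    out = preventable_burden(df, "standard", model_set)
    from lyfsct.coding import encode_dataframe
    from lyfsct.submodel import cohort_five_year_risks
    cfg = EligibilityConfig()
    days = cohort_benefits(df, "standard", model_set, cfg)
    terms_lc = encode_dataframe(df, "lcdrat")
    terms_acm = encode_dataframe(df, "acm")
    r_ns, _ = cohort_five_year_risks(terms_lc, terms_acm, df["age"].to_numpy(int),
                                     model_set.lcdrat, model_set.acm)
    r_s, _ = cohort_five_year_risks(terms_lc, terms_acm, df["age"].to_numpy(int),
                                    model_set.lcdrat, model_set.acm,
                                    hazard_multiplier=0.796, effect_years=5)
    w = df["survey_weight"].to_numpy()
    eligible = days >= 16.2
    expected_deaths = float(np.sum(w[eligible] * (r_ns - r_s)[eligible]))
    overall = out[out["group"] == "overall"].iloc[0]
    assert overall["preventable_lc_deaths"] == pytest.approx(expected_deaths,
                                                             rel=1e-12)
    if not eligible.any():
        assert overall["gainable_life_years"] == 0.0


def test_preventable_burden_single_person_definitional(model_set):
    df = _toy_cohort([20.0], ["white"], [7.0])
    out = preventable_burden(df, "standard", model_set)
    overall = out[out["group"] == "overall"].iloc[0]
    from lyfsct.coding import encode_dataframe
    from lyfsct.submodel import cohort_five_year_risks
    terms_lc = encode_dataframe(df, "lcdrat")
    terms_acm = encode_dataframe(df, "acm")
    r_ns, _ = cohort_five_year_risks(terms_lc, terms_acm, [60],
                                     model_set.lcdrat, model_set.acm)
    r_s, _ = cohort_five_year_risks(terms_lc, terms_acm, [60],
                                    model_set.lcdrat, model_set.acm,
                                    hazard_multiplier=0.796, effect_years=5)
    d = float(r_ns[0] - r_s[0])
    days = cohort_benefits(df, "standard", model_set)
    if days[0] >= 16.2:
        assert overall["preventable_lc_deaths"] == pytest.approx(7.0 * d, rel=1e-12)
    else:
        assert overall["preventable_lc_deaths"] == 0.0
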