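import dataclasses

import numpy as np
import pandas as pd
import pytest

from lyfsct.coding import reference_record
from lyfsct.records import PersonRecord
from lyfsct.simulate import CohortConfig, generate_covariates
from lyfsct.strategies import ModelSet
from lyfsct.submodel import load_default_submodels


@pytest.fixture(scope="session")
def models() -> dict:
    return load_default_submodels()


@pytest.fixture(scope="session")
def model_set(models) -> ModelSet:
    return ModelSet.from_mapping(models)


@pytest.fixture()
def reference() -> PersonRecord:
    return reference_record()


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return generate_covariates(CohortConfig(n=400, seed=11))


def random_records(rng: np.random.Generator, n: int) -> list[PersonRecord]:
    """Random valid person profiles spanning the covariate space."""
    records = []
    for _ in range(n):
        age = int(rng.integers(50, 81))
        status = "current" if rng.random() < 0.4 else "former"
        start = int(rng.integers(15, 21))
        if status == "current":
            quit_years = 0.0
            years = float(age - start)
        else:
            quit_years = float(rng.uniform(0, min(25, age - start - 3)))
            years = float(age - start - quit_years)
        cpd = float(rng.uniform(3, 50))
        records.append(PersonRecord(
            age=age,
            sex="female" if rng.random() < 0.5 else "male",
            race_ethnicity=str(rng.choice(["african_american", "asian_american",
                                           "hispanic_american", "white"])),
            education=int(rng.integers(1, 7)),
            bmi=float(rng.uniform(17, 42)),
            smoking_status=status,
            cigarettes_per_day=cpd,
            years_smoked=years,
            quit_years=quit_years,
            pack_years=cpd * years / 20.0,
            family_history_lc=int(rng.integers(0, 3)),
            calendar_year=int(rng.integers(2015, 2019)),
            emphysema=bool(rng.random() < 0.05),
            diabetes=bool(rng.random() < 0.15),
            hypertension=bool(rng.random() < 0.4),
        ))
    return records


def perturb(record: PersonRecord, **changes) -> PersonRecord:
    return dataclasses.replace(record, **changes)
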