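"""Shared fixtures: a small synthetic breast-cancer-style risk model.

All fixtures are generated programmatically; rates are in the ballpark of
age-specific cancer incidence and all-cause competing mortality for a
female population aged 40-80.
"""

from __future__ import annotations

import numpy as np
import pytest

import absrisk as ar

AGE_LO, AGE_HI = 40, 80


def make_rate_tables() -> tuple[ar.AgeRateTable, ar.AgeRateTable]:
    ages = np.arange(AGE_LO, AGE_HI + 1)
    # incidence rising from ~1/1000 to ~4/1000 per year; mortality ~exponential
    incidence = 0.001 + 0.003 * (ages - AGE_LO) / (AGE_HI - AGE_LO)
    mortality = 0.002 * np.exp(0.07 * (ages - AGE_LO))
    return ar.AgeRateTable(ages, incidence), ar.AgeRateTable(ages, mortality)


def make_schema() -> list[ar.Covariate]:
    return [
        ar.Covariate("bmi", "numeric"),
        ar.Covariate("alcohol", "numeric"),
        ar.Covariate("parity", "categorical", ("nulliparous", "1-2", "3+")),
    ]


DISTRIBUTIONS = {
    "bmi": ar.NormalDist(0.0, 1.0),  # standardized BMI
    "alcohol": ar.UniformDist(0.0, 2.0),  # drinks/day
    "parity": ar.CategoricalDist((0.2, 0.5, 0.3)),
}

FORMULA = "bmi + alcohol + parity"
BETA = {
    "bmi": 0.18,
    "alcohol": 0.25,
    "parity[1-2]": -0.15,
    "parity[3+]": -0.30,
}


def make_model(n_reference: int = 2000, seed: int = 2024) -> ar.ModelSpec:
    incidence, mortality = make_rate_tables()
    reference = ar.generate_reference(make_schema(), n_reference, DISTRIBUTIONS, seed)
    return ar.ModelSpec(FORMULA, dict(BETA), reference, incidence, mortality)


@pytest.fixture(scope="session")
def model() -> ar.ModelSpec:
    return make_model()


@pytest.fixture(scope="session")
def baseline(model) -> ar.AgeRateTable:
    return ar.estimate_baseline(model.incidence, model.reference_design(), model.beta)


@pytest.fixture()
def rate_tables():
    return make_rate_tables()


@pytest.fixture()
def schema():
    return make_schema()
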