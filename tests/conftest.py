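import numpy as np
import pytest

from immunoclock import (
    GeneratorParams,
    fit_lms,
    fit_lqr,
    fit_nqr,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_params():
    return GeneratorParams()


@pytest.fixture(scope="session")
def ws_params():
    """Well-specified configuration: Gaussian logit-scale noise (skew 0)."""
    return GeneratorParams(skew=0.0)


@pytest.fixture(scope="session")
def cohort1600(default_params):
    return generate_cohort(1600, default_params, seed=11)


@pytest.fixture(scope="session")
def ws_cohort1600(ws_params):
    return generate_cohort(1600, ws_params, seed=7)


@pytest.fixture(scope="session")
def fitted_models(cohort1600):
    age = cohort1600["age_years"].to_numpy()
    y = cohort1600["immax"].to_numpy()
    return {
        "LMS": fit_lms(age, y),
        "LQR": fit_lqr(age, y),
        "NQR": fit_nqr(age, y),
    }


@pytest.fixture(scope="session")
def ws_lms(ws_cohort1600):
    return fit_lms(ws_cohort1600["age_years"].to_numpy(),
                   ws_cohort1600["immax"].to_numpy())
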