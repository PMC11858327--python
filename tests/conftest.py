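import numpy as np
import pytest

from glimcrp import CohortSpec, generate_cohort
from glimcrp.pipeline import prepare_cohort


def make_spec(**overrides) -> CohortSpec:
    """Default spec with keyword overrides (nested models accepted as dicts)."""
    return CohortSpec(**{"n_patients": 2000, "seed": 0, **overrides})


def null_outcome_model() -> dict:
    """All slopes zero: outcomes independent of CRP, BMI and age."""
    coeffs = {"beta_maxcrp": 0.0, "beta_lowbmi": 0.0, "beta_age": 0.0}
    return {
        "death": {"intercept": -2.0, **coeffs},
        "bi_lt_60": {"intercept": -0.5, **coeffs},
        "los_ge_14": {"intercept": 0.5, **coeffs},
    }


@pytest.fixture(scope="session")
def analysed_cohort():
    """A prepared (screened + featurised + outcomes) default cohort."""
    raw = generate_cohort(make_spec(n_patients=4000, seed=11))
    return prepare_cohort(raw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
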