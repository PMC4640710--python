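import pytest

from helpers import make_panel
from proxrisk.cohort import generate_cohort
from proxrisk.config import default_config


@pytest.fixture(scope="session")
def default_panel():
    """One paper-calibrated simulated cohort, shared across read-only tests."""
    return generate_cohort(default_config(seed=7))


@pytest.fixture(scope="session")
def small_panel():
    """A smaller simulated cohort for the costlier model fits."""
    return generate_cohort(default_config(n_subjects=150, n_trusts=8, seed=21))


@pytest.fixture()
def three_subject_panel():
    return make_panel([
        {"subject_id": 1, "trust_id": 1,
         "waves": {"baseline": {"c_insight": 1}, "m6": {"c_insight": 2}, "m12": {}},
         "violence": {"w1": 1, "w2": 0}},
        {"subject_id": 2, "trust_id": 1,
         "waves": {"baseline": {}, "m6": {"s_coping": 2}},
         "violence": {"w1": 0}},
        {"subject_id": 3, "trust_id": 2, "gender": "female",
         "waves": {"baseline": {"h_violence": 2}, "m6": {}, "m12": {"c_instability": 1}},
         "violence": {"w1": 0, "w2": 1}},
    ])
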