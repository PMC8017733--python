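import numpy as np
import pytest

from bsirisk.cohort import PatientRecord
from bsirisk.scores import score_cohort
from bsirisk.synth import simulate_cohort


def make_record(event_id="E1", **overrides) -> PatientRecord:
    """A complete record satisfying no score criterion; override per test."""
    base = dict(
        event_id=event_id, age=50.0, sex="female", temperature=37.0,
        systolic_bp=120.0, respiratory_rate=16.0, heart_rate=80.0,
        wbc=8.0, neutrophils=5.0, lymphocytes=1.5, platelets=250.0,
        creatinine=80.0, lactate=1.0, crp=50.0, bilirubin=10.0,
        chills=False, suspected_endocarditis=False,
        indwelling_vascular_catheter=False, altered_mentation=False,
        sofa_baseline=0, sofa_admission=0,
        culture_outcome="negative", pathogens=[],
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(seed=11)


@pytest.fixture(scope="session")
def default_panels(default_cohort):
    return score_cohort(default_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
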