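from datetime import date

import pytest

from pdmedalgo import classify_cohort, default_codebook
from pdmedalgo.simulate import ScenarioConfig, simulate_cohort


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def mixed_cohort(codebook):
    """A mid-sized mixed synthetic cohort shared by read-only tests."""
    return simulate_cohort(ScenarioConfig(n_patients=800, seed=20), codebook)


@pytest.fixture(scope="session")
def mixed_outcomes(mixed_cohort, codebook):
    table, funnel, outcomes = classify_cohort(mixed_cohort.dataset, codebook)
    return table, funnel, outcomes


def make_patient(pid="P1", sex="male", birth=date(1950, 6, 15), death=None,
                 periods=((date(2000, 1, 1), date(2025, 3, 31)),),
                 **kw):
    from pdmedalgo import PatientRecord
    return PatientRecord(patient_id=pid, sex=sex, birth_date=birth,
                         death_date=death, insurance_periods=periods, **kw)
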