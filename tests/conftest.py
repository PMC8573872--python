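import datetime as dt

import pytest

from aimphenotype.definitions import default_registry
from aimphenotype.events import PatientRecord
from aimphenotype.synthetic import GeneratorConfig, generate_cohort

BIRTH = dt.date(2000, 1, 1)


def day(offset: int) -> dt.date:
    """Date `offset` days after the shared test birth date."""
    return BIRTH + dt.timedelta(days=offset)


def patient(pid: str = "P1", **collections) -> PatientRecord:
    return PatientRecord(patient_id=pid, birth_date=BIRTH, **collections)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient gold-labeled cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_patients=60, seed=11))
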