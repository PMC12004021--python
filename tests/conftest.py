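import datetime as dt
from pathlib import Path

import pytest

from clivd.records import (
    CodeSystem,
    DiagnosisEvent,
    EventStream,
    MeasurementEvent,
    Parameter,
    Patient,
    Sex,
    TextEvent,
)
from clivd.risk import load_model_config
from clivd.synthetic import CohortConfig, generate_cohort

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def model():
    return load_model_config()


@pytest.fixture(scope="session")
def fixture_cohort():
    """1,000-patient synthetic cohort under default (study) conditions."""
    return generate_cohort(CohortConfig(n_patients=1000, seed=11))


@pytest.fixture
def simple_stream():
    """Middle-aged man with a weight measurement and an alcohol diagnosis."""
    return EventStream(
        Patient("P1", Sex.MALE, dt.date(1960, 6, 15)),
        (
            MeasurementEvent(dt.date(2015, 3, 1), Parameter.WEIGHT, 80.0),
            DiagnosisEvent(dt.date(2014, 1, 1), CodeSystem.ICD10, "F10.1"),
            TextEvent(dt.date(2016, 5, 2), "Ei tupakoi."),
        ),
    )


def make_stream(sex=Sex.MALE, birth=dt.date(1960, 6, 15), events=(), pid="P1"):
    return EventStream(Patient(pid, sex, birth), tuple(events))
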