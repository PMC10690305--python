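import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from backtraj.cohort import Cohort


def _m(pid, var, t, v, source="lab"):
    return {"patient_id": pid, "variable": var, "time_h": t, "value": v, "source": source}


@pytest.fixture
def toy_cohort() -> Cohort:
    """Six patients covering crossing-before-DHC, crossing-after-DHC,
    death-first, discharge-first, late discharge, and a crossing beyond
    the 192 h horizon."""
    patients = pd.DataFrame(
        {
            "patient_id": ["A", "B", "C", "D", "E", "F"],
            "death_h": [np.nan, np.nan, 50.0, np.nan, np.nan, np.nan],
            "discharge_h": [100.0, np.nan, np.nan, 100.0, 250.0, 250.0],
        }
    )
    measurements = pd.DataFrame(
        [
            _m("A", "mls", 10.0, 2.0, "imaging"),
            _m("A", "mls", 40.0, 6.0, "imaging"),
            _m("B", "mls", 20.0, 3.0, "imaging"),
            _m("B", "mls", 40.0, 6.0, "imaging"),
            _m("C", "mls", 10.0, 2.0, "imaging"),
            _m("D", "mls", 10.0, 1.0, "imaging"),
            _m("E", "mls", 10.0, 1.0, "imaging"),
            _m("F", "mls", 200.0, 7.0, "imaging"),
        ]
    )
    procedures = pd.DataFrame(
        [{"patient_id": "B", "procedure": "dhc", "time_h": 30.0}]
    )
    return Cohort(patients, measurements, procedures).validate()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231120)
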