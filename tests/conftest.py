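import pandas as pd
import pytest

from precohort.synthetic import SimConfig, make_toy_patient, simulate_population


@pytest.fixture(scope="session")
def four_test_patient():
    """Diagnosed 2013-01-01; HbA1c tests at days 0/120/400/500 relative to
    2013-06-01 with values 8.1 / 6.5 / 7.5 / 7.8.

    Hand enumeration of the window rule gives exactly two decision points:
    (index day 0 -> outcome day 120, controlled) and (index day 400 ->
    outcome day 500, uncontrolled).  Day 120 is no index (value < 7) and
    day 500 has no follow-up test.
    """
    base = pd.Timestamp("2013-06-01")
    events = [
        {
            "table": "measurements",
            "date": base + pd.Timedelta(days=day),
            "nhg_code": "817",
            "description": "HbA1c",
            "value": value,
        }
        for day, value in [(0, 8.1), (120, 6.5), (400, 7.5), (500, 7.8)]
    ]
    return make_toy_patient(events, diagnosis_date="2013-01-01")


@pytest.fixture(scope="session")
def small_population():
    """A 300-patient simulated population shared across read-only tests."""
    tables, truth = simulate_population(SimConfig(n_patients=300, seed=7))
    return tables, truth
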