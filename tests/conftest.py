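import pandas as pd
import pytest

from gpcomplexity import reference, synthetic


@pytest.fixture(scope="session")
def toy_registry():
    return reference.toy_registry()


@pytest.fixture(scope="session")
def small_config():
    return reference.reference_simulation_config(
        seed=42, n_practices=10, patients_per_practice=60, consult_rate_per_year=4.0
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """~2 400 consultations with planted truth across all reference factors."""
    return synthetic.simulate_dataset(small_config)


def consultations_frame(rows):
    """rows: (consultation_id, patient_id, date, duration_minutes)."""
    df = pd.DataFrame(
        rows, columns=["consultation_id", "patient_id", "date", "duration_minutes"]
    )
    df["date"] = pd.to_datetime(df["date"])
    return df


def events_frame(rows):
    """rows: (event_id, patient_id, consultation_id or None, date, code)."""
    df = pd.DataFrame(
        rows, columns=["event_id", "patient_id", "consultation_id", "date", "code"]
    )
    df["date"] = pd.to_datetime(df["date"])
    df["consultation_id"] = df["consultation_id"].astype("Int64")
    return df


def prescriptions_frame(rows):
    """rows: (rx_id, patient_id, consultation_id or None, date, substance_id)."""
    df = pd.DataFrame(
        rows,
        columns=["rx_id", "patient_id", "consultation_id", "date", "substance_id"],
    )
    df["date"] = pd.to_datetime(df["date"])
    df["consultation_id"] = df["consultation_id"].astype("Int64")
    return df
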