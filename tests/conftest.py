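import pandas as pd
import pytest


def day(offset: int, base: str = "2000-01-01") -> pd.Timestamp:
    """Toy calendar: day 0 is 2000-01-01."""
    return pd.Timestamp(base) + pd.Timedelta(days=offset)


def rx_frame(rows):
    """rows: (person_id, drug_code, day offset, days_supplied)."""
    return pd.DataFrame(
        [(p, c, day(d), n) for p, c, d, n in rows],
        columns=["person_id", "drug_code", "dispense_date", "days_supplied"],
    )


def follow_up_frame(rows):
    """rows: (person_id, entry offset, exit offset[, cause])."""
    return pd.DataFrame(
        [(r[0], day(r[1]), day(r[2]), r[3] if len(r) > 3 else "admin_end") for r in rows],
        columns=["person_id", "entry", "exit", "exit_cause"],
    )


@pytest.fixture
def toy_persons():
    return pd.DataFrame(
        {
            "person_id": ["P1", "P2"],
            "sex": ["F", "M"],
            "birth_date": [pd.Timestamp("1935-01-01"), pd.Timestamp("1938-06-15")],
            "diagnosis_date": [pd.Timestamp("1990-05-01"), pd.Timestamp("2010-03-15")],
            "death_date": [pd.Timestamp("2010-01-01"), pd.NaT],
            "emigration_date": [pd.NaT, pd.NaT],
        }
    )
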