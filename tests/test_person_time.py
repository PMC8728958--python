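"""Follow-up derivation, age-band splitting and person-time tabulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from claimlife.person_time import (
    AGE_BANDS,
    DAYS_PER_YEAR,
    add_years,
    apply_surgery_censoring,
    compute_follow_ups,
    follow_up_interval,
    split_by_age_bands,
    tabulate,
)

from conftest import follow_up_frame

STUDY = (pd.Timestamp("1997-07-01"), pd.Timestamp("2017-06-30"))


def person(**kw):
    base = {
        "person_id": "P1",
        "birth_date": pd.Timestamp("1935-01-01"),
        "diagnosis_date": pd.Timestamp("1990-05-01"),
        "death_date": None,
        "emigration_date": None,
    }
    base.update(kw)
    return base


def test_entry_at_65th_birthday_exit_at_death():
    fu = follow_up_interval(person(death_date=pd.Timestamp("2010-01-01")), *STUDY)
    assert fu.entry == pd.Timestamp("2000-01-01")
    assert fu.exit == pd.Timestamp("2010-01-01")
    assert fu.exit_cause == "death"


def test_late_diagnosis_enters_at_diagnosis_and_ends_administratively():
    fu = follow_up_interval(
        person(birth_date=pd.Timestamp("1938-03-15"), diagnosis_date=pd.Timestamp("2010-03-15")),
        *STUDY,
    )
    assert fu.entry == pd.Timestamp("2010-03-15")
    assert fu.exit == STUDY[1]
    assert fu.exit_cause == "admin_end"


def test_death_before_65th_birthday_is_excluded():
    fu = follow_up_interval(
        person(birth_date=pd.Timestamp("1950-01-01"), death_date=pd.Timestamp("2010-01-01")),
        *STUDY,
    )
    assert fu is None


def test_emigration_binds_when_earliest():
    fu = follow_up_interval(person(emigration_date=pd.Timestamp("2005-05-05")), *STUDY)
    assert fu.exit == pd.Timestamp("2005-05-05") and fu.exit_cause == "emigration"


def test_missing_birth_date_raises():
    with pytest.raises(ValueError, match="birth date"):
        follow_up_interval(person(birth_date=None), *STUDY)


def test_compute_follow_ups_matches_scalar_version(toy_persons):
    fus = compute_follow_ups(toy_persons, *STUDY)
    for _, row in fus.iterrows():
        p = toy_persons[toy_persons["person_id"] == row["person_id"]].iloc[0].to_dict()
        scalar = follow_up_interval(p, *STUDY)
        assert (scalar.entry, scalar.exit, scalar.exit_cause) == (
            row["entry"], row["exit"], row["exit_cause"]
        )


def test_add_years_handles_leap_day():
    assert add_years([pd.Timestamp("1936-02-29")], 65)[0] == pd.Timestamp("2001-02-28")
    assert add_years([pd.Timestamp("1936-02-29")], 64)[0] == pd.Timestamp("2000-02-29")


def test_split_by_age_bands_conserves_days():
    birth = pd.Timestamp("1940-01-01")
    start, end = pd.Timestamp("2008-01-01"), pd.Timestamp("2012-01-01")  # ages 68..72
    parts = split_by_age_bands(start, end, birth)
    assert [p[0] for p in parts] == ["65-69", "70-74"]
    total = sum((e - s).days for _, s, e in parts)
    assert total == (end - start).days
    years = [(e - s).days / DAYS_PER_YEAR for _, s, e in parts]
    assert years[0] == pytest.approx(2.0, abs=0.01)
    assert years[1] == pytest.approx(2.0, abs=0.01)


def test_split_entirely_in_open_band_and_zero_length():
    birth = pd.Timestamp("1920-01-01")
    parts = split_by_age_bands(pd.Timestamp("2012-01-01"), pd.Timestamp("2014-01-01"), birth)
    assert [p[0] for p in parts] == ["90+"]
    assert split_by_age_bands(pd.Timestamp("2012-01-01"), pd.Timestamp("2012-01-01"), birth) == []


@settings(derandomize=True, max_examples=100)
@given(st.integers(0, 12000), st.integers(0, 12000))
def test_split_conservation_property(a, b):
    """Band sub-lengths always sum to the interval length, any interval."""
    birth = pd.Timestamp("1936-02-29")
    b65 = pd.Timestamp("2001-02-28")
    lo, hi = min(a, b), max(a, b)
    start, end = b65 + pd.Timedelta(days=lo), b65 + pd.Timedelta(days=hi)
    parts = split_by_age_bands(start, end, birth)
    assert sum((e - s).days for _, s, e in parts) == hi - lo


def _one_person_setup(death=None):
    persons = pd.DataFrame(
        {
            "person_id": ["P1"],
            "sex": ["F"],
            "birth_date": [pd.Timestamp("1940-01-01")],
            "diagnosis_date": [pd.Timestamp("1990-01-01")],
            "death_date": [death],
            "emigration_date": [pd.NaT],
        }
    )
    return persons


def test_tabulate_single_person_bookkeeping():
    """Continuous mesalamine from 65.0, death at ~67.5: one 65-69 cell with
    the full person-time and the death."""
    persons = _one_person_setup(death=pd.Timestamp("2007-07-02"))
    fu = pd.DataFrame(
        {
            "person_id": ["P1"],
            "entry": [pd.Timestamp("2005-01-01")],
            "exit": [pd.Timestamp("2007-07-02")],
            "exit_cause": ["death"],
        }
    )
    exposure = pd.DataFrame(
        {
            "person_id": ["P1"],
            "group": ["mesalamine"],
            "start": [pd.Timestamp("2005-01-01")],
            "end": [pd.Timestamp("2007-07-02")],
        }
    )
    cells = tabulate(exposure, fu, persons)
    cell = cells.set_index(["group", "sex", "age_band"]).loc[("mesalamine", "F", "65-69")]
    expected_py = (pd.Timestamp("2007-07-02") - pd.Timestamp("2005-01-01")).days / DAYS_PER_YEAR
    assert cell["person_years"] == pytest.approx(expected_py)
    assert expected_py == pytest.approx(2.5, abs=0.01)
    assert cell["deaths"] == 1
    assert cells["deaths"].sum() == 1


def test_death_on_two_simultaneous_groups_counts_in_each():
    persons = _one_person_setup(death=pd.Timestamp("2006-01-01"))
    fu = pd.DataFrame(
        {
            "person_id": ["P1"],
            "entry": [pd.Timestamp("2005-01-01")],
            "exit": [pd.Timestamp("2006-01-01")],
            "exit_cause": ["death"],
        }
    )
    exposure = pd.DataFrame(
        {
            "person_id": ["P1", "P1"],
            "group": ["mesalamine", "steroid"],
            "start": [pd.Timestamp("2005-01-01")] * 2,
            "end": [pd.Timestamp("2006-01-01")] * 2,
        }
    )
    cells = tabulate(exposure, fu, persons).set_index(["group", "sex", "age_band"])
    assert cells.loc[("mesalamine", "F", "65-69"), "deaths"] == 1
    assert cells.loc[("steroid", "F", "65-69"), "deaths"] == 1


def test_no_deaths_when_exit_is_administrative():
    persons = _one_person_setup()
    fu = pd.DataFrame(
        {
            "person_id": ["P1"],
            "entry": [pd.Timestamp("2005-01-01")],
            "exit": [pd.Timestamp("2007-01-01")],
            "exit_cause": ["admin_end"],
        }
    )
    exposure = pd.DataFrame(
        {
            "person_id": ["P1"],
            "group": ["no_therapy"],
            "start": [pd.Timestamp("2005-01-01")],
            "end": [pd.Timestamp("2007-01-01")],
        }
    )
    cells = tabulate(exposure, fu, persons)
    assert cells["deaths"].sum() == 0


def test_tabulate_rejects_exposure_outside_follow_up():
    persons = _one_person_setup()
    fu = pd.DataFrame(
        {
            "person_id": ["P1"],
            "entry": [pd.Timestamp("2005-01-01")],
            "exit": [pd.Timestamp("2007-01-01")],
            "exit_cause": ["admin_end"],
        }
    )
    exposure = pd.DataFrame(
        {
            "person_id": ["P1"],
            "group": ["no_therapy"],
            "start": [pd.Timestamp("2004-12-31")],
            "end": [pd.Timestamp("2007-01-01")],
        }
    )
    with pytest.raises(ValueError, match="outside follow-up"):
        tabulate(exposure, fu, persons)


def test_surgery_censoring_rules():
    fu = pd.DataFrame(
        {
            "person_id": ["P1", "P2", "P3"],
            "entry": pd.to_datetime(["2000-01-01"] * 3),
            "exit": pd.to_datetime(["2010-01-01"] * 3),
            "exit_cause": ["death", "death", "admin_end"],
        }
    )
    surgeries = pd.DataFrame(
        {
            "person_id": ["P1", "P2", "P3"],
            "surgery_date": pd.to_datetime(["2012-01-01", "2005-06-01", "1999-12-31"]),
        }
    )
    out = apply_surgery_censoring(fu, surgeries).set_index("person_id")
    # surgery after death: unchanged
    assert out.loc["P1", "exit"] == pd.Timestamp("2010-01-01")
    assert out.loc["P1", "exit_cause"] == "death"
    # surgery mid-follow-up: exit moves, death no longer counted
    assert out.loc["P2", "exit"] == pd.Timestamp("2005-06-01")
    assert out.loc["P2", "exit_cause"] == "surgery"
    # surgery before entry: person removed
    assert "P3" not in out.index


def test_surgery_censoring_without_table_is_identity():
    fu = follow_up_frame([("P1", 0, 100)])
    assert apply_surgery_censoring(fu, None).equals(fu)
    assert apply_surgery_censoring(fu, pd.DataFrame(columns=["person_id", "surgery_date"])).equals(fu)
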