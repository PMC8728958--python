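"""Exposure-episode construction, grace windows, group assignment and
subtype classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from claimlife import intervals as iv
from claimlife.exposure import (
    DEFAULT_DRUG_MAP,
    DrugClassMap,
    assign_exposure_intervals,
    build_drug_episodes,
    classify_subtype,
    derive_combination,
    to_day_numbers,
)

from conftest import day, follow_up_frame, rx_frame


def episodes_as_days(cov: pd.DataFrame, drug_class: str):
    sel = cov[cov["drug_class"] == drug_class]
    s = to_day_numbers(sel["start"]) - to_day_numbers([day(0)])[0]
    e = to_day_numbers(sel["end"]) - to_day_numbers([day(0)])[0]
    return sorted(zip(s.tolist(), e.tolist()))


@pytest.mark.parametrize(
    "code,supply,second_day,expected",
    [
        # 30-day window for non-biologics: gap 25 bridges, 31 splits
        ("MES001", 30, 55, [(0, 85)]),
        ("MES001", 30, 60, [(0, 90)]),      # gap exactly 30 still bridges
        ("MES001", 30, 61, [(0, 30), (61, 91)]),
        # 84-day window for 8-weekly biologics: 56+84 merges, 56+85 splits
        ("IFX001", 56, 140, [(0, 196)]),
        ("IFX001", 56, 141, [(0, 56), (141, 197)]),
        # 42-day window for other biologics
        ("ADA001", 28, 70, [(0, 98)]),
        ("ADA001", 28, 71, [(0, 28), (71, 99)]),
    ],
)
def test_grace_window_boundaries(code, supply, second_day, expected):
    rx = rx_frame([("P1", code, 0, supply), ("P1", code, second_day, supply)])
    cov = build_drug_episodes(rx, DEFAULT_DRUG_MAP)
    cls = DEFAULT_DRUG_MAP.drug_class(code)
    assert episodes_as_days(cov, cls) == expected


def test_episodes_merge_within_code_then_union_across_codes():
    # two mesalamine products 40 days apart: neither code bridges the gap on
    # its own coverage, and the class union keeps them as separate intervals
    rx = rx_frame([("P1", "MES001", 0, 30), ("P1", "MES002", 70, 30)])
    cov = build_drug_episodes(rx)
    assert episodes_as_days(cov, "mesalamine") == [(0, 30), (70, 100)]


def test_unmapped_code_and_bad_days_supplied_raise():
    with pytest.raises(ValueError, match="XXX999"):
        build_drug_episodes(rx_frame([("P1", "XXX999", 0, 30)]))
    with pytest.raises(ValueError, match="days_supplied"):
        build_drug_episodes(rx_frame([("P1", "MES001", 0, 0)]))


def test_merge_idempotence_on_episode_output():
    """Re-feeding episodes as exact-coverage dispensings reproduces them."""
    rx = rx_frame(
        [("P1", "MES001", 0, 30), ("P1", "MES001", 55, 30), ("P1", "MES001", 120, 10)]
    )
    cov = build_drug_episodes(rx)
    back = pd.DataFrame(
        {
            "person_id": cov["person_id"],
            "drug_code": "MES001",
            "dispense_date": cov["start"],
            "days_supplied": (
                to_day_numbers(cov["end"]) - to_day_numbers(cov["start"])
            ),
        }
    )
    again = build_drug_episodes(back)
    assert episodes_as_days(again, "mesalamine") == episodes_as_days(cov, "mesalamine")


def test_derive_combination_set_algebra():
    comb, imm_mono, bio_mono = derive_combination([(0, 100)], [(50, 150)])
    assert (comb, imm_mono, bio_mono) == ([(50, 100)], [(0, 50)], [(100, 150)])
    assert derive_combination([(0, 30)], [(60, 90)])[0] == []
    comb, imm_mono, bio_mono = derive_combination([(0, 80)], [(0, 80)])
    assert comb == [(0, 80)] and imm_mono == [] and bio_mono == []


dispensing_lists = st.lists(
    st.tuples(
        st.sampled_from(["MES001", "AZA001", "PRD001", "IFX001", "ADA001"]),
        st.integers(0, 300),
        st.integers(1, 90),
    ),
    max_size=12,
)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(dispensing_lists, st.integers(0, 100), st.integers(150, 500))
def test_partition_and_exclusivity_properties(disp, lo, hi):
    """no_therapy plus the class coverages tile follow-up exactly, and no
    day is both combination and a monotherapy."""
    rx = rx_frame([("P1", c, d, n) for c, d, n in disp])
    fu = follow_up_frame([("P1", lo, hi)])
    cov = build_drug_episodes(rx) if len(rx) else pd.DataFrame(
        columns=["person_id", "drug_class", "start", "end"]
    )
    exp = assign_exposure_intervals(cov, fu)
    base = to_day_numbers([day(0)])[0]
    by_group = {
        g: iv.normalize(
            zip(to_day_numbers(sub["start"]) - base, to_day_numbers(sub["end"]) - base)
        )
        for g, sub in exp.groupby("group")
    }
    fu_days = set(range(lo, hi))

    def days(group):
        return {d for s, e in by_group.get(group, []) for d in range(s, e)}

    all_covered = set().union(*(days(g) for g in by_group))
    assert all_covered == fu_days
    assert days("no_therapy").isdisjoint(
        days("mesalamine") | days("steroid") | days("combination")
        | days("immunomodulator_mono") | days("biologic_mono")
    )
    assert days("combination").isdisjoint(days("immunomodulator_mono"))
    assert days("combination").isdisjoint(days("biologic_mono"))
    # every group stays inside follow-up
    assert all_covered <= fu_days


def test_no_dispensings_yields_single_no_therapy_interval():
    fu = follow_up_frame([("P1", 10, 110)])
    exp = assign_exposure_intervals(
        pd.DataFrame(columns=["person_id", "drug_class", "start", "end"]), fu
    )
    assert list(exp["group"]) == ["no_therapy"]
    assert exp["start"].iloc[0] == day(10) and exp["end"].iloc[0] == day(110)


def test_simultaneous_mesalamine_and_steroid_both_count():
    """Groups other than the mono/combination triple are non-exclusive."""
    rx = rx_frame([("P1", "MES001", 0, 50), ("P1", "PRD001", 20, 10)])
    fu = follow_up_frame([("P1", 0, 50)])
    exp = assign_exposure_intervals(build_drug_episodes(rx), fu)
    got = {(g, (s - day(0)).days, (e - day(0)).days)
           for g, s, e in zip(exp["group"], exp["start"], exp["end"])}
    assert ("mesalamine", 0, 50) in got
    assert ("steroid", 20, 30) in got
    assert not any(g == "no_therapy" for g, _, _ in got)


def test_full_coverage_leaves_no_therapy_empty():
    rx = rx_frame([("P1", "MES001", 0, 200)])
    fu = follow_up_frame([("P1", 20, 120)])
    exp = assign_exposure_intervals(build_drug_episodes(rx), fu)
    assert "no_therapy" not in set(exp["group"])
    # coverage clipped to follow-up
    assert exp["start"].min() == day(20) and exp["end"].max() == day(120)


@pytest.mark.parametrize(
    "labels,expected",
    [
        (["CD"] * 6 + ["UC"] * 3, "CD"),
        (["CD"] * 4 + ["UC"] * 5, "UC"),
        (["UC"] * 4 + ["CD"] * 5, "CD"),
        # ten visits: only the last nine count
        (["UC"] * 5 + ["CD"] * 5, "CD"),
        (["CD"] * 4, "CD"),          # short history, unanimous majority
        (["CD", "UC"] * 2, "unclassified"),  # short history, tie
        ([], "unclassified"),
    ],
)
def test_classify_subtype_rules(labels, expected):
    assert classify_subtype(labels) == expected


def test_classify_subtype_rejects_unknown_labels():
    with pytest.raises(ValueError):
        classify_subtype(["CD", "IBS"])


def test_drug_class_map_validation():
    with pytest.raises(ValueError, match="unknown drug classes"):
        DrugClassMap({"X": "antibiotic"})
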