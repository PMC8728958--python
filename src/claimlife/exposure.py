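"""Medication exposure episodes from dispensing claims.

Dispensing records (drug code, dispense date, days supplied) are turned into
per-person, per-class coverage intervals.  Dispensings of the same drug code
are chained into a single episode when the gap between the end of one
coverage period and the next dispensing does not exceed the class's grace
window -- 30 days for non-biologics (non-adherence allowance), 84 days for
biologics on a typical 8-week schedule (infliximab, ustekinumab,
vedolizumab) and 42 days for other biologics -- with the bridged gap counted
as exposed.  No grace tail is appended after the final dispensing: coverage
ends when the days supplied run out.

Class coverages are combined into the six analysis groups:

* ``combination``            day-level overlap of immunomodulator and
                             biologic coverage,
* ``immunomodulator_mono``   immunomodulator coverage minus combination,
* ``biologic_mono``          biologic coverage minus combination,
* ``mesalamine``/``steroid`` their class coverages as-is (these groups are
                             not mutually exclusive with any other),
* ``no_therapy``             follow-up time with no active coverage from any
                             of the five studied classes.

IBD subtype (Crohn's disease vs ulcerative colitis) is classified from the
last 9 outpatient-visit diagnosis labels.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv

__all__ = [
    "CLASSES",
    "GROUPS",
    "DEFAULT_GRACE_DAYS",
    "DEFAULT_DRUG_MAP",
    "DrugClassMap",
    "build_drug_episodes",
    "derive_combination",
    "assign_exposure_intervals",
    "classify_subtype",
    "classify_subtypes",
]

CLASSES = (
    "immunomodulator",
    "biologic_q8",
    "biologic_other",
    "mesalamine",
    "systemic_steroid",
)
BIOLOGIC_CLASSES = ("biologic_q8", "biologic_other")

#: Analysis groups in conventional reporting order.
GROUPS = (
    "mesalamine",
    "immunomodulator_mono",
    "biologic_mono",
    "combination",
    "steroid",
    "no_therapy",
)

#: Permitted gap (days) between end of coverage and the next dispensing.
DEFAULT_GRACE_DAYS = {
    "immunomodulator": 30,
    "mesalamine": 30,
    "systemic_steroid": 30,
    "biologic_q8": 84,
    "biologic_other": 42,
}

_EPOCH = np.datetime64("1970-01-01", "D")


def to_day_numbers(dates) -> np.ndarray:
    """Calendar dates -> integer days since 1970-01-01."""
    arr = pd.to_datetime(pd.Series(dates)).to_numpy()
    return arr.astype("datetime64[D]").astype(np.int64)


def to_dates(days) -> pd.Series:
    arr = np.asarray(days, dtype=np.int64).view("datetime64[D]")
    return pd.Series(arr.astype("datetime64[ns]"))


@dataclass(frozen=True)
class DrugClassMap:
    """Mapping from drug codes to medication classes plus grace windows.

    Stands in for a jurisdiction's drug-identification-number lists; users
    supply their own ``drug_map.csv`` (columns ``drug_code``, ``class``).
    """

    code_to_class: Mapping[str, str]
    grace_days: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GRACE_DAYS)
    )

    def __post_init__(self) -> None:
        bad = {c for c in self.code_to_class.values() if c not in CLASSES}
        if bad:
            raise ValueError(f"unknown drug classes: {sorted(bad)}")
        for cls in CLASSES:
            if self.grace_days.get(cls, -1) < 0:
                raise ValueError(f"missing or negative grace window for {cls!r}")

    def drug_class(self, code: str) -> str:
        return self.code_to_class[code]

    def grace(self, drug_class: str) -> int:
        return int(self.grace_days[drug_class])

    @classmethod
    def from_csv(cls, path, grace_days: Mapping[str, int] | None = None) -> "DrugClassMap":
        df = pd.read_csv(path, dtype=str)
        missing = {"drug_code", "class"} - set(df.columns)
        if missing:
            raise ValueError(f"drug map {path}: missing columns {sorted(missing)}")
        dup = df["drug_code"][df["drug_code"].duplicated()]
        if len(dup):
            raise ValueError(f"drug map {path}: duplicated codes {sorted(set(dup))}")
        return cls(dict(zip(df["drug_code"], df["class"])), grace_days or dict(DEFAULT_GRACE_DAYS))


#: Synthetic drug codes used by the cohort generator.
DEFAULT_DRUG_MAP = DrugClassMap(
    {
        "MES001": "mesalamine",
        "MES002": "mesalamine",
        "AZA001": "immunomodulator",
        "MP6001": "immunomodulator",
        "MTX001": "immunomodulator",
        "PRD001": "systemic_steroid",
        "PRD002": "systemic_steroid",
        "IFX001": "biologic_q8",
        "UST001": "biologic_q8",
        "VDZ001": "biologic_q8",
        "ADA001": "biologic_other",
        "GOL001": "biologic_other",
    }
)

_COVERAGE_COLUMNS = ["person_id", "drug_class", "start", "end"]


def _merge_runs(df: pd.DataFrame, keys: list[str], grace) -> pd.DataFrame:
    """Vectorised grace-window merge of rows (s, e) within each key group.

    ``grace`` is a scalar or the name of a column constant within each
    group.  Output rows are episodes: start of the first member, running
    max of member ends.
    """
    df = df.sort_values(keys + ["s", "e"], kind="mergesort").reset_index(drop=True)
    g = df[grace] if isinstance(grace, str) else grace
    run_end = df.groupby(keys, sort=False)["e"].cummax()
    prev_end = run_end.groupby([df[k] for k in keys], sort=False).shift(1)
    same_episode = df["s"] <= prev_end + g  # NaN at group heads -> False
    df["_episode"] = (~same_episode.fillna(False)).cumsum()
    agg = df.groupby(keys + ["_episode"], sort=False).agg(s=("s", "min"), e=("e", "max"))
    return agg.reset_index().drop(columns=["_episode"])


def build_drug_episodes(
    prescriptions: pd.DataFrame, drug_map: DrugClassMap = DEFAULT_DRUG_MAP
) -> pd.DataFrame:
    """Per-person, per-class coverage intervals from dispensing records.

    Parameters
    ----------
    prescriptions
        Columns ``person_id``, ``drug_code``, ``dispense_date``,
        ``days_supplied`` (positive integers).
    drug_map
        Drug-code -> class mapping with per-class grace windows.

    Returns
    -------
    DataFrame with columns ``person_id, drug_class, start, end`` where
    ``[start, end)`` are half-open coverage intervals: same-code dispensings
    merged under the class grace window, then unioned across codes of the
    same class.
    """
    if prescriptions.empty:
        return pd.DataFrame(columns=_COVERAGE_COLUMNS)
    rx = prescriptions.copy()
    days = pd.to_numeric(rx["days_supplied"], errors="raise")
    if (days < 1).any():
        bad = rx.loc[days < 1]
        raise ValueError(
            f"days_supplied must be >= 1; offending rows at index {list(bad.index[:5])}"
        )
    unmapped = sorted(set(rx["drug_code"]) - set(drug_map.code_to_class))
    if unmapped:
        raise ValueError(f"unmapped drug codes: {unmapped}")
    rx["drug_class"] = rx["drug_code"].map(drug_map.code_to_class)
    rx["s"] = to_day_numbers(rx["dispense_date"])
    rx["e"] = rx["s"] + days.astype(np.int64)
    rx["grace"] = rx["drug_class"].map(drug_map.grace_days).astype(np.int64)

    # per drug code: chain dispensings under the class grace window
    episodes = _merge_runs(
        rx[["person_id", "drug_code", "drug_class", "grace", "s", "e"]],
        ["person_id", "drug_code", "drug_class"],
        "grace",
    )
    # per class: plain union of that class's per-code episodes
    coverage = _merge_runs(episodes[["person_id", "drug_class", "s", "e"]],
                           ["person_id", "drug_class"], 0)
    out = coverage[["person_id", "drug_class"]].copy()
    out["start"] = to_dates(coverage["s"]).to_numpy()
    out["end"] = to_dates(coverage["e"]).to_numpy()
    return out.sort_values(["person_id", "drug_class", "start"]).reset_index(drop=True)


def derive_combination(
    imm_coverage: Iterable[iv.Interval], bio_coverage: Iterable[iv.Interval]
) -> tuple[iv.IntervalList, iv.IntervalList, iv.IntervalList]:
    """Split immunomodulator and biologic coverage into combination therapy
    and the two monotherapies.

    Combination therapy is operationalised as the day-level overlap of the
    grace-bridged class coverages; monotherapy is the remainder of each
    class.  No calendar day can belong to both combination and a
    monotherapy group.
    """
    imm = iv.normalize(imm_coverage)
    bio = iv.normalize(bio_coverage)
    comb = iv.intersect(imm, bio)
    return comb, iv.subtract(imm, comb), iv.subtract(bio, comb)


def _coverage_by_person(coverage: pd.DataFrame) -> dict:
    out: dict = defaultdict(lambda: defaultdict(list))
    if coverage.empty:
        return out
    s = to_day_numbers(coverage["start"])
    e = to_day_numbers(coverage["end"])
    for pid, cls, a, b in zip(coverage["person_id"], coverage["drug_class"], s, e):
        out[pid][cls].append((int(a), int(b)))
    return out


def assign_exposure_intervals(
    coverage: pd.DataFrame, follow_ups: pd.DataFrame
) -> pd.DataFrame:
    """Assign each person's follow-up to the six analysis groups.

    Parameters
    ----------
    coverage
        Output of :func:`build_drug_episodes`.
    follow_ups
        Columns ``person_id, entry, exit`` (half-open follow-up window).

    Returns
    -------
    DataFrame ``person_id, group, start, end``.  Mesalamine and steroid
    intervals are class coverage clipped to follow-up (overlap with any
    other group permitted); immunomodulator/biologic coverage is split by
    :func:`derive_combination`; ``no_therapy`` is the exact complement of
    all five class coverages within follow-up, so per person the groups
    reconstruct the follow-up window.
    """
    cov = _coverage_by_person(coverage)
    entries = to_day_numbers(follow_ups["entry"])
    exits = to_day_numbers(follow_ups["exit"])
    rows: list[tuple] = []

    def emit(pid, group, ivs):
        for s, e in ivs:
            rows.append((pid, group, s, e))

    for pid, lo, hi in zip(follow_ups["person_id"], entries, exits):
        lo, hi = int(lo), int(hi)
        c = cov.get(pid, {})
        mes = iv.clip(c.get("mesalamine", []), lo, hi)
        ster = iv.clip(c.get("systemic_steroid", []), lo, hi)
        imm = iv.clip(c.get("immunomodulator", []), lo, hi)
        bio = iv.clip(
            iv.union(c.get("biologic_q8", []), c.get("biologic_other", [])), lo, hi
        )
        comb, imm_mono, bio_mono = derive_combination(imm, bio)
        covered = iv.union(iv.union(imm, bio), iv.union(mes, ster))
        no_tx = iv.subtract([(lo, hi)], covered)
        emit(pid, "mesalamine", mes)
        emit(pid, "immunomodulator_mono", imm_mono)
        emit(pid, "biologic_mono", bio_mono)
        emit(pid, "combination", comb)
        emit(pid, "steroid", ster)
        emit(pid, "no_therapy", no_tx)

    out = pd.DataFrame(rows, columns=["person_id", "group", "s", "e"])
    if out.empty:
        return pd.DataFrame(columns=["person_id", "group", "start", "end"])
    res = out[["person_id", "group"]].copy()
    res["start"] = to_dates(out["s"]).to_numpy()
    res["end"] = to_dates(out["e"]).to_numpy()
    return res


def classify_subtype(dx_by_date: Sequence[str]) -> str:
    """Classify IBD subtype from outpatient-visit diagnosis labels.

    ``dx_by_date`` are CD/UC labels in visit-date order.  With at least nine
    visits the call uses the last nine: CD when five or more are CD, UC when
    five or more are UC.  With fewer than nine visits (where the nine-visit
    rule is undefined) a simple majority of the available visits is used and
    ties are left unclassified.
    """
    labels = [d for d in dx_by_date]
    if not labels:
        return "unclassified"
    bad = set(labels) - {"CD", "UC"}
    if bad:
        raise ValueError(f"unknown diagnosis labels: {sorted(bad)}")
    window = labels[-9:]
    counts = Counter(window)
    if len(labels) >= 9:
        if counts["CD"] >= 5:
            return "CD"
        if counts["UC"] >= 5:
            return "UC"
        return "unclassified"
    if counts["CD"] > counts["UC"]:
        return "CD"
    if counts["UC"] > counts["CD"]:
        return "UC"
    return "unclassified"


def classify_subtypes(visits: pd.DataFrame) -> pd.Series:
    """Per-person subtype from a visits table (person_id, visit_date, dx)."""
    if visits.empty:
        return pd.Series(dtype=object, name="subtype")
    v = visits.sort_values(["person_id", "visit_date"], kind="mergesort")
    return (
        v.groupby("person_id", sort=True)["dx"]
        .apply(lambda s: classify_subtype(list(s)))
        .rename("subtype")
    )
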