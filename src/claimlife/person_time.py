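"""Follow-up windows, age-band splitting and person-time tabulation.

Follow-up runs from the latest of the 65th birthday, the IBD diagnosis date
and the study start, until the earliest of death, emigration and the study
end (optionally truncated at first surgery in the sensitivity analysis).
Exposure intervals are split at the 70th/75th/80th/85th/90th birthdays into
the abridged-table age bands and aggregated into person-years and death
counts per (medication group x sex x age band).

Conventions: all intervals are half-open ``[start, end)`` at day
resolution; person-years are days / 365.25; a death is attributed to every
group whose exposure interval covers the death date, where an interval
ending exactly on the death date still counts (a death on the last covered
day belongs to the therapy).  Because the groups are not mutually
exclusive, one death may appear in several groups' cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .exposure import to_day_numbers, to_dates

__all__ = [
    "AGE_BANDS",
    "BAND_START_AGES",
    "DAYS_PER_YEAR",
    "FollowUp",
    "add_years",
    "follow_up_interval",
    "compute_follow_ups",
    "apply_surgery_censoring",
    "split_by_age_bands",
    "tabulate",
]

AGE_BANDS = ("65-69", "70-74", "75-79", "80-84", "85-89", "90+")
BAND_START_AGES = (65, 70, 75, 80, 85, 90)
DAYS_PER_YEAR = 365.25

_EXIT_CAUSES = ("death", "emigration", "admin_end", "surgery")


def add_years(dates, years: int) -> pd.Series:
    """Calendar anniversary: same month/day ``years`` later, with Feb 29
    falling back to Feb 28 in non-leap years."""
    dt = pd.DatetimeIndex(pd.Series(dates))
    y = dt.year.to_numpy() + years
    m = dt.month.to_numpy()
    d = dt.day.to_numpy()
    leap = (y % 4 == 0) & ((y % 100 != 0) | (y % 400 == 0))
    d = np.where((m == 2) & (d == 29) & ~leap, 28, d)
    return pd.to_datetime(pd.DataFrame({"year": y, "month": m, "day": d}))


def _band_cut_days(birth_dates) -> np.ndarray:
    """(n, 6) integer-day matrix of the 65th..90th birthdays."""
    cuts = [to_day_numbers(add_years(birth_dates, a)) for a in BAND_START_AGES]
    return np.stack(cuts, axis=1)


@dataclass(frozen=True)
class FollowUp:
    person_id: str
    entry: pd.Timestamp
    exit: pd.Timestamp
    exit_cause: str


def follow_up_interval(
    person: Mapping, study_start, study_end
) -> Optional[FollowUp]:
    """Follow-up window for one person record, or ``None`` if the person
    contributes no eligible time.

    Entry is the latest of the 65th birthday, diagnosis date and study
    start; exit the earliest of death, emigration and study end.  On ties,
    death takes precedence over emigration over administrative end.
    """
    birth = person.get("birth_date")
    if birth is None or pd.isna(birth):
        raise ValueError(f"person {person.get('person_id')}: missing birth date")
    birth = pd.Timestamp(birth)
    b65 = add_years([birth], 65)[0]
    entry = max(b65, pd.Timestamp(person["diagnosis_date"]), pd.Timestamp(study_start))
    death = person.get("death_date")
    emig = person.get("emigration_date")
    candidates = [
        (pd.Timestamp(death) if death is not None and not pd.isna(death) else pd.Timestamp.max, "death"),
        (pd.Timestamp(emig) if emig is not None and not pd.isna(emig) else pd.Timestamp.max, "emigration"),
        (pd.Timestamp(study_end), "admin_end"),
    ]
    exit_date, cause = min(candidates, key=lambda t: t[0])
    if entry >= exit_date:
        return None
    return FollowUp(str(person["person_id"]), entry, exit_date, cause)


def compute_follow_ups(persons: pd.DataFrame, study_start, study_end) -> pd.DataFrame:
    """Vectorised follow-up computation for a persons table.

    Returns columns ``person_id, entry, exit, exit_cause``; persons with no
    eligible time are dropped.
    """
    cols = ["person_id", "entry", "exit", "exit_cause"]
    if persons.empty:
        return pd.DataFrame(columns=cols)
    if persons["birth_date"].isna().any():
        bad = persons.loc[persons["birth_date"].isna(), "person_id"].tolist()[:5]
        raise ValueError(f"missing birth date for persons {bad}")
    b65 = pd.Series(add_years(persons["birth_date"], 65).to_numpy())
    diag = pd.to_datetime(persons["diagnosis_date"]).reset_index(drop=True)
    start = pd.Timestamp(study_start)
    entry = pd.concat([b65, diag], axis=1).max(axis=1).clip(lower=start)

    far = pd.Timestamp.max.normalize()
    death = pd.to_datetime(persons["death_date"]).fillna(far).reset_index(drop=True)
    emig = pd.to_datetime(persons["emigration_date"]).fillna(far).reset_index(drop=True)
    end = pd.Series([pd.Timestamp(study_end)] * len(persons))
    exit_date = pd.concat([death, emig, end], axis=1).min(axis=1)
    cause = np.where(
        death == exit_date, "death", np.where(emig == exit_date, "emigration", "admin_end")
    )
    out = pd.DataFrame(
        {
            "person_id": persons["person_id"].reset_index(drop=True),
            "entry": entry,
            "exit": exit_date,
            "exit_cause": cause,
        }
    )
    return out[out["entry"] < out["exit"]].reset_index(drop=True)


def apply_surgery_censoring(
    follow_ups: pd.DataFrame, surgeries: Optional[pd.DataFrame]
) -> pd.DataFrame:
    """Truncate follow-up at the first surgery date.

    Exit moves to the surgery date when it is strictly earlier than the
    current exit (the cause becomes ``surgery``); persons whose first
    surgery predates entry are removed.  With no surgeries table this is
    the identity transform.
    """
    if surgeries is None or len(surgeries) == 0 or follow_ups.empty:
        return follow_ups.copy()
    first = (
        surgeries.assign(surgery_date=pd.to_datetime(surgeries["surgery_date"]))
        .groupby("person_id", sort=False)["surgery_date"]
        .min()
    )
    out = follow_ups.copy()
    surg = out["person_id"].map(first)
    binds = surg.notna() & (surg < out["exit"])
    out.loc[binds, "exit"] = surg[binds]
    out.loc[binds, "exit_cause"] = "surgery"
    return out[out["entry"] < out["exit"]].reset_index(drop=True)


def split_by_age_bands(start, end, birth_date) -> list[tuple[str, pd.Timestamp, pd.Timestamp]]:
    """Split one half-open interval at the 70th..90th birthdays.

    Returns ``(band, sub_start, sub_end)`` tuples whose day lengths sum
    exactly to the input length.  A zero-length interval yields nothing.
    """
    s, e = int(to_day_numbers([start])[0]), int(to_day_numbers([end])[0])
    cuts = _band_cut_days(pd.Series([pd.Timestamp(birth_date)]))[0]
    if s < cuts[0]:
        raise ValueError("interval starts before the 65th birthday")
    out = []
    for k, band in enumerate(AGE_BANDS):
        lo = max(s, int(cuts[k]))
        hi = e if k == len(AGE_BANDS) - 1 else min(e, int(cuts[k + 1]))
        if hi > lo:
            out.append((band, to_dates([lo])[0], to_dates([hi])[0]))
    return out


def tabulate(
    exposure: pd.DataFrame, follow_ups: pd.DataFrame, persons: pd.DataFrame
) -> pd.DataFrame:
    """Person-years and deaths per (group, sex, age band).

    ``exposure`` must already be clipped to follow-up (contract of
    :func:`claimlife.exposure.assign_exposure_intervals`); a violation
    raises.  The returned frame is a complete grid over the groups and
    sexes present and all six age bands, with zero-filled empty cells.
    """
    pid = persons.set_index("person_id")
    sexes = sorted(pid["sex"].unique()) if len(pid) else []
    groups = sorted(exposure["group"].unique()) if len(exposure) else []
    grid = pd.MultiIndex.from_product(
        [groups, sexes, AGE_BANDS], names=["group", "sex", "age_band"]
    )
    cells = pd.DataFrame(index=grid, data={"person_years": 0.0, "deaths": 0}).reset_index()
    if exposure.empty or follow_ups.empty:
        return cells

    fu = follow_ups.set_index("person_id")
    exp = exposure.copy()
    exp["s"] = to_day_numbers(exp["start"])
    exp["e"] = to_day_numbers(exp["end"])
    exp["entry_d"] = to_day_numbers(fu.loc[exp["person_id"], "entry"].to_numpy())
    exp["exit_d"] = to_day_numbers(fu.loc[exp["person_id"], "exit"].to_numpy())
    if ((exp["s"] < exp["entry_d"]) | (exp["e"] > exp["exit_d"])).any():
        raise ValueError("exposure interval outside follow-up window")
    exp["sex"] = pid.loc[exp["person_id"], "sex"].to_numpy()

    cuts = _band_cut_days(pid.loc[exp["person_id"], "birth_date"])
    s = exp["s"].to_numpy()
    e = exp["e"].to_numpy()
    pieces = []
    for k, band in enumerate(AGE_BANDS):
        lo = np.maximum(s, cuts[:, k])
        hi = e if k == len(AGE_BANDS) - 1 else np.minimum(e, cuts[:, k + 1])
        days = np.clip(hi - lo, 0, None)
        mask = days > 0
        if mask.any():
            pieces.append(
                pd.DataFrame(
                    {
                        "group": exp["group"].to_numpy()[mask],
                        "sex": exp["sex"].to_numpy()[mask],
                        "age_band": band,
                        "days": days[mask],
                    }
                )
            )
    if pieces:
        py = (
            pd.concat(pieces)
            .groupby(["group", "sex", "age_band"], sort=False)["days"]
            .sum()
            / DAYS_PER_YEAR
        )
    else:
        py = pd.Series(dtype=float)

    # deaths: groups whose interval covers the death date; an interval
    # ending on the death date counts (half-open end extended for deaths)
    died = fu[fu["exit_cause"] == "death"]
    dmask = exp["person_id"].isin(died.index) & (exp["e"] == exp["exit_d"])
    dead = exp[dmask]
    if len(dead):
        dcuts = cuts[dmask.to_numpy()]
        band_idx = (dead["exit_d"].to_numpy()[:, None] >= dcuts[:, 1:]).sum(axis=1)
        deaths = (
            pd.DataFrame(
                {
                    "group": dead["group"].to_numpy(),
                    "sex": dead["sex"].to_numpy(),
                    "age_band": np.array(AGE_BANDS)[band_idx],
                }
            )
            .groupby(["group", "sex", "age_band"], sort=False)
            .size()
        )
    else:
        deaths = pd.Series(dtype=int)

    cells = cells.set_index(["group", "sex", "age_band"])
    cells["person_years"] = py.reindex(cells.index).fillna(0.0)
    cells["deaths"] = deaths.reindex(cells.index).fillna(0).astype(int)
    return cells.reset_index()
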