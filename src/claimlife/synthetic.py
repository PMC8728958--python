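"""Synthetic claims cohorts with known treatment-state-dependent mortality.

The generator emulates the structure of provincial drug-benefit claims for
adults 65 and older: a persons table (sex, birth, diagnosis, death,
emigration dates), outpatient dispensing records carrying the number of
days supplied, surgery dates, and outpatient visits labelled CD/UC.  Every
person follows a semi-Markov process over the six medication states
(mesalamine, immunomodulator monotherapy, biologic monotherapy, combination
therapy, systemic steroids, no therapy); while in a drug state the person
accrues dispensings whose coverage plus refill gaps realises that state.
Death is driven by piecewise-constant hazards specific to sex, treatment
state and 5-year age band, so the true life expectancy of any frozen state
is available in closed form (:func:`true_life_expectancy`) and every
downstream estimate can be checked against known truth.

Default hazard schedules are Gompertz-like ladders (hazard x1.5 per 5-year
band) whose levels were fixed so that the per-state true life expectancies
at 65 match typical elderly-IBD values by sex: longest on mesalamine,
similar for immunomodulator and biologic monotherapy, shortest on systemic
steroids.  All dates are generated at day resolution; years convert to days
at 365.25 throughout the package.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .exposure import DEFAULT_DRUG_MAP, GROUPS

__all__ = [
    "HazardSchedule",
    "StateProcess",
    "DispensingRule",
    "SimulationConfig",
    "CohortBundle",
    "true_life_expectancy",
    "simulate_death_age",
    "simulate_death_ages",
    "scaled_schedule",
    "default_hazards",
    "default_config",
    "frozen_state_config",
    "generate_cohort",
]

DAYS_PER_YEAR = 365.25
BAND_START_AGES = (65.0, 70.0, 75.0, 80.0, 85.0, 90.0)
_EPOCH = _dt.date(1970, 1, 1)

#: Medication classes dispensed in each treatment state ("@biologic" is the
#: person's own biologic class, drawn once per person).
STATE_CLASSES: Dict[str, Tuple[str, ...]] = {
    "mesalamine": ("mesalamine",),
    "immunomodulator_mono": ("immunomodulator",),
    "biologic_mono": ("@biologic",),
    "combination": ("immunomodulator", "@biologic"),
    "steroid": ("systemic_steroid",),
    "no_therapy": (),
}

_CLASS_CODES = {
    "mesalamine": ("MES001", "MES002"),
    "immunomodulator": ("AZA001", "MP6001", "MTX001"),
    "systemic_steroid": ("PRD001", "PRD002"),
    "biologic_q8": ("IFX001", "UST001", "VDZ001"),
    "biologic_other": ("ADA001", "GOL001"),
}


class HazardSchedule(BaseModel):
    """Piecewise-constant mortality hazard over contiguous age bands.

    ``starts`` are ascending band-start ages; the last band is open-ended.
    ``mu`` holds the hazard per person-year for each band; the open band's
    hazard must be positive so remaining lifetime is finite.
    """

    model_config = ConfigDict(frozen=True)

    starts: Tuple[float, ...] = BAND_START_AGES
    mu: Tuple[float, ...]

    @model_validator(mode="after")
    def _check(self):
        if len(self.starts) != len(self.mu):
            raise ValueError("starts and mu must have equal length")
        if len(self.starts) < 1:
            raise ValueError("schedule needs at least one band")
        if any(b <= a for a, b in zip(self.starts, self.starts[1:])):
            raise ValueError("band starts must be strictly ascending")
        if any(h < 0 for h in self.mu):
            raise ValueError("hazards must be non-negative")
        if self.mu[-1] <= 0:
            raise ValueError("open-band hazard must be positive")
        return self

    def band_index(self, age: float) -> int:
        return max(0, int(np.searchsorted(self.starts, age, side="right")) - 1)


def true_life_expectancy(schedule: HazardSchedule, from_age: float) -> float:
    """Closed-form remaining life expectancy under the schedule.

    e(x) = sum over closed bands at or after x of S_i (1 - exp(-mu_i n_i)) / mu_i
    plus S_omega / mu_omega for the open band, where S_i is the survival to
    the band start.  ``from_age`` must coincide with a band boundary.
    """
    starts = np.asarray(schedule.starts, dtype=float)
    hits = np.nonzero(np.isclose(starts, from_age, atol=1e-9))[0]
    if len(hits) == 0:
        raise ValueError(f"from_age {from_age} is not a band boundary of {starts}")
    j = int(hits[0])
    if schedule.mu[-1] <= 0:
        raise ValueError("infinite life expectancy: open-band hazard is zero")
    e = 0.0
    surv = 1.0
    for i in range(j, len(starts) - 1):
        n = starts[i + 1] - starts[i]
        h = schedule.mu[i]
        if h == 0:
            e += surv * n
        else:
            e += surv * (-np.expm1(-h * n)) / h
            surv *= np.exp(-h * n)
    e += surv / schedule.mu[-1]
    return float(e)


def _segments_from(schedule: HazardSchedule, entry_age: float):
    """(seg_start, hazard) pairs from entry_age onward; last is open."""
    starts = schedule.starts
    i = schedule.band_index(entry_age)
    seg_starts = [entry_age] + [s for s in starts[i + 1 :]]
    seg_mu = list(schedule.mu[i:])
    return np.asarray(seg_starts, dtype=float), np.asarray(seg_mu, dtype=float)


def simulate_death_age(schedule: HazardSchedule, entry_age: float, rng) -> float:
    """One death age by piecewise-exponential inversion.

    Draws a unit-exponential cumulative-hazard target (zero draws are
    resampled so the death age is strictly greater than entry) and walks it
    through the bands.
    """
    if entry_age < schedule.starts[0] - 1e-9:
        raise ValueError("entry_age precedes the first band")
    target = rng.exponential()
    while target <= 0.0:
        target = rng.exponential()
    seg_starts, seg_mu = _segments_from(schedule, entry_age)
    for i in range(len(seg_starts) - 1):
        h = seg_mu[i]
        span = seg_starts[i + 1] - seg_starts[i]
        if h > 0 and target <= h * span:
            return float(seg_starts[i] + target / h)
        target -= h * span
    return float(seg_starts[-1] + target / seg_mu[-1])


def simulate_death_ages(
    schedule: HazardSchedule, entry_age: float, n: int, rng
) -> np.ndarray:
    """Vectorised version of :func:`simulate_death_age` for Monte-Carlo
    cross-checks."""
    seg_starts, seg_mu = _segments_from(schedule, entry_age)
    widths = np.diff(seg_starts)
    cum = np.concatenate([[0.0], np.cumsum(seg_mu[:-1] * widths)])
    targets = rng.exponential(size=n)
    zero = targets <= 0.0
    while zero.any():
        targets[zero] = rng.exponential(size=int(zero.sum()))
        zero = targets <= 0.0
    # first segment whose cumulative end exceeds the target; zero-hazard
    # segments are flat in `cum` and therefore skipped
    idx = np.searchsorted(cum[1:], targets, side="right")
    idx = np.minimum(idx, len(seg_mu) - 1)
    return seg_starts[idx] + (targets - cum[idx]) / seg_mu[idx]


def scaled_schedule(m65: float, ratio: float = 1.5) -> HazardSchedule:
    """Gompertz-like ladder: hazard m65 at 65-69 rising by ``ratio`` per
    5-year band."""
    return HazardSchedule(
        starts=BAND_START_AGES,
        mu=tuple(m65 * ratio**i for i in range(len(BAND_START_AGES))),
    )


# Hazard level at 65-69 per (sex, state); fixed so the true LE at 65 of each
# frozen state matches typical elderly-IBD values (see docs/methods.md).
DEFAULT_M65: Dict[str, Dict[str, float]] = {
    "F": {
        "mesalamine": 0.014420,          # true LE at 65: 22.1 y
        "combination": 0.016609,         # 20.5 y
        "no_therapy": 0.019772,          # 18.7 y
        "biologic_mono": 0.025345,       # 16.4 y
        "immunomodulator_mono": 0.028505,  # 15.4 y
        "steroid": 0.046558,             # 11.7 y
    },
    "M": {
        "mesalamine": 0.018084,          # 19.6 y
        "combination": 0.024774,         # 16.6 y
        "no_therapy": 0.023426,          # 17.1 y
        "biologic_mono": 0.031452,       # 14.6 y
        "immunomodulator_mono": 0.034844,  # 13.8 y
        "steroid": 0.057588,             # 10.3 y
    },
}


def default_hazards() -> Dict[str, Dict[str, HazardSchedule]]:
    return {
        sex: {state: scaled_schedule(m65) for state, m65 in by_state.items()}
        for sex, by_state in DEFAULT_M65.items()
    }


class StateProcess(BaseModel):
    """Semi-Markov treatment-state process over the six groups.

    Sojourn times are exponential with per-state means; on leaving a state
    the next state is uniform over the other five.
    """

    initial_probs: Dict[str, float] = Field(
        default_factory=lambda: {
            "mesalamine": 0.42,
            "no_therapy": 0.40,
            "immunomodulator_mono": 0.08,
            "steroid": 0.06,
            "biologic_mono": 0.03,
            "combination": 0.01,
        }
    )
    mean_dwell_years: Dict[str, float] = Field(
        default_factory=lambda: {
            "mesalamine": 3.0,
            "no_therapy": 3.0,
            "immunomodulator_mono": 2.0,
            "biologic_mono": 2.0,
            "combination": 1.5,
            "steroid": 0.4,
        }
    )

    @model_validator(mode="after")
    def _check(self):
        if set(self.initial_probs) != set(GROUPS):
            raise ValueError(f"initial_probs must cover exactly the states {GROUPS}")
        if set(self.mean_dwell_years) != set(GROUPS):
            raise ValueError(f"mean_dwell_years must cover exactly the states {GROUPS}")
        p = np.array([self.initial_probs[s] for s in GROUPS])
        if (p < 0).any() or (p > 1).any() or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("initial_probs must lie in [0,1] and sum to 1")
        if any(v <= 0 for v in self.mean_dwell_years.values()):
            raise ValueError("mean dwell times must be positive")
        return self


class DispensingRule(BaseModel):
    """How a drug class emits dispensings while its state is active."""

    days_supplied: List[int]
    probs: List[float]
    gap_mean_days: float

    @model_validator(mode="after")
    def _check(self):
        if len(self.days_supplied) != len(self.probs) or not self.days_supplied:
            raise ValueError("days_supplied and probs must be equal-length and non-empty")
        if any(d < 1 for d in self.days_supplied):
            raise ValueError("days_supplied entries must be >= 1")
        p = np.asarray(self.probs)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("probs must be non-negative and sum to 1")
        if self.gap_mean_days < 0:
            raise ValueError("gap_mean_days must be non-negative")
        return self


def _default_dispensing() -> Dict[str, DispensingRule]:
    return {
        "mesalamine": DispensingRule(days_supplied=[30, 60, 90], probs=[0.5, 0.3, 0.2], gap_mean_days=12.0),
        "immunomodulator": DispensingRule(days_supplied=[30, 90], probs=[0.6, 0.4], gap_mean_days=12.0),
        "systemic_steroid": DispensingRule(days_supplied=[14, 30], probs=[0.6, 0.4], gap_mean_days=10.0),
        "biologic_q8": DispensingRule(days_supplied=[56], probs=[1.0], gap_mean_days=30.0),
        "biologic_other": DispensingRule(days_supplied=[28], probs=[1.0], gap_mean_days=15.0),
    }


class SimulationConfig(BaseModel):
    """Everything needed to draw one cohort reproducibly."""

    n_persons: int = Field(ge=0)
    sex_ratio_female: float = Field(default=0.519, ge=0.0, le=1.0)
    birth_year_range: Tuple[int, int] = (1915, 1950)
    prob_diagnosed_before_65: float = Field(default=0.625, ge=0.0, le=1.0)
    diagnosis_age_range_early: Tuple[float, float] = (20.0, 64.0)
    diagnosis_age_mean_excess: float = Field(default=5.0, gt=0.0)
    study_start: _dt.date = _dt.date(1997, 7, 1)
    study_end: _dt.date = _dt.date(2017, 6, 30)
    states: StateProcess = Field(default_factory=StateProcess)
    dispensing: Dict[str, DispensingRule] = Field(default_factory=_default_dispensing)
    prob_biologic_q8: float = Field(default=0.7, ge=0.0, le=1.0)
    emigration_hazard: float = Field(default=0.005, ge=0.0)
    surgery_hazard: float = Field(default=0.01, ge=0.0)
    post_surgery_hazard_ratio: float = Field(default=1.0, gt=0.0)
    hazards: Dict[str, Dict[str, HazardSchedule]] = Field(default_factory=default_hazards)
    subtype_probs: Dict[str, float] = Field(
        default_factory=lambda: {"CD": 0.385, "UC": 0.566, "unclassified": 0.049}
    )
    visit_rate_per_year: float = Field(default=1.5, ge=0.0)
    visit_label_accuracy: float = Field(default=0.93, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ValueError("birth_year_range must be (low, high)")
        if self.study_start >= self.study_end:
            raise ValueError("study window start must precede its end")
        lo, hi = self.diagnosis_age_range_early
        if not (0 < lo < hi <= 65):
            raise ValueError("diagnosis_age_range_early must lie within (0, 65]")
        for sex in ("F", "M"):
            if sex not in self.hazards:
                raise ValueError(f"hazards missing sex {sex!r}")
            if set(self.hazards[sex]) != set(GROUPS):
                raise ValueError(f"hazards[{sex!r}] must cover exactly the states {GROUPS}")
        if set(self.dispensing) != set(_CLASS_CODES):
            raise ValueError("dispensing rules must cover the five drug classes")
        p = np.array(list(self.subtype_probs.values()))
        if set(self.subtype_probs) != {"CD", "UC", "unclassified"} or not np.isclose(
            p.sum(), 1.0, atol=1e-9
        ):
            raise ValueError("subtype_probs must cover CD/UC/unclassified and sum to 1")
        return self


@dataclass
class CohortBundle:
    """Generated claims tables plus the ground truth that produced them."""

    persons: pd.DataFrame
    prescriptions: pd.DataFrame
    surgeries: pd.DataFrame
    visits: pd.DataFrame
    truth: dict

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.persons.to_csv(out / "persons.csv", index=False, date_format="%Y-%m-%d")
        self.prescriptions.to_csv(out / "prescriptions.csv", index=False, date_format="%Y-%m-%d")
        self.surgeries.to_csv(out / "surgeries.csv", index=False, date_format="%Y-%m-%d")
        self.visits.to_csv(out / "visits.csv", index=False, date_format="%Y-%m-%d")
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))

    @classmethod
    def load(cls, outdir) -> "CohortBundle":
        out = Path(outdir)
        date_cols = {
            "persons": ["birth_date", "diagnosis_date", "death_date", "emigration_date"],
            "prescriptions": ["dispense_date"],
            "surgeries": ["surgery_date"],
            "visits": ["visit_date"],
        }
        frames = {}
        for name, cols in date_cols.items():
            df = pd.read_csv(out / f"{name}.csv")
            for c in cols:
                if c in df.columns:
                    df[c] = pd.to_datetime(df[c])
            frames[name] = df
        truth = json.loads((out / "truth.json").read_text())
        return cls(frames["persons"], frames["prescriptions"], frames["surgeries"], frames["visits"], truth)


def default_config(n_persons: int, seed: int = 0, **overrides) -> SimulationConfig:
    return SimulationConfig(n_persons=n_persons, seed=seed, **overrides)


def frozen_state_config(
    state: str,
    n_persons: int,
    seed: int = 0,
    schedules: Optional[Dict[str, HazardSchedule]] = None,
    **overrides,
) -> SimulationConfig:
    """Config in which every person stays in ``state`` for good.

    ``schedules`` optionally overrides the frozen state's hazard per sex;
    used by the oracle and parameter-recovery experiments.
    """
    if state not in GROUPS:
        raise ValueError(f"unknown state {state!r}")
    probs = {s: 0.0 for s in GROUPS}
    probs[state] = 1.0
    dwell = {s: 1e9 for s in GROUPS}
    hazards = default_hazards()
    if schedules is not None:
        for sex, sched in schedules.items():
            hazards[sex] = dict(hazards[sex])
            hazards[sex][state] = sched
    return SimulationConfig(
        n_persons=n_persons,
        seed=seed,
        states=StateProcess(initial_probs=probs, mean_dwell_years=dwell),
        hazards=hazards,
        **overrides,
    )


def _date_to_days(d: _dt.date) -> int:
    return (d - _EPOCH).days


def _scan_death(schedule, t0, t1, target, surgery_age, hr):
    """Walk the cumulative-hazard target through [t0, t1).

    The hazard is the schedule's band hazard, multiplied by ``hr`` from
    ``surgery_age`` onward.  Returns (death_age or None, remaining target).
    """
    starts = schedule.starts
    bounds = [s for s in starts if t0 < s < t1]
    if hr != 1.0 and t0 < surgery_age < t1:
        bounds.append(surgery_age)
    bounds = sorted(set(bounds))
    segs = [t0] + bounds + [t1]
    for a, b in zip(segs, segs[1:]):
        h = schedule.mu[schedule.band_index(a)]
        if hr != 1.0 and a >= surgery_age:
            h *= hr
        if h > 0 and target <= h * (b - a):
            return a + target / h, 0.0
        target -= h * (b - a)
    return None, target


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Draw one cohort; deterministic given the config (including seed)."""
    rng = np.random.default_rng(config.seed)
    states = list(GROUPS)
    init_p = np.array([config.states.initial_probs[s] for s in states])
    dwell = config.states.mean_dwell_years
    start_d = _date_to_days(config.study_start)
    end_d = _date_to_days(config.study_end)
    disp_rules = {
        cls: (np.asarray(rule.days_supplied), np.asarray(rule.probs),
              float(rule.gap_mean_days), _CLASS_CODES[cls])
        for cls, rule in config.dispensing.items()
    }
    subtype_p = [config.subtype_probs[k] for k in ("CD", "UC", "unclassified")]

    persons_rows: list = []
    rx_rows: list = []
    surgery_rows: list = []
    visit_rows: list = []

    for i in range(config.n_persons):
        pid = f"P{i + 1:06d}"
        sex = "F" if rng.random() < config.sex_ratio_female else "M"
        by = int(rng.integers(config.birth_year_range[0], config.birth_year_range[1] + 1))
        year_len = 366 if (by % 4 == 0 and (by % 100 != 0 or by % 400 == 0)) else 365
        birth = _dt.date(by, 1, 1) + _dt.timedelta(days=int(rng.integers(0, year_len)))
        birth_d = _date_to_days(birth)
        b65_d = _date_to_days(
            birth.replace(year=by + 65)
            if not (birth.month == 2 and birth.day == 29)
            else _dt.date(by + 65, 2, 28)
        )
        if rng.random() < config.prob_diagnosed_before_65:
            diag_age = rng.uniform(*config.diagnosis_age_range_early)
        else:
            diag_age = 65.0 + rng.exponential(config.diagnosis_age_mean_excess)
            for _ in range(20):
                if birth_d + diag_age * DAYS_PER_YEAR <= end_d:
                    break
                diag_age = 65.0 + rng.exponential(config.diagnosis_age_mean_excess)
        diag_d = birth_d + int(round(diag_age * DAYS_PER_YEAR))
        entry_d = max(b65_d, diag_d, start_d)

        death_date = None
        emig_date = None
        if entry_d < end_d:
            entry_age = (entry_d - birth_d) / DAYS_PER_YEAR
            admin_age = entry_age + (end_d - entry_d) / DAYS_PER_YEAR
            emig_age = (
                entry_age + rng.exponential(1.0 / config.emigration_hazard)
                if config.emigration_hazard > 0
                else np.inf
            )
            surgery_age = (
                entry_age + rng.exponential(1.0 / config.surgery_hazard)
                if config.surgery_hazard > 0
                else np.inf
            )
            target = rng.exponential()
            while target <= 0.0:
                target = rng.exponential()
            biologic_class = (
                "biologic_q8" if rng.random() < config.prob_biologic_q8 else "biologic_other"
            )

            sojourns: list = []
            death_age = np.inf
            stop_age = min(admin_age, emig_age)
            t = entry_age
            state = states[int(rng.choice(len(states), p=init_p))]
            while t < stop_age:
                seg_end = min(t + rng.exponential(dwell[state]), stop_age)
                d_age, target = _scan_death(
                    config.hazards[sex][state], t, seg_end, target,
                    surgery_age, config.post_surgery_hazard_ratio,
                )
                if d_age is not None:
                    death_age = d_age
                    sojourns.append((state, t, d_age))
                    break
                sojourns.append((state, t, seg_end))
                if seg_end >= stop_age:
                    break
                t = seg_end
                nxt = int(rng.integers(0, len(states) - 1))
                others = [s for s in states if s != state]
                state = others[nxt]

            exit_age = min(death_age, emig_age, admin_age)
            exit_d = (
                end_d
                if exit_age == admin_age
                else birth_d + int(round(exit_age * DAYS_PER_YEAR))
            )
            exit_d = min(exit_d, end_d)
            if death_age <= min(emig_age, admin_age):
                death_date = exit_d
            elif emig_age < admin_age:
                emig_date = exit_d
            if surgery_age < exit_age:
                surgery_rows.append(
                    (pid, birth_d + int(round(surgery_age * DAYS_PER_YEAR)))
                )

            for st, a0, a1 in sojourns:
                a1 = min(a1, exit_age)
                for cls in STATE_CLASSES[st]:
                    cls = biologic_class if cls == "@biologic" else cls
                    days_arr, probs_arr, gap_mean, codes = disp_rules[cls]
                    tt = a0
                    while tt < a1:
                        if len(days_arr) == 1:
                            days = int(days_arr[0])
                        else:
                            days = int(days_arr[int(rng.choice(len(days_arr), p=probs_arr))])
                        code = codes[int(rng.integers(0, len(codes)))]
                        disp_d = birth_d + int(round(tt * DAYS_PER_YEAR))
                        if disp_d <= exit_d:
                            rx_rows.append((pid, code, disp_d, days))
                        gap = rng.exponential(gap_mean) if gap_mean > 0 else 0.0
                        tt += (days + gap) / DAYS_PER_YEAR

            # outpatient visits with noisy subtype labels
            subtype = ("CD", "UC", "unclassified")[int(rng.choice(3, p=subtype_p))]
            fu_years = (exit_d - entry_d) / DAYS_PER_YEAR
            if subtype == "unclassified":
                # an even, balanced short history stays unclassifiable
                n_vis = 2 * int(rng.integers(1, 5))
                labels = ["CD", "UC"] * (n_vis // 2)
            else:
                n_vis = int(rng.poisson(config.visit_rate_per_year * max(fu_years, 0.0)))
                other = "UC" if subtype == "CD" else "CD"
                labels = [
                    subtype if rng.random() < config.visit_label_accuracy else other
                    for _ in range(n_vis)
                ]
            if n_vis > 0:
                offsets = np.sort(rng.random(n_vis)) * max(exit_d - entry_d, 1)
                for off, lab in zip(offsets, labels):
                    visit_rows.append((pid, entry_d + int(off), lab))

        persons_rows.append(
            (pid, sex, birth_d, diag_d, death_date, emig_date)
        )

    _NAT = np.iinfo(np.int64).min  # datetime64 NaT sentinel

    def _dates(col):
        ints = np.array(
            [_NAT if x is None or (isinstance(x, float) and np.isnan(x)) else int(x) for x in col],
            dtype=np.int64,
        )
        return pd.Series(ints.view("datetime64[D]").astype("datetime64[ns]"))

    persons = pd.DataFrame(
        persons_rows,
        columns=["person_id", "sex", "birth_date", "diagnosis_date", "death_date", "emigration_date"],
    )
    for c in ("birth_date", "diagnosis_date", "death_date", "emigration_date"):
        persons[c] = _dates(persons[c])
    prescriptions = pd.DataFrame(
        rx_rows, columns=["person_id", "drug_code", "dispense_date", "days_supplied"]
    )
    prescriptions["dispense_date"] = _dates(prescriptions["dispense_date"])
    if not prescriptions.empty:
        prescriptions["days_supplied"] = prescriptions["days_supplied"].astype(int)
    surgeries = pd.DataFrame(surgery_rows, columns=["person_id", "surgery_date"])
    surgeries["surgery_date"] = _dates(surgeries["surgery_date"])
    visits = pd.DataFrame(visit_rows, columns=["person_id", "visit_date", "dx"])
    visits["visit_date"] = _dates(visits["visit_date"])

    truth = {
        "true_le65": {
            sex: {
                state: true_life_expectancy(sched, 65.0)
                for state, sched in by_state.items()
            }
            for sex, by_state in config.hazards.items()
        },
        "config": config.model_dump(mode="json"),
    }
    return CohortBundle(persons, prescriptions, surgeries, visits, truth)
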