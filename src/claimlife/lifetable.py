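"""Abridged period life tables, life expectancy at 65 and comparisons.

Given stratum-level death counts and person-years per 5-year age band
(65-69 ... 85-89, open 90+), this module computes age-specific mortality
rates m_x, converts them to conditional death probabilities q_x, builds the
abridged life-table columns (l, L, T, e) on a radix of 1, and returns life
expectancy at 65 with a sampling variance and 95% confidence interval.

The q conversion is Chiang's hyperbolic form by default,

    q = n*m / (1 + n*(1-a)*m),

with the exponential form q = 1 - exp(-n*m) selectable.  The fraction of
the band lived by those dying, a, defaults to 1/2; the ``constant_hazard``
option solves a from the band rate (a = 1/(n*m) - 1/expm1(n*m)), which
makes the table exact when the underlying hazard is constant within bands.
The open age interval is closed as L = l/m (exponential closure, the only
closure consistent with a constant hazard beyond the last cut point); the
closure is a named, registered option so alternative treatments of the last
age group can be dropped in.

Var(e65) follows Chiang's decomposition over the closed bands,
Var(q) = q^2 (1-q) / D, plus a Silcocks-type term l^2 / (m^2 D) for the
open interval.  A parametric bootstrap (Poisson resampling of band death
counts) is provided as an independent cross-check on the analytic CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .person_time import AGE_BANDS, BAND_START_AGES

__all__ = [
    "RateSet",
    "AbridgedLifeTable",
    "LEEstimate",
    "LEDifference",
    "mortality_rates",
    "build_life_table",
    "life_expectancy",
    "survival_curve",
    "le_difference",
    "bootstrap_ci",
    "OPEN_CLOSURES",
]

Z95 = 1.96
_BAND_WIDTH = 5.0


@dataclass(frozen=True)
class RateSet:
    """Deaths, person-years and rates per age band for one stratum."""

    deaths: np.ndarray
    person_years: np.ndarray
    bands: tuple = AGE_BANDS
    group: Optional[str] = None
    sex: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "deaths", np.asarray(self.deaths, dtype=float))
        object.__setattr__(self, "person_years", np.asarray(self.person_years, dtype=float))
        if len(self.deaths) != len(self.bands) or len(self.person_years) != len(self.bands):
            raise ValueError("deaths/person_years must have one entry per band")

    @property
    def m(self) -> np.ndarray:
        """Mortality rate per person-year, deaths / person-years."""
        return self.deaths / self.person_years


def mortality_rates(cells: pd.DataFrame, group=None, sex=None) -> RateSet:
    """Age-specific mortality rates for one (group, sex) stratum.

    ``cells`` holds columns ``age_band, person_years, deaths`` (optionally
    pre-filtered, otherwise ``group``/``sex`` select the stratum).  Every
    age band must be present with positive person-years.
    """
    df = cells
    if group is not None:
        df = df[df["group"] == group]
    if sex is not None:
        df = df[df["sex"] == sex]
    df = df.set_index("age_band")
    missing = [b for b in AGE_BANDS if b not in df.index]
    if missing:
        raise ValueError(f"missing age bands {missing} in stratum {group}/{sex}")
    df = df.loc[list(AGE_BANDS)]
    py = df["person_years"].to_numpy(dtype=float)
    if (py <= 0).any():
        bad = [b for b, p in zip(AGE_BANDS, py) if p <= 0]
        raise ValueError(f"zero person-years in bands {bad} of stratum {group}/{sex}")
    return RateSet(df["deaths"].to_numpy(dtype=float), py, AGE_BANDS, group, sex)


def _a_constant_hazard(x: np.ndarray) -> np.ndarray:
    """Average fraction of the band lived by those dying when the hazard is
    constant within the band; x = n*m.  Limits to 1/2 as x -> 0."""
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, 0.5)
    big = x > 1e-4
    with np.errstate(divide="ignore", invalid="ignore"):
        out[big] = 1.0 / x[big] - 1.0 / np.expm1(x[big])
    small = ~big & (x > 0)
    out[small] = 0.5 - x[small] / 12.0
    return out


def _close_exponential(l_open: float, m_open: float) -> float:
    return l_open / m_open


#: Named closures for the open age interval: l_omega -> L_omega.
OPEN_CLOSURES: Dict[str, Callable[[float, float], float]] = {
    "exponential": _close_exponential,
}


@dataclass
class AbridgedLifeTable:
    """Per-band life-table columns for one stratum (radix l_65 = 1)."""

    bands: tuple
    n: np.ndarray          # band widths; NaN for the open interval
    m: np.ndarray          # mortality rate per person-year
    a: np.ndarray          # fraction of band lived by those dying; NaN open
    q: np.ndarray          # conditional probability of dying in the band
    var_q: np.ndarray      # sampling variance of q (0 where deaths = 0)
    l: np.ndarray          # survivors at band start
    L: np.ndarray          # person-years lived in the band
    T: np.ndarray          # person-years remaining at band start
    e: np.ndarray          # remaining life expectancy at band start
    deaths: np.ndarray
    person_years: np.ndarray
    group: Optional[str] = None
    sex: Optional[str] = None
    options: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_band": list(self.bands),
                "m": self.m,
                "q": self.q,
                "l": self.l,
                "L": self.L,
                "T": self.T,
                "e": self.e,
                "deaths": self.deaths,
                "person_years": self.person_years,
            }
        )


def build_life_table(
    rates: RateSet,
    *,
    q_conversion: str = "chiang",
    a_mode: str = "midpoint",
    open_closure: str = "exponential",
) -> AbridgedLifeTable:
    """Abridged period life table from age-specific mortality rates.

    Parameters
    ----------
    rates
        One :class:`RateSet` (all six bands, positive person-years).
    q_conversion
        ``"chiang"`` (hyperbolic, default) or ``"exponential"``.
    a_mode
        ``"midpoint"`` (a = 0.5, default) or ``"constant_hazard"``.
    open_closure
        Name of the open-interval closure from :data:`OPEN_CLOSURES`.
    """
    if q_conversion not in ("chiang", "exponential"):
        raise ValueError(f"unknown q_conversion {q_conversion!r}")
    if a_mode not in ("midpoint", "constant_hazard"):
        raise ValueError(f"unknown a_mode {a_mode!r}")
    if open_closure not in OPEN_CLOSURES:
        raise ValueError(f"unknown open_closure {open_closure!r}")

    k = len(rates.bands)
    m = rates.m
    D = rates.deaths
    if m[-1] <= 0:
        raise ValueError("life table does not close: open-band mortality rate is zero")

    n = np.full(k, _BAND_WIDTH)
    n[-1] = np.nan
    mc = m[:-1]
    nc = n[:-1]
    if a_mode == "midpoint":
        a_closed = np.full(k - 1, 0.5)
    else:
        a_closed = _a_constant_hazard(nc * mc)

    if q_conversion == "chiang":
        q_closed = nc * mc / (1.0 + nc * (1.0 - a_closed) * mc)
    else:
        q_closed = -np.expm1(-nc * mc)
    q_closed = np.clip(q_closed, 0.0, 1.0)

    q = np.append(q_closed, 1.0)
    a = np.append(a_closed, np.nan)
    l = np.empty(k)
    l[0] = 1.0
    for i in range(k - 1):
        l[i + 1] = l[i] * (1.0 - q[i])
    if (l <= 0).any():
        raise ValueError("life table degenerate: zero survivorship before the open band")

    L = np.empty(k)
    L[:-1] = nc * l[1:] + a_closed * nc * (l[:-1] - l[1:])
    L[-1] = OPEN_CLOSURES[open_closure](l[-1], m[-1])
    T = np.cumsum(L[::-1])[::-1]
    e = T / l

    with np.errstate(divide="ignore", invalid="ignore"):
        var_q = np.where(D > 0, q**2 * (1.0 - q) / np.where(D > 0, D, 1.0), 0.0)
    var_q[-1] = 0.0  # the open interval enters the LE variance separately

    return AbridgedLifeTable(
        bands=tuple(rates.bands),
        n=n, m=m.copy(), a=a, q=q, var_q=var_q, l=l, L=L, T=T, e=e,
        deaths=D.copy(), person_years=rates.person_years.copy(),
        group=rates.group, sex=rates.sex,
        options={"q_conversion": q_conversion, "a_mode": a_mode,
                 "open_closure": open_closure},
    )


@dataclass(frozen=True)
class LEEstimate:
    """Life expectancy at 65 with variance and 95% CI for one stratum."""

    e65: float
    variance: float
    ci95: tuple
    group: Optional[str] = None
    sex: Optional[str] = None
    method: str = "analytic"
    meta: dict = field(default_factory=dict)

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


def life_expectancy(lt: AbridgedLifeTable) -> LEEstimate:
    """Life expectancy at 65 with Chiang-decomposition variance.

    Var(e65) sums, over closed bands, l^2 [(1-a) n + e_{next}]^2 Var(q),
    plus the open-interval term l^2 / (m^2 D); everything is divided by
    the squared radix.
    """
    e65 = float(lt.e[0])
    l, a, n, e = lt.l, lt.a, lt.n, lt.e
    closed = slice(0, len(lt.bands) - 1)
    weights = (l[closed] ** 2) * ((1.0 - a[closed]) * n[closed] + e[1:]) ** 2
    var = float(np.sum(weights * lt.var_q[closed]))
    D_open = lt.deaths[-1]
    if D_open > 0:
        var += float(l[-1] ** 2 / (lt.m[-1] ** 2 * D_open))
    var /= float(l[0] ** 2)
    se = np.sqrt(var)
    return LEEstimate(
        e65=e65,
        variance=var,
        ci95=(e65 - Z95 * se, e65 + Z95 * se),
        group=lt.group,
        sex=lt.sex,
        method="analytic",
        meta={"options": dict(lt.options)},
    )


def survival_curve(lt: AbridgedLifeTable) -> list[tuple[float, float]]:
    """Expected proportion remaining alive at each band-start age,
    normalised to 1 at age 65."""
    return [(float(age), float(li / lt.l[0])) for age, li in zip(BAND_START_AGES, lt.l)]


@dataclass(frozen=True)
class LEDifference:
    """Difference of two life expectancies (row minus column)."""

    delta: float
    ci95: tuple
    significant: bool
    group_a: Optional[str] = None
    group_b: Optional[str] = None
    sex: Optional[str] = None


def le_difference(a: LEEstimate, b: LEEstimate) -> LEDifference:
    """a.e65 - b.e65 with a normal 95% CI from the summed variances.

    The strata are treated as independent; the difference is flagged
    significant when the CI excludes 0.
    """
    delta = a.e65 - b.e65
    se = float(np.sqrt(a.variance + b.variance))
    lo, hi = delta - Z95 * se, delta + Z95 * se
    return LEDifference(
        delta=delta,
        ci95=(lo, hi),
        significant=bool(lo > 0 or hi < 0),
        group_a=a.group,
        group_b=b.group,
        sex=a.sex,
    )


def bootstrap_ci(
    rates: RateSet,
    reps: int = 1000,
    seed: int = 0,
    *,
    q_conversion: str = "chiang",
    a_mode: str = "midpoint",
    open_closure: str = "exponential",
) -> LEEstimate:
    """Percentile bootstrap CI for e65 by Poisson resampling of deaths.

    Band death counts are resampled D* ~ Poisson(D) with person-years held
    fixed; replicates whose open band draws zero deaths cannot close and
    are redrawn (the count is reported in ``meta['redraws']``).
    """
    if reps < 200:
        raise ValueError("reps must be >= 200 for a percentile CI")
    rng = np.random.default_rng(seed)
    e_star = np.empty(reps)
    redraws = 0
    for r in range(reps):
        while True:
            d_star = rng.poisson(rates.deaths)
            if d_star[-1] > 0:
                break
            redraws += 1
            if redraws > 1000 * reps:
                raise RuntimeError("bootstrap cannot close the open interval")
        rs = RateSet(d_star, rates.person_years, rates.bands, rates.group, rates.sex)
        lt = build_life_table(
            rs, q_conversion=q_conversion, a_mode=a_mode, open_closure=open_closure
        )
        e_star[r] = lt.e[0]
    lo, hi = np.percentile(e_star, [2.5, 97.5])
    point = build_life_table(
        rates, q_conversion=q_conversion, a_mode=a_mode, open_closure=open_closure
    ).e[0]
    return LEEstimate(
        e65=float(point),
        variance=float(np.var(e_star, ddof=1)),
        ci95=(float(lo), float(hi)),
        group=rates.group,
        sex=rates.sex,
        method="bootstrap",
        meta={"reps": reps, "redraws": redraws, "seed": seed},
    )
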