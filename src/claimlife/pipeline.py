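"""End-to-end pipeline: cohort -> exposure -> person-time -> life tables.

One :class:`PipelineConfig` drives both the simulated and the file-based
path, so a full analysis is a single reproducible call.  The outputs mirror
the standard reporting surfaces of a medication/life-expectancy study:
per-stratum life-expectancy estimates with CIs, a row-minus-column
difference matrix with significance flags, expected-survival curves, and
direct age-standardized mortality rates.  A JSON manifest echoes every
setting used, the seed, package/library versions and any warnings (e.g.
zero-death bands), which is sufficient to reproduce a run exactly.
"""

from __future__ import annotations

import datetime as _dt
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Literal, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .exposure import (
    DEFAULT_DRUG_MAP,
    GROUPS,
    DrugClassMap,
    assign_exposure_intervals,
    build_drug_episodes,
    classify_subtypes,
)
from .io import read_persons, read_prescriptions, read_surgeries, read_visits
from .lifetable import (
    LEEstimate,
    bootstrap_ci,
    build_life_table,
    le_difference,
    life_expectancy,
    mortality_rates,
    survival_curve,
)
from .person_time import AGE_BANDS, apply_surgery_censoring, compute_follow_ups, tabulate
from .standardization import prevalent_snapshot, reference_weights, standardized_rate
from .synthetic import CohortBundle, SimulationConfig, generate_cohort

__all__ = [
    "LifetableOptions",
    "PipelineConfig",
    "ReportBundle",
    "run_pipeline",
    "write_report",
    "load_config",
    "expected_age_at_death",
    "difference_matrix",
    "le_differences_table",
    "make_figures",
]


class LifetableOptions(BaseModel):
    q_conversion: Literal["chiang", "exponential"] = "chiang"
    a_mode: Literal["midpoint", "constant_hazard"] = "midpoint"
    open_closure: str = "exponential"
    ci_method: Literal["analytic", "bootstrap"] = "analytic"
    bootstrap_reps: int = Field(default=1000, ge=200)


class PipelineConfig(BaseModel):
    """Configuration for a full run (exactly one input source)."""

    simulation: Optional[SimulationConfig] = None
    input_dir: Optional[str] = None
    drug_map_path: Optional[str] = None
    study_start: _dt.date = _dt.date(1997, 7, 1)
    study_end: _dt.date = _dt.date(2017, 6, 30)
    censor_surgery: bool = False
    subtype_filter: Literal["all", "CD", "UC"] = "all"
    lifetable: LifetableOptions = Field(default_factory=LifetableOptions)
    standardization_ci: Literal["gamma", "normal"] = "gamma"
    reference_date: _dt.date = _dt.date(2016, 7, 1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if (self.simulation is None) == (self.input_dir is None):
            raise ValueError("exactly one of simulation/input_dir must be given")
        return self


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.model_validate(yaml.safe_load(fh))


@dataclass
class ReportBundle:
    """All tabular outputs of one pipeline run."""

    cells: pd.DataFrame
    life_tables: pd.DataFrame
    le_estimates: pd.DataFrame
    le_differences: pd.DataFrame
    survival_curves: pd.DataFrame
    standardized_rates: pd.DataFrame
    exposure: pd.DataFrame
    follow_ups: pd.DataFrame
    manifest: dict
    estimates: Dict[Tuple[str, str], LEEstimate] = field(default_factory=dict)


def expected_age_at_death(le) -> float:
    """Age a 65-year-old can expect to reach: 65 + e65, one decimal."""
    e65 = le.e65 if isinstance(le, LEEstimate) else float(le)
    return round(65.0 + e65, 1)


def le_differences_table(estimates: Mapping[str, LEEstimate], order=GROUPS) -> pd.DataFrame:
    """Tidy pairwise differences (row minus column) for one sex."""
    rows = []
    present = [g for g in order if g in estimates]
    for ga in present:
        for gb in present:
            if ga == gb:
                continue
            d = le_difference(estimates[ga], estimates[gb])
            rows.append(
                {
                    "group_row": ga,
                    "group_col": gb,
                    "delta": d.delta,
                    "ci_low": d.ci95[0],
                    "ci_high": d.ci95[1],
                    "significant": d.significant,
                }
            )
    return pd.DataFrame(rows)


def difference_matrix(estimates: Mapping[str, LEEstimate], order=GROUPS) -> pd.DataFrame:
    """Row-minus-column matrix of formatted differences.

    Entries read ``delta (lo, hi)`` with ``*`` marking CIs excluding 0; the
    diagonal is suppressed.
    """
    present = [g for g in order if g in estimates]
    mat = pd.DataFrame(index=present, columns=present, dtype=object)
    for ga in present:
        for gb in present:
            if ga == gb:
                mat.loc[ga, gb] = ""
                continue
            d = le_difference(estimates[ga], estimates[gb])
            star = "*" if d.significant else ""
            mat.loc[ga, gb] = f"{d.delta:.1f} ({d.ci95[0]:.1f}, {d.ci95[1]:.1f}){star}"
    return mat


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = config.simulation.model_copy(update={"seed": config.seed})
        bundle = generate_cohort(sim)
        window = (sim.study_start, sim.study_end)
        drug_map = DEFAULT_DRUG_MAP
    else:
        d = Path(config.input_dir)
        persons = read_persons(d / "persons.csv")
        bundle = CohortBundle(
            persons=persons,
            prescriptions=read_prescriptions(d / "prescriptions.csv", persons),
            surgeries=read_surgeries(d / "surgeries.csv", persons),
            visits=read_visits(d / "visits.csv", persons),
            truth={},
        )
        window = (config.study_start, config.study_end)
        drug_map = DEFAULT_DRUG_MAP
    if config.drug_map_path:
        drug_map = DrugClassMap.from_csv(config.drug_map_path)
    return bundle, window, drug_map


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full analysis; deterministic given config (incl. seed)."""
    warnings: list[str] = []
    bundle, (study_start, study_end), drug_map = _load_inputs(config)
    persons = bundle.persons

    if config.subtype_filter != "all":
        subtype = classify_subtypes(bundle.visits)
        keep = subtype[subtype == config.subtype_filter].index
        persons = persons[persons["person_id"].isin(keep)].reset_index(drop=True)

    follow_ups = compute_follow_ups(persons, study_start, study_end)
    if config.censor_surgery:
        follow_ups = apply_surgery_censoring(follow_ups, bundle.surgeries)

    rx = bundle.prescriptions
    if not rx.empty:
        rx = rx[rx["person_id"].isin(set(follow_ups["person_id"]))]
    coverage = build_drug_episodes(rx, drug_map)
    exposure = assign_exposure_intervals(coverage, follow_ups)
    cells = tabulate(exposure, follow_ups, persons)

    opts = config.lifetable
    estimates: Dict[Tuple[str, str], LEEstimate] = {}
    lt_frames, curve_rows, asr_rows = [], [], []
    try:
        weights = reference_weights(
            prevalent_snapshot(persons, follow_ups, config.reference_date)
        )
    except ValueError as exc:
        weights = None
        warnings.append(f"standardization skipped: {exc}")

    for (group, sex), df in cells.groupby(["group", "sex"]):
        try:
            rates = mortality_rates(df, group=group, sex=sex)
        except ValueError as exc:
            warnings.append(f"stratum {group}/{sex} skipped: {exc}")
            continue
        zero_bands = [b for b, d in zip(rates.bands, rates.deaths) if d == 0]
        if zero_bands:
            warnings.append(
                f"stratum {group}/{sex}: zero deaths in bands {zero_bands} "
                "(their q-variance contribution is 0, CI may be narrow)"
            )
        try:
            lt = build_life_table(
                rates,
                q_conversion=opts.q_conversion,
                a_mode=opts.a_mode,
                open_closure=opts.open_closure,
            )
        except ValueError as exc:
            warnings.append(f"stratum {group}/{sex} skipped: {exc}")
            continue
        if opts.ci_method == "bootstrap":
            est = bootstrap_ci(
                rates,
                reps=opts.bootstrap_reps,
                seed=config.seed + 1,
                q_conversion=opts.q_conversion,
                a_mode=opts.a_mode,
                open_closure=opts.open_closure,
            )
        else:
            est = life_expectancy(lt)
        estimates[(group, sex)] = est
        lt_frames.append(lt.to_frame().assign(group=group, sex=sex))
        for age, alive in survival_curve(lt):
            curve_rows.append({"group": group, "sex": sex, "age": age, "proportion_alive": alive})
        if weights is not None:
            asr = standardized_rate(
                rates, weights[weights["sex"] == sex], method=config.standardization_ci
            )
            asr_rows.append(
                {
                    "group": group,
                    "sex": sex,
                    "rate_per_1000py": asr.rate,
                    "ci_low": asr.ci95[0],
                    "ci_high": asr.ci95[1],
                    "method": asr.method,
                }
            )

    le_rows = [
        {
            "group": g,
            "sex": s,
            "e65": est.e65,
            "se": est.se,
            "ci_low": est.ci95[0],
            "ci_high": est.ci95[1],
            "expected_age_at_death": expected_age_at_death(est),
            "method": est.method,
        }
        for (g, s), est in estimates.items()
    ]
    diff_frames = []
    for sex in sorted({s for _, s in estimates}):
        by_group = {g: est for (g, s), est in estimates.items() if s == sex}
        tidy = le_differences_table(by_group)
        if len(tidy):
            diff_frames.append(tidy.assign(sex=sex))

    manifest = {
        "package": "claimlife",
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "warnings": warnings,
        "environment": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    return ReportBundle(
        cells=cells,
        life_tables=pd.concat(lt_frames, ignore_index=True) if lt_frames else pd.DataFrame(),
        le_estimates=pd.DataFrame(le_rows),
        le_differences=pd.concat(diff_frames, ignore_index=True) if diff_frames else pd.DataFrame(),
        survival_curves=pd.DataFrame(curve_rows),
        standardized_rates=pd.DataFrame(asr_rows),
        exposure=exposure,
        follow_ups=follow_ups,
        manifest=manifest,
        estimates=estimates,
    )


def write_report(report: ReportBundle, outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.cells.to_csv(out / "person_time.csv", index=False)
    report.life_tables.to_csv(out / "life_tables.csv", index=False)
    report.le_estimates.to_csv(out / "le_estimates.csv", index=False)
    report.le_differences.to_csv(out / "le_differences.csv", index=False)
    report.survival_curves.to_csv(out / "survival_curves.csv", index=False)
    report.standardized_rates.to_csv(out / "standardized_rates.csv", index=False)
    report.exposure.to_csv(out / "exposure_intervals.csv", index=False, date_format="%Y-%m-%d")
    report.follow_ups.to_csv(out / "follow_ups.csv", index=False, date_format="%Y-%m-%d")
    (out / "manifest.json").write_text(json.dumps(report.manifest, indent=2, sort_keys=True))
    return out


def make_figures(results_dir, outdir=None) -> list:
    """Optional plots from a written report: LE bars with CIs, expected
    survival curves, and standardized-rate bars, one panel per sex."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = Path(results_dir)
    out = Path(outdir) if outdir else results
    out.mkdir(parents=True, exist_ok=True)
    written = []

    le = pd.read_csv(results / "le_estimates.csv")
    curves = pd.read_csv(results / "survival_curves.csv")
    asr = pd.read_csv(results / "standardized_rates.csv")

    def _per_sex(df, fname, plot_fn, ylabel):
        sexes = sorted(df["sex"].unique())
        fig, axes = plt.subplots(1, max(len(sexes), 1), figsize=(6 * max(len(sexes), 1), 4.5), squeeze=False)
        for ax, sex in zip(axes[0], sexes):
            plot_fn(ax, df[df["sex"] == sex])
            ax.set_title(f"sex = {sex}")
            ax.set_ylabel(ylabel)
        fig.tight_layout()
        path = out / fname
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    def _le_bars(ax, df):
        df = df.set_index("group").reindex([g for g in GROUPS if g in set(df["group"])])
        err = np.vstack([df["e65"] - df["ci_low"], df["ci_high"] - df["e65"]])
        ax.bar(df.index, df["e65"], yerr=err, capsize=3)
        ax.tick_params(axis="x", rotation=45)

    def _curves(ax, df):
        for group, gdf in df.groupby("group"):
            ax.step(gdf["age"], gdf["proportion_alive"], where="post", label=group)
        ax.set_xlabel("age (years)")
        ax.legend(fontsize=7)

    def _asr_bars(ax, df):
        df = df.set_index("group").reindex([g for g in GROUPS if g in set(df["group"])])
        err = np.vstack([df["rate_per_1000py"] - df["ci_low"], df["ci_high"] - df["rate_per_1000py"]])
        ax.bar(df.index, df["rate_per_1000py"], yerr=err, capsize=3)
        ax.tick_params(axis="x", rotation=45)

    if len(le):
        _per_sex(le, "life_expectancy.png", _le_bars, "life expectancy at 65 (years)")
    if len(curves):
        _per_sex(curves, "survival_curves.png", _curves, "expected proportion alive")
    if len(asr):
        _per_sex(asr, "standardized_rates.png", _asr_bars, "deaths per 1000 person-years")
    return written
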