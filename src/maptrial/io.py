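"""Delimited-table readers/writers and the end-to-end analysis pipeline.

Three tables carry a trial dataset:

* cohort — one row per patient (site, arm, clocks, baselines, event days)
* vitals — long table of 4-hourly MAP / NE-equivalent dose (hours from T0)
* labs   — long table of daily peak creatinine and RRT flags

plus an optional historical BP-readings table for pre-illness MAP
estimation.  All tables are plain CSV; column names are stable constants.
"""

from __future__ import annotations

import logging
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import LMMSpec, daily_group_means, fit_lmm, summarize_groups
from .eligibility import BPReading, ReadingSource
from .exposure import MAPObservation, MAPSeries, summarize_exposure
from .renal import CreatinineSeries, assess_renal_outcome

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "patient_id", "site", "arm", "age", "sex", "apache3", "shock_type", "t0",
    "randomization_delay_h", "pre_illness_map", "baseline_creatinine_umol_l",
    "creatinine_at_randomization_umol_l", "death_day", "rrt_start_day",
    "icu_discharge_day",
]
VITALS_COLUMNS = ["patient_id", "t_hours", "map_mmHg", "ne_dose_ug_kg_min"]
LABS_COLUMNS = ["patient_id", "day_index", "peak_creatinine_umol_l", "rrt"]
READINGS_COLUMNS = ["patient_id", "timestamp", "sbp", "dbp", "source"]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df


def read_vitals(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(VITALS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"vitals table missing columns: {sorted(missing)}")
    return df


def read_labs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LABS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"labs table missing columns: {sorted(missing)}")
    return df


def read_bp_readings(path: str | Path) -> dict[str, list[BPReading]]:
    """Historical BP readings grouped by patient."""
    df = pd.read_csv(path)
    missing = set(READINGS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"readings table missing columns: {sorted(missing)}")
    out: dict[str, list[BPReading]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.patient_id), []).append(
            BPReading(
                timestamp=datetime.fromisoformat(row.timestamp),
                systolic=float(row.sbp),
                diastolic=float(row.dbp),
                source=ReadingSource(row.source),
            )
        )
    return out


def series_from_vitals(vitals: pd.DataFrame, patient_id: str) -> MAPSeries:
    """Build a MAPSeries for one patient from the vitals long table.

    Rows with a missing MAP keep their slot excluded (the threshold metrics
    treat the adjacent intervals as unclassifiable), implemented by
    dropping the row: the time gap it leaves behind is what the metrics
    key on.
    """
    grp = vitals[vitals["patient_id"] == patient_id].sort_values("t_hours")
    observations = []
    for row in grp.itertuples():
        if pd.isna(row.map_mmHg):
            logger.info("excluded missing MAP at t=%s h for %s", row.t_hours, patient_id)
            continue
        dose = None if pd.isna(row.ne_dose_ug_kg_min) else float(row.ne_dose_ug_kg_min)
        observations.append(
            MAPObservation(t=float(row.t_hours), map=float(row.map_mmHg), ne_dose=dose)
        )
    return MAPSeries(patient_id=patient_id, observations=tuple(observations))


def creatinine_from_tables(
    cohort_row: pd.Series, labs: pd.DataFrame
) -> CreatinineSeries:
    grp = labs[labs["patient_id"] == cohort_row["patient_id"]]
    daily = {
        int(r.day_index): float(r.peak_creatinine_umol_l)
        for r in grp.itertuples()
        if not pd.isna(r.peak_creatinine_umol_l)
    }
    rrt_days = [int(r.day_index) for r in grp.itertuples() if r.rrt == 1]

    def _day(col: str) -> int | None:
        v = cohort_row.get(col)
        return None if pd.isna(v) else int(v)

    rrt_start = _day("rrt_start_day")
    if rrt_start is None and rrt_days:
        rrt_start = min(rrt_days)
    return CreatinineSeries(
        baseline=float(cohort_row["baseline_creatinine_umol_l"]),
        at_randomization=float(cohort_row["creatinine_at_randomization_umol_l"]),
        daily_peaks=daily,
        rrt_start_day=rrt_start,
        death_day=_day("death_day"),
        icu_discharge_day=_day("icu_discharge_day"),
    )


def compute_exposure_table(cohort: pd.DataFrame, vitals: pd.DataFrame) -> pd.DataFrame:
    """Per-patient exposure summary (one row per patient)."""
    rows = []
    for row in cohort.itertuples():
        series = series_from_vitals(vitals, row.patient_id)
        if not series.observations:
            logger.warning("no vitals for %s; skipped", row.patient_id)
            continue
        s = summarize_exposure(series, float(row.pre_illness_map))
        rows.append(
            {
                "patient_id": row.patient_id,
                "arm": row.arm,
                "twa_map_deficit": s.twa_map_deficit,
                "pct_time_deficit_gt20": s.pct_time_deficit_gt20,
                "pct_time_map_lt65": s.pct_time_map_lt65,
                "achieved_map": s.achieved_map,
                "total_observed_hours": s.total_observed_hours,
            }
        )
    return pd.DataFrame(rows)


def compute_renal_table(cohort: pd.DataFrame, labs: pd.DataFrame) -> pd.DataFrame:
    """Per-patient renal endpoint panel."""
    rows = []
    for _, row in cohort.iterrows():
        outcome = assess_renal_outcome(creatinine_from_tables(row, labs))
        rows.append(
            {
                "patient_id": row["patient_id"],
                "arm": row["arm"],
                "make14": outcome.make14,
                "new_significant_aki": outcome.new_significant_aki,
                "death_14d": outcome.death,
                "new_rrt_14d": outcome.new_rrt,
                "creatinine_doubling": outcome.doubling,
                "peak_creatinine_increase_pct": outcome.peak_creatinine_increase_pct,
                "peak_stage_shift": outcome.peak_stage_shift,
            }
        )
    return pd.DataFrame(rows)


def daily_long_table(cohort: pd.DataFrame, vitals: pd.DataFrame) -> pd.DataFrame:
    """Patient-day long table of exposure outcomes for repeated-measures models."""
    pre_map = dict(zip(cohort["patient_id"], cohort["pre_illness_map"]))
    arm = dict(zip(cohort["patient_id"], cohort["arm"]))
    delay = dict(zip(cohort["patient_id"], cohort["randomization_delay_h"]))
    v = vitals.dropna(subset=["map_mmHg"]).copy()
    v["day"] = (v["t_hours"] // 24).astype(int) + 1
    rows = []
    for (pid, day), grp in v.groupby(["patient_id", "day"], sort=True):
        maps = grp["map_mmHg"].to_numpy(dtype=float)
        doses = grp["ne_dose_ug_kg_min"].to_numpy(dtype=float)
        deficit = 100.0 * (pre_map[pid] - maps) / pre_map[pid]
        rows.append(
            {
                "patient_id": pid,
                "day": day,
                "treatment": int(arm[pid] == "individualized"),
                "days_t0_to_randomization": delay[pid] / 24.0,
                "days_since_randomization": day - 1 - delay[pid] / 24.0,
                "pct_deficit": float(deficit.mean()),
                "achieved_map": float(maps.mean()),
                "vasopressor_dose": float(np.nanmean(doses)) if np.any(~np.isnan(doses)) else np.nan,
                "daily_highest": float(maps.max()),
                "daily_lowest": float(maps.min()),
            }
        )
    return pd.DataFrame(rows)


def run_trial_analysis(
    cohort: pd.DataFrame,
    vitals: pd.DataFrame,
    labs: pd.DataFrame,
    fit_mixed_models: bool = True,
) -> dict[str, pd.DataFrame]:
    """Full analysis pass over one dataset.

    Returns the exposure summary, renal panel, two-arm outcome comparison
    table, daily group means of the modeled outcomes, and (optionally) the
    mixed-model coefficient table for percentage MAP-deficit.
    """
    exposure = compute_exposure_table(cohort, vitals)
    renal = compute_renal_table(cohort, labs)
    merged = exposure.merge(renal.drop(columns=["arm"]), on="patient_id")
    outcomes = summarize_groups(
        merged,
        arm_col="arm",
        binary_cols=["death_14d", "make14", "new_significant_aki", "new_rrt_14d"],
        continuous_cols=[
            "twa_map_deficit",
            "pct_time_deficit_gt20",
            "pct_time_map_lt65",
            "achieved_map",
            "peak_creatinine_increase_pct",
        ],
        arms=("standard", "individualized"),
    )
    long = daily_long_table(cohort, vitals)
    daily = daily_group_means(
        long.assign(arm=np.where(long["treatment"] == 1, "individualized", "standard")),
        outcome="pct_deficit",
    )
    results = {
        "exposure": exposure,
        "renal": renal,
        "outcomes": outcomes,
        "daily_means": daily,
    }
    if fit_mixed_models:
        results["lmm_pct_deficit"] = fit_lmm(long, LMMSpec(outcome="pct_deficit"))
    return results
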