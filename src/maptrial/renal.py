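"""Renal outcomes: KDIGO staging, new significant AKI, and MAKE-14.

Staging follows the creatinine/RRT arms of the KDIGO acute-kidney-injury
criteria (urine-output criteria are out of scope at daily chart resolution):

* stage 3 — on RRT, or creatinine >= 3.0x baseline, or >= 353.6 umol/l
* stage 2 — creatinine >= 2.0x baseline
* stage 1 — creatinine >= 1.5x baseline, or an absolute rise >= 26.5 umol/l

With only daily peak creatinines, the 48-h window of the absolute-rise
criterion is approximated by comparing adjacent-day peaks.

MAKE-14 (major adverse kidney events by day 14) is the composite of death,
new renal replacement therapy, or doubling of creatinine from the
pre-morbid baseline at day 14 (or ICU discharge, whichever is earlier).
"New significant AKI" is a peak KDIGO stage shift of at least two from the
stage at randomization, within 14 days of vasopressor start.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

from .errors import ContractError

__all__ = [
    "BaselineSource",
    "CreatinineSeries",
    "RenalOutcome",
    "Sex",
    "assess_renal_outcome",
    "daily_kdigo_stages",
    "estimate_baseline_creatinine",
    "kdigo_stage",
    "make14",
    "new_significant_aki",
    "peak_creatinine_increase",
]

#: KDIGO stage-3 absolute creatinine threshold (umol/l; 4.0 mg/dl).
STAGE3_ABSOLUTE_UMOL_L = 353.6

#: KDIGO stage-1 absolute-rise threshold (umol/l; 0.3 mg/dl).
STAGE1_RISE_UMOL_L = 26.5

#: mg/dl -> umol/l conversion for creatinine.
MGDL_TO_UMOLL = 88.4

#: Assumed eGFR (ml/min/1.73 m^2) when back-estimating a missing baseline.
ASSUMED_EGFR = 75.0


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class BaselineSource(str, enum.Enum):
    PREMORBID_12MO = "premorbid-12mo"
    IN_HOSPITAL_7D_BEFORE_ICU = "in-hospital-7d-before-icu"
    KDIGO_ESTIMATED = "kdigo-estimated"


def estimate_baseline_creatinine(
    age: float,
    sex: Sex | str,
    measured: float | None = None,
    measured_source: BaselineSource = BaselineSource.PREMORBID_12MO,
) -> tuple[float, BaselineSource]:
    """Baseline creatinine (umol/l): measured if available, else estimated.

    When no pre-morbid measurement exists the baseline is back-calculated
    from the MDRD equation (coefficient 175, no race term) at an assumed
    eGFR of 75 ml/min/1.73 m^2, the KDIGO convention:

        eGFR = 175 * Scr^-1.154 * age^-0.203 * (0.742 if female)

    solved for Scr in mg/dl and converted to umol/l.
    """
    if measured is not None:
        return float(measured), measured_source
    sex = Sex(sex)
    factor = 175.0 * age ** -0.203 * (0.742 if sex is Sex.FEMALE else 1.0)
    scr_mgdl = (factor / ASSUMED_EGFR) ** (1.0 / 1.154)
    return scr_mgdl * MGDL_TO_UMOLL, BaselineSource.KDIGO_ESTIMATED


def kdigo_stage(baseline: float, current: float, on_rrt: bool = False) -> int:
    """KDIGO AKI stage (0-3) from baseline and current creatinine (umol/l)."""
    if baseline <= 0 or current <= 0:
        raise ContractError("creatinine values must be positive")
    if on_rrt or current >= 3.0 * baseline or current >= STAGE3_ABSOLUTE_UMOL_L:
        return 3
    if current >= 2.0 * baseline:
        return 2
    if current >= 1.5 * baseline or (current - baseline) >= STAGE1_RISE_UMOL_L:
        return 1
    return 0


@dataclass(frozen=True)
class CreatinineSeries:
    """Creatinine trajectory and renal events for one patient.

    ``daily_peaks`` maps the day index (1-based from T0) to the peak
    creatinine of that day in umol/l; event days use the same clock.
    """

    baseline: float
    at_randomization: float
    daily_peaks: dict[int, float] = field(default_factory=dict)
    baseline_source: BaselineSource = BaselineSource.PREMORBID_12MO
    rrt_start_day: int | None = None
    death_day: int | None = None
    icu_discharge_day: int | None = None

    def __post_init__(self) -> None:
        if self.baseline <= 0 or self.at_randomization <= 0:
            raise ContractError("creatinine values must be positive")
        if any(v <= 0 for v in self.daily_peaks.values()):
            raise ContractError("daily peak creatinines must be positive")


@dataclass(frozen=True)
class RenalOutcome:
    """Derived renal endpoints for one patient."""

    daily_stage: dict[int, int]
    peak_stage_shift: int
    new_significant_aki: bool
    make14: bool
    death: bool
    new_rrt: bool
    doubling: bool
    peak_creatinine_increase_pct: float | None


def daily_kdigo_stages(series: CreatinineSeries, horizon: int = 14) -> dict[int, int]:
    """KDIGO stage per observed day within the horizon.

    Stages are computed against the fixed pre-morbid baseline; days on RRT
    are stage 3.  The absolute-rise stage-1 criterion additionally compares
    adjacent-day peaks (the daily-resolution stand-in for its 48-h window).
    """
    stages: dict[int, int] = {}
    days = sorted(d for d in series.daily_peaks if 1 <= d <= horizon)
    for day in days:
        on_rrt = series.rrt_start_day is not None and day >= series.rrt_start_day
        stage = kdigo_stage(series.baseline, series.daily_peaks[day], on_rrt)
        if stage == 0 and (day - 1) in series.daily_peaks:
            if series.daily_peaks[day] - series.daily_peaks[day - 1] >= STAGE1_RISE_UMOL_L:
                stage = 1
        stages[day] = stage
    if series.rrt_start_day is not None and series.rrt_start_day <= horizon:
        # RRT days are stage 3 even without a charted creatinine
        for day in range(series.rrt_start_day, horizon + 1):
            stages.setdefault(day, 3)
    return stages


def new_significant_aki(series: CreatinineSeries, horizon: int = 14) -> bool:
    """Peak KDIGO stage shift >=2 from the randomization-day stage."""
    entry_stage = kdigo_stage(series.baseline, series.at_randomization)
    stages = daily_kdigo_stages(series, horizon)
    if not stages:
        return False
    return max(stages.values()) - entry_stage >= 2


def make14(series: CreatinineSeries, horizon: int = 14) -> RenalOutcome:
    """MAKE-14 composite and its components.

    Doubling is assessed against the pre-morbid baseline using the last
    daily peak at or before min(day 14, ICU discharge day).
    """
    death = series.death_day is not None and series.death_day <= horizon
    new_rrt = series.rrt_start_day is not None and series.rrt_start_day <= horizon
    assess_day = horizon
    if series.icu_discharge_day is not None:
        assess_day = min(assess_day, series.icu_discharge_day)
    at_or_before = [d for d in series.daily_peaks if 1 <= d <= assess_day]
    doubling = False
    if at_or_before:
        doubling = series.daily_peaks[max(at_or_before)] >= 2.0 * series.baseline
    elif not (death or new_rrt):
        warnings.warn(
            "no creatinine at the assessment day and no other MAKE component; "
            "doubling recorded as absent",
            stacklevel=2,
        )
    stages = daily_kdigo_stages(series, horizon)
    entry_stage = kdigo_stage(series.baseline, series.at_randomization)
    shift = max((max(stages.values()) - entry_stage), 0) if stages else 0
    return RenalOutcome(
        daily_stage=stages,
        peak_stage_shift=shift,
        new_significant_aki=shift >= 2,
        make14=death or new_rrt or doubling,
        death=death,
        new_rrt=new_rrt,
        doubling=doubling,
        peak_creatinine_increase_pct=peak_creatinine_increase(series, horizon),
    )


def peak_creatinine_increase(
    series: CreatinineSeries, horizon: int = 14
) -> float | None:
    """Percent peak creatinine rise over the randomization value.

    Defined only for patients without RRT within the horizon (None
    otherwise, and None when no daily peak was charted).  Negative values
    are possible and are not clamped.
    """
    if series.at_randomization <= 0:
        raise ContractError("creatinine at randomization must be positive")
    if series.rrt_start_day is not None and series.rrt_start_day <= horizon:
        return None
    peaks = [v for d, v in series.daily_peaks.items() if 1 <= d <= horizon]
    if not peaks:
        return None
    return 100.0 * (max(peaks) - series.at_randomization) / series.at_randomization


def assess_renal_outcome(series: CreatinineSeries, horizon: int = 14) -> RenalOutcome:
    """Full renal endpoint panel for one patient (alias of :func:`make14`)."""
    return make14(series, horizon)
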