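"""Screening, pre-illness MAP estimation, and MAP-target assignment.

The individualized-target strategy anchors each patient's vasopressor MAP
target to their own usual (pre-illness) mean arterial pressure, estimated
from 2-5 historical cuff readings taken while the patient was in usual
health.  The control strategy targets the conventional default of 65 mmHg.
This module implements the screening rules, the reading-selection and
averaging procedure, and the arm-specific target band.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timedelta

from .errors import ContractError, InsufficientReadingsError, InvalidReadingError

__all__ = [
    "Arm",
    "BPReading",
    "ExclusionFlag",
    "PreIllnessProfile",
    "ReadingSource",
    "ScreeningDecision",
    "ScreeningRecord",
    "TargetBand",
    "assign_target",
    "estimate_preillness_map",
    "map_from_bp",
    "screen_eligibility",
    "select_preillness_readings",
]

#: Readings must be at least this far apart to count as independent.
MIN_READING_SPACING = timedelta(hours=12)

#: Look-back horizon for usual-health readings (3 years).
READING_LOOKBACK = timedelta(days=3 * 365.25)

#: Individualized targets are clamped to this range (mmHg).
TARGET_FLOOR = 55.0
TARGET_CEILING = 95.0

#: Control-arm default target (mmHg).
STANDARD_DEFAULT_TARGET = 65.0

#: Half-width of the individualized target band (mmHg).
BAND_HALF_WIDTH = 2.0


class ReadingSource(str, enum.Enum):
    """Where a historical BP reading was charted.

    Clinic-type sources are preferred; observation charts from the last 48 h
    of a prior hospitalization are a fallback used only when clinic-type
    readings cannot supply the minimum of two.
    """

    AMBULATORY = "ambulatory"
    OUTPATIENT_CLINIC = "outpatient-clinic"
    PRE_ADMISSION = "pre-admission"
    ECHO_CLINIC = "echo-clinic"
    PRIOR_HOSPITALIZATION = "prior-hospitalization-last-48h"


CLINIC_SOURCES = frozenset(
    {
        ReadingSource.AMBULATORY,
        ReadingSource.OUTPATIENT_CLINIC,
        ReadingSource.PRE_ADMISSION,
        ReadingSource.ECHO_CLINIC,
    }
)


class Arm(str, enum.Enum):
    STANDARD = "standard"
    INDIVIDUALIZED = "individualized"


class ExclusionFlag(str, enum.Enum):
    MORIBUND = "moribund"
    RRT_CURRENT_OR_IMMINENT = "rrt_current_or_imminent"
    CREATININE_RISE_GT_350 = "creatinine_rise_gt_350"
    ESRD = "esrd"
    VASOPRESSOR_OLDER_THAN_24H = "vasopressor_older_than_24h"
    TRAUMA = "trauma"
    PREGNANCY = "pregnancy"
    ACTIVE_BLEEDING = "active_bleeding"
    INSUFFICIENT_BP_READINGS = "insufficient_bp_readings"
    ECMO = "ecmo"
    BP_TARGET_CONTRAINDICATION = "bp_target_contraindication"


def map_from_bp(systolic: float, diastolic: float) -> float:
    """Mean arterial pressure from a systolic/diastolic cuff reading.

    MAP = diastolic + (systolic - diastolic) / 3, unrounded.

    Raises
    ------
    InvalidReadingError
        If either pressure is non-positive or systolic does not exceed
        diastolic.
    """
    if diastolic <= 0 or systolic <= 0:
        raise InvalidReadingError(
            f"pressures must be positive, got {systolic}/{diastolic}"
        )
    if systolic <= diastolic:
        raise InvalidReadingError(
            f"systolic must exceed diastolic, got {systolic}/{diastolic}"
        )
    return diastolic + (systolic - diastolic) / 3.0


@dataclass(frozen=True)
class BPReading:
    """One historical blood-pressure observation."""

    timestamp: datetime
    systolic: float
    diastolic: float
    source: ReadingSource = ReadingSource.OUTPATIENT_CLINIC

    def __post_init__(self) -> None:
        if not (20.0 < self.diastolic < 300.0) or not (20.0 < self.systolic < 300.0):
            raise InvalidReadingError(
                f"pressures out of range: {self.systolic}/{self.diastolic}"
            )
        if self.systolic <= self.diastolic:
            raise InvalidReadingError(
                f"systolic must exceed diastolic: {self.systolic}/{self.diastolic}"
            )

    @property
    def map(self) -> float:
        return map_from_bp(self.systolic, self.diastolic)


@dataclass(frozen=True)
class PreIllnessProfile:
    """Selected readings and their mean MAP."""

    readings: tuple[BPReading, ...]
    pre_illness_map: float


def _greedy_select(pool: list[BPReading], limit: int = 5) -> list[BPReading]:
    # Most recent first; keep a reading only if >=12 h from every kept one.
    kept: list[BPReading] = []
    for reading in sorted(pool, key=lambda r: r.timestamp, reverse=True):
        if all(
            abs(reading.timestamp - k.timestamp) >= MIN_READING_SPACING for k in kept
        ):
            kept.append(reading)
            if len(kept) == limit:
                break
    return kept


def select_preillness_readings(
    candidates: list[BPReading] | tuple[BPReading, ...],
    screening_time: datetime,
) -> tuple[BPReading, ...]:
    """Pick up to 5 usual-health readings for the pre-illness MAP estimate.

    Readings must fall within the 3-year look-back before ``screening_time``
    and be pairwise >=12 h apart; selection is greedy from the most recent
    reading backwards.  Clinic-type sources are used first; readings from the
    last 48 h of a prior hospitalization are consulted only when fewer than
    two clinic-type readings qualify.

    Raises
    ------
    InsufficientReadingsError
        If no pool yields at least two qualifying readings.
    """
    in_window = [
        r
        for r in candidates
        if screening_time - READING_LOOKBACK <= r.timestamp <= screening_time
    ]
    clinic = [r for r in in_window if r.source in CLINIC_SOURCES]
    selected = _greedy_select(clinic)
    if len(selected) < 2:
        hospital = [
            r for r in in_window if r.source == ReadingSource.PRIOR_HOSPITALIZATION
        ]
        selected = _greedy_select(hospital)
    if len(selected) < 2:
        raise InsufficientReadingsError(
            f"only {len(selected)} qualifying pre-morbid BP reading(s); need >=2"
        )
    return tuple(selected)


def estimate_preillness_map(
    readings: list[BPReading] | tuple[BPReading, ...],
) -> PreIllnessProfile:
    """Pre-illness MAP as the unweighted mean of per-reading MAPs."""
    if not 2 <= len(readings) <= 5:
        raise ContractError(f"need 2-5 readings, got {len(readings)}")
    maps = [r.map for r in readings]
    return PreIllnessProfile(
        readings=tuple(readings), pre_illness_map=sum(maps) / len(maps)
    )


@dataclass(frozen=True)
class ScreeningRecord:
    """Eligibility-relevant facts about a screened patient.

    Optional supporting criteria that were not measured count as not met
    (screening proceeds on partial data).
    """

    age: float
    vasopressor_started: bool
    lactate: float | None = None
    base_deficit: float | None = None
    urine_output_low: bool = False
    respiratory_rate: float | None = None
    gcs: int | None = None
    exclusion_flags: frozenset[ExclusionFlag] = field(default_factory=frozenset)


@dataclass(frozen=True)
class ScreeningDecision:
    eligible: bool
    failed_criteria: tuple[str, ...]


def screen_eligibility(record: ScreeningRecord) -> ScreeningDecision:
    """Apply the inclusion/exclusion rules and report every failed criterion.

    Eligible patients are aged >=40, on clinician-initiated vasopressors, have
    at least one shock-supporting criterion (lactate >=2 mmol/l, base deficit
    >=3 mmol/l, low urine output, respiratory rate >22/min, or GCS <14), and
    carry no exclusion flag.
    """
    failed: list[str] = []
    if record.age < 40:
        failed.append("age")
    if not record.vasopressor_started:
        failed.append("vasopressor")
    supporting = (
        (record.lactate is not None and record.lactate >= 2.0)
        or (record.base_deficit is not None and record.base_deficit >= 3.0)
        or record.urine_output_low
        or (record.respiratory_rate is not None and record.respiratory_rate > 22)
        or (record.gcs is not None and record.gcs < 14)
    )
    if not supporting:
        failed.append("no_supporting_criterion")
    failed.extend(sorted(flag.value for flag in record.exclusion_flags))
    return ScreeningDecision(eligible=not failed, failed_criteria=tuple(failed))


@dataclass(frozen=True)
class TargetBand:
    """Arm-specific MAP target.

    The individualized band is the clamped pre-illness MAP +/- 2 mmHg; the
    standard arm is a single default target of 65 mmHg (or a clinician
    override), represented as a degenerate band with low = high = center.
    """

    arm: Arm
    center: float
    low: float
    high: float
    clinician_override: float | None = None


def assign_target(
    arm: Arm | str,
    pre_illness_map: float | None = None,
    override: float | None = None,
) -> TargetBand:
    """Assign the MAP target band for a randomized patient.

    Standard arm: center 65 mmHg unless a clinician override is given.
    Individualized arm: center = pre-illness MAP clamped to [55, 95] mmHg,
    band = center +/- 2 mmHg (the band is applied after clamping).
    """
    arm = Arm(arm)
    if arm is Arm.STANDARD:
        center = STANDARD_DEFAULT_TARGET if override is None else float(override)
        return TargetBand(
            arm=arm, center=center, low=center, high=center, clinician_override=override
        )
    if pre_illness_map is None:
        raise ContractError("individualized arm requires a pre-illness MAP")
    center = min(max(float(pre_illness_map), TARGET_FLOOR), TARGET_CEILING)
    return TargetBand(
        arm=arm,
        center=center,
        low=center - BAND_HALF_WIDTH,
        high=center + BAND_HALF_WIDTH,
        clinician_override=override,
    )
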