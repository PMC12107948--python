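"""Relative-hypotension exposure metrics over the active treatment window.

The exposure of interest is the MAP-deficit: the percentage shortfall of the
achieved mean arterial pressure relative to the patient's pre-illness MAP,

    deficit(t) = 100 * (pre_illness_map - MAP(t)) / pre_illness_map .

Its summary over the vasopressor-treatment window is the time-weighted
average of the positive incremental area under the deficit curve: the MAP
signal is treated as piecewise-linear between 4-hourly observations, only
the positive part of the deficit is integrated (zero-crossings located
exactly within each segment), and the area is divided by the observed
duration.  Threshold-time fractions (% time with >20% deficit, % time with
MAP < 65 mmHg) classify each inter-observation interval by its left
endpoint (last observation carried forward) and exclude intervals adjacent
to a missing observation from both numerator and denominator.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, EmptySeriesError, EmptyWindowError

__all__ = [
    "DeficitBin",
    "DeficitProfile",
    "ExposureSummary",
    "MAPObservation",
    "MAPSeries",
    "NE_EQUIVALENCE",
    "achieved_map",
    "active_window",
    "daily_extremes",
    "deficit_at",
    "deficit_profile",
    "norepinephrine_equivalent",
    "pct_time_deficit_above",
    "pct_time_map_below",
    "summarize_exposure",
    "twa_map_deficit",
]

#: Nominal charting interval (hours).  An inter-observation gap larger than
#: this indicates a missing observation; such intervals are excluded from
#: threshold-time metrics.
NOMINAL_INTERVAL_H = 4.0

#: Active treatment window cap: 5 days from vasopressor start (hours).
MAX_WINDOW_H = 120.0

#: Vasopressor-free gap that terminates the window (hours).
WEANING_GAP_H = 24.0

#: Norepinephrine-equivalence factors.  Doses in ug/kg/min except
#: vasopressin, whose factor converts U/min to NE-equivalent ug/kg/min.
#: Dobutamine is an inotrope and is excluded.
NE_EQUIVALENCE: dict[str, float] = {
    "norepinephrine": 1.0,
    "epinephrine": 1.0,
    "phenylephrine": 0.1,
    "vasopressin": 2.5,
}


def norepinephrine_equivalent(
    doses: dict[str, float], table: dict[str, float] | None = None
) -> float:
    """Combine raw vasopressor doses into a norepinephrine-equivalent dose.

    Agents absent from the equivalence table (e.g. dobutamine) contribute
    nothing.  The table is overridable for site-specific conventions.
    """
    table = NE_EQUIVALENCE if table is None else table
    return sum(table.get(agent, 0.0) * dose for agent, dose in doses.items())


@dataclass(frozen=True)
class MAPObservation:
    """One 4-hourly chart observation on the study clock (hours from T0)."""

    t: float
    map: float
    ne_dose: float | None = None

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ContractError(f"observation time must be >=0 h, got {self.t}")
        if not (20.0 < self.map < 200.0):
            raise ContractError(f"MAP out of plausible range: {self.map}")
        if self.ne_dose is not None and self.ne_dose < 0:
            raise ContractError(f"NE-equivalent dose must be >=0: {self.ne_dose}")


@dataclass(frozen=True)
class MAPSeries:
    """Time-ordered MAP/vasopressor observations for one patient."""

    patient_id: str
    observations: tuple[MAPObservation, ...]
    cessation_time: float | None = None

    def __post_init__(self) -> None:
        ts = [o.t for o in self.observations]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ContractError("observation times must be strictly increasing")
        if ts and ts[-1] > MAX_WINDOW_H:
            raise ContractError(f"observations beyond the {MAX_WINDOW_H} h window")

    @property
    def times(self) -> np.ndarray:
        return np.array([o.t for o in self.observations], dtype=float)

    @property
    def maps(self) -> np.ndarray:
        return np.array([o.map for o in self.observations], dtype=float)

    @property
    def doses(self) -> np.ndarray:
        return np.array(
            [math.nan if o.ne_dose is None else o.ne_dose for o in self.observations],
            dtype=float,
        )


def active_window(
    epochs: list[tuple[float, float]] | tuple[tuple[float, float], ...],
) -> tuple[float, float]:
    """Active treatment window from vasopressor on/off epochs.

    The window starts at T0 and ends when the patient has been vasopressor
    free for at least 24 h (i.e. at the end of the last epoch not followed by
    a >=24 h gap before a restart), capped at 120 h (5 days).
    """
    if not epochs:
        raise EmptyWindowError("no vasopressor epochs")
    ordered = sorted(epochs)
    end = ordered[0][1]
    for start, stop in ordered[1:]:
        if start - end >= WEANING_GAP_H:
            break
        end = max(end, stop)
    return (0.0, min(MAX_WINDOW_H, end))


def deficit_at(pre_illness_map: float, map_value: float) -> float:
    """Signed percentage MAP-deficit relative to the pre-illness MAP.

    Negative when the achieved MAP exceeds the pre-illness MAP; clamping of
    the negative part happens only inside the time-weighted integral.
    """
    if pre_illness_map <= 0:
        raise ContractError(f"pre-illness MAP must be positive: {pre_illness_map}")
    return 100.0 * (pre_illness_map - map_value) / pre_illness_map


def _positive_area(t: np.ndarray, d: np.ndarray) -> float:
    """Integral of max(signal, 0) for a piecewise-linear signal d(t).

    Zero-crossings are located exactly within each segment rather than
    clamping the sampled values before integration.
    """
    t0, t1 = t[:-1], t[1:]
    d0, d1 = d[:-1], d[1:]
    dt = t1 - t0
    area = np.zeros_like(dt)
    both_pos = (d0 >= 0) & (d1 >= 0)
    area[both_pos] = 0.5 * (d0[both_pos] + d1[both_pos]) * dt[both_pos]
    # sign change: the positive triangle on either side of the crossing
    pos_neg = (d0 > 0) & (d1 < 0)
    area[pos_neg] = 0.5 * d0[pos_neg] ** 2 / (d0[pos_neg] - d1[pos_neg]) * dt[pos_neg]
    neg_pos = (d0 < 0) & (d1 > 0)
    area[neg_pos] = 0.5 * d1[neg_pos] ** 2 / (d1[neg_pos] - d0[neg_pos]) * dt[neg_pos]
    return float(area.sum())


def twa_map_deficit(series: MAPSeries, pre_illness_map: float) -> float:
    """Time-weighted average percentage MAP-deficit (positive iAUC).

    The deficit signal is piecewise-linear between observations; only its
    positive part is integrated, and the area is divided by the span from
    first to last observation.  A single observation returns
    max(0, deficit) at that point.
    """
    t = series.times
    valid = ~np.isnan(series.maps)
    t, m = t[valid], series.maps[valid]
    if t.size == 0:
        raise EmptySeriesError(f"no MAP observations for {series.patient_id}")
    d = np.array([deficit_at(pre_illness_map, v) for v in m])
    if t.size == 1:
        return max(0.0, float(d[0]))
    return _positive_area(t, d) / float(t[-1] - t[0])


def _classified_fraction(
    t: np.ndarray, values: np.ndarray, predicate, nominal_interval_h: float
) -> float:
    """Fraction of charted time whose left-endpoint value satisfies predicate.

    Intervals longer than the nominal charting interval (a missing
    observation) or with an unobserved endpoint are excluded from both
    numerator and denominator.  Returns NaN when no interval qualifies.
    """
    if t.size < 2:
        return math.nan
    dt = np.diff(t)
    ok = (
        (dt <= nominal_interval_h + 1e-9)
        & ~np.isnan(values[:-1])
        & ~np.isnan(values[1:])
    )
    total = float(dt[ok].sum())
    if total == 0.0:
        return math.nan
    hit = predicate(values[:-1]) & ok
    return 100.0 * float(dt[hit].sum()) / total


def pct_time_deficit_above(
    series: MAPSeries,
    pre_illness_map: float,
    threshold: float = 20.0,
    nominal_interval_h: float = NOMINAL_INTERVAL_H,
) -> float:
    """Percentage of charted time with MAP-deficit above ``threshold`` %."""
    if pre_illness_map <= 0:
        raise ContractError(f"pre-illness MAP must be positive: {pre_illness_map}")
    d = 100.0 * (pre_illness_map - series.maps) / pre_illness_map
    return _classified_fraction(
        series.times, d, lambda x: x > threshold, nominal_interval_h
    )


def pct_time_map_below(
    series: MAPSeries,
    cutoff: float = 65.0,
    nominal_interval_h: float = NOMINAL_INTERVAL_H,
) -> float:
    """Percentage of charted time with MAP below ``cutoff`` mmHg."""
    return _classified_fraction(
        series.times, series.maps, lambda x: x < cutoff, nominal_interval_h
    )


def achieved_map(series: MAPSeries) -> float:
    """Trapezoidal time-weighted average MAP over the observed span."""
    valid = ~np.isnan(series.maps)
    t, m = series.times[valid], series.maps[valid]
    if t.size == 0:
        raise EmptySeriesError(f"no MAP observations for {series.patient_id}")
    if t.size == 1:
        return float(m[0])
    return float(np.trapezoid(m, t) / (t[-1] - t[0]))


def daily_extremes(series: MAPSeries) -> tuple[dict[int, float], dict[int, float]]:
    """Per-day highest and lowest observed MAP.

    Days are consecutive 24-h windows anchored at T0 (day 1 = [0, 24) h);
    days with no observation are absent from the output.
    """
    highs: dict[int, float] = {}
    lows: dict[int, float] = {}
    for obs in series.observations:
        if math.isnan(obs.map):
            continue
        day = int(obs.t // 24) + 1
        highs[day] = max(highs.get(day, -math.inf), obs.map)
        lows[day] = min(lows.get(day, math.inf), obs.map)
    return highs, lows


class DeficitBin(str, enum.Enum):
    """MAP-deficit severity bins used in the management-profile summary."""

    LOW = "<10%"
    MID = "10-20%"
    HIGH = ">20%"


def _deficit_bin(d: float) -> DeficitBin:
    if d < 10.0:
        return DeficitBin.LOW
    if d <= 20.0:
        return DeficitBin.MID
    return DeficitBin.HIGH


@dataclass(frozen=True)
class DeficitProfile:
    """Occupancy (% of classified time) per deficit-bin x escalation cell."""

    occupancy: dict[tuple[DeficitBin, bool], float]

    def total(self) -> float:
        return sum(self.occupancy.values())


def deficit_profile(
    series: MAPSeries,
    pre_illness_map: float,
    nominal_interval_h: float = NOMINAL_INTERVAL_H,
) -> DeficitProfile:
    """Joint profile of deficit severity and vasopressor escalation.

    Each inter-observation interval is assigned the deficit bin of its left
    endpoint and an escalation flag (NE-equivalent dose strictly rising over
    the interval).  Intervals with a missing MAP or dose at either endpoint
    are excluded from both numerator and denominator.
    """
    t, m, doses = series.times, series.maps, series.doses
    occupancy = {
        (b, esc): 0.0 for b in DeficitBin for esc in (False, True)
    }
    if t.size < 2:
        return DeficitProfile(occupancy)
    dt = np.diff(t)
    ok = (
        (dt <= nominal_interval_h + 1e-9)
        & ~np.isnan(m[:-1])
        & ~np.isnan(m[1:])
        & ~np.isnan(doses[:-1])
        & ~np.isnan(doses[1:])
    )
    total = float(dt[ok].sum())
    if total == 0.0:
        return DeficitProfile(occupancy)
    for i in np.flatnonzero(ok):
        cell = (
            _deficit_bin(deficit_at(pre_illness_map, m[i])),
            bool(doses[i + 1] > doses[i]),
        )
        occupancy[cell] += 100.0 * float(dt[i]) / total
    return DeficitProfile(occupancy)


@dataclass(frozen=True)
class ExposureSummary:
    """Per-patient relative-hypotension exposure metrics."""

    patient_id: str
    twa_map_deficit: float
    pct_time_deficit_gt20: float
    pct_time_map_lt65: float
    achieved_map: float
    daily_highest_map: dict[int, float]
    daily_lowest_map: dict[int, float]
    total_observed_hours: float


def summarize_exposure(
    series: MAPSeries,
    pre_illness_map: float,
    nominal_interval_h: float = NOMINAL_INTERVAL_H,
) -> ExposureSummary:
    """Compute the full exposure summary for one patient."""
    highs, lows = daily_extremes(series)
    t = series.times[~np.isnan(series.maps)]
    span = float(t[-1] - t[0]) if t.size > 1 else 0.0
    return ExposureSummary(
        patient_id=series.patient_id,
        twa_map_deficit=twa_map_deficit(series, pre_illness_map),
        pct_time_deficit_gt20=pct_time_deficit_above(
            series, pre_illness_map, 20.0, nominal_interval_h
        ),
        pct_time_map_lt65=pct_time_map_below(series, 65.0, nominal_interval_h),
        achieved_map=achieved_map(series),
        daily_highest_map=highs,
        daily_lowest_map=lows,
        total_observed_hours=span,
    )
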