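"""Population-activity recovery durations from daily POI-visit counts.

The recovery definition follows the mobility-data convention used in
post-disaster activity studies: a unit's pre-event baseline is its mean
daily visit count over a fixed pre-event window; daily counts are
smoothed with a centered 7-day moving average; the unit counts as
recovered on the first day the smoothed series sustains at least 90% of
the baseline for 3 consecutive days. Durations are expressed in weeks
from a configurable week origin and right-censored at 14 weeks.

The discretized recovery week is ceil(duration), clamped into {2..14}:
nothing can be observed as recovered before the end of week 2 under the
weekly state encoding, and the analysis window closes at week 14.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VisitSeries",
    "RecoveryRecord",
    "CENSOR_WEEKS",
    "MIN_WEEK",
    "discretize_week",
    "compute_baseline",
    "moving_average",
    "recovery_duration",
    "filter_min_visits",
    "read_visits_csv",
    "durations_to_frame",
    "read_durations_csv",
]

CENSOR_WEEKS = 14
MIN_WEEK = 2


@dataclass
class VisitSeries:
    """Daily visit counts for one unit and one POI class."""

    unit_id: str
    poi_class: str
    dates: pd.DatetimeIndex
    visits: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.visits = np.asarray(self.visits, dtype=float)
        if len(self.dates) != len(self.visits):
            raise ValueError("dates and visits must align")
        if len(self.dates) > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]")
            if not np.all(deltas == np.timedelta64(1, "D")):
                raise ValueError("dates must be strictly increasing, daily")
        if np.any(self.visits < 0):
            raise ValueError("visits must be non-negative")


@dataclass(frozen=True)
class RecoveryRecord:
    """One unit's recovery duration (weeks) and its discretized week."""

    unit_id: str
    duration_weeks: float
    week: int
    censored: bool


def discretize_week(duration_weeks: float) -> int:
    """ceil, then clamp into {MIN_WEEK .. CENSOR_WEEKS}."""
    return int(min(max(math.ceil(duration_weeks), MIN_WEEK), CENSOR_WEEKS))


def compute_baseline(series: VisitSeries, baseline_start: date, baseline_end: date) -> float:
    """Mean daily visits over the closed [baseline_start, baseline_end] window."""
    lo, hi = pd.Timestamp(baseline_start), pd.Timestamp(baseline_end)
    mask = (series.dates >= lo) & (series.dates <= hi)
    n_expected = (hi - lo).days + 1
    if int(mask.sum()) != n_expected:
        raise ValueError(
            f"baseline window not fully covered for unit {series.unit_id!r}"
        )
    return float(series.visits[mask].mean())


def moving_average(series: VisitSeries, half_window: int = 3) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Centered moving average over [t - half_window, t + half_window].

    Days whose window extends past either end of the series are
    dropped, so the output is shorter by 2*half_window.
    """
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    w = 2 * half_window + 1
    if len(series.visits) < w:
        raise ValueError("series shorter than the full smoothing window")
    if half_window == 0:
        return series.dates, series.visits.copy()
    smoothed = np.convolve(series.visits, np.ones(w) / w, mode="valid")
    dates = series.dates[half_window:-half_window]
    return dates, smoothed


def recovery_duration(
    smoothed_dates: pd.DatetimeIndex,
    smoothed: np.ndarray,
    baseline: float,
    unit_id: str = "",
    recovery_fraction: float = 0.9,
    run_days: int = 3,
    week_origin: date | None = None,
    window_end: date | None = None,
) -> RecoveryRecord:
    """First sustained return to ``recovery_fraction`` of baseline.

    The recovery day r is the first day such that the smoothed series is
    >= recovery_fraction * baseline on days r .. r+run_days-1, searched
    within [week_origin, window_end]. duration_weeks = (r - origin + 1)/7.
    If no qualifying day exists the unit is censored at 14 weeks.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if not 0 < recovery_fraction <= 1:
        raise ValueError("recovery_fraction must be in (0, 1]")
    if run_days < 1:
        raise ValueError("run_days must be >= 1")
    origin = pd.Timestamp(week_origin) if week_origin is not None else smoothed_dates[0]
    end = pd.Timestamp(window_end) if window_end is not None else smoothed_dates[-1]

    ok = np.asarray(smoothed) >= recovery_fraction * baseline
    in_window = (smoothed_dates >= origin) & (smoothed_dates <= end)
    for i in np.nonzero(in_window)[0]:
        if i + run_days <= len(ok) and ok[i : i + run_days].all():
            r = smoothed_dates[i]
            duration = ((r - origin).days + 1) / 7.0
            return RecoveryRecord(unit_id, duration, discretize_week(duration), False)
    return RecoveryRecord(unit_id, float(CENSOR_WEEKS), CENSOR_WEEKS, True)


def filter_min_visits(
    records: Sequence[RecoveryRecord],
    series_by_unit: dict[str, VisitSeries],
    baseline_start: date,
    baseline_end: date,
    min_mean_daily_visits: float = 4.0,
) -> tuple[list[RecoveryRecord], dict[str, int]]:
    """Drop units whose baseline-window mean daily visits fall below the
    minimum. Returns the kept records and a {kept, dropped} report."""
    if min_mean_daily_visits < 0:
        raise ValueError("min_mean_daily_visits must be >= 0")
    kept, dropped = [], 0
    for rec in records:
        s = series_by_unit[rec.unit_id]
        if compute_baseline(s, baseline_start, baseline_end) >= min_mean_daily_visits:
            kept.append(rec)
        else:
            dropped += 1
    return kept, {"kept": len(kept), "dropped": dropped}


def process_visits(
    series_list: Sequence[VisitSeries],
    baseline_start: date,
    baseline_end: date,
    week_origin: date,
    window_end: date,
    recovery_fraction: float = 0.9,
    run_days: int = 3,
    half_window: int = 3,
    min_mean_daily_visits: float = 4.0,
    poi_class: str = "essential",
) -> tuple[list[RecoveryRecord], dict[str, int]]:
    """Full preprocessing chain for one POI class.

    baseline -> centered moving average -> sustained-return rule ->
    minimum-visit filter.
    """
    selected = [s for s in series_list if s.poi_class == poi_class]
    by_unit = {s.unit_id: s for s in selected}
    records = []
    for s in selected:
        base = compute_baseline(s, baseline_start, baseline_end)
        dates, smooth = moving_average(s, half_window)
        records.append(
            recovery_duration(
                dates,
                smooth,
                base,
                unit_id=s.unit_id,
                recovery_fraction=recovery_fraction,
                run_days=run_days,
                week_origin=week_origin,
                window_end=window_end,
            )
        )
    return filter_min_visits(records, by_unit, baseline_start, baseline_end, min_mean_daily_visits)


# ---------------------------------------------------------------------------
# IO


def read_visits_csv(path: str | Path) -> list[VisitSeries]:
    """Read `unit_id,date,poi_class,visits` (ISO dates) into series."""
    df = pd.read_csv(path, parse_dates=["date"])
    out = []
    for (uid, cls), grp in df.groupby(["unit_id", "poi_class"], sort=False):
        grp = grp.sort_values("date")
        out.append(VisitSeries(str(uid), str(cls), pd.DatetimeIndex(grp["date"]), grp["visits"].to_numpy()))
    return out


def durations_to_frame(records: Sequence[RecoveryRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in records],
            "duration_weeks": [r.duration_weeks for r in records],
            "week": [r.week for r in records],
            "censored": [r.censored for r in records],
        }
    )


def read_durations_csv(path: str | Path) -> list[RecoveryRecord]:
    df = pd.read_csv(path, dtype={"unit_id": str})
    out = []
    for row in df.itertuples(index=False):
        dur = float(row.duration_weeks)
        week = int(row.week) if hasattr(row, "week") else discretize_week(dur)
        cens = bool(row.censored) if hasattr(row, "censored") else dur >= CENSOR_WEEKS
        out.append(RecoveryRecord(str(row.unit_id), dur, week, cens))
    return out


def shift_days(d: date, days: int) -> date:
    return d + timedelta(days=days)
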