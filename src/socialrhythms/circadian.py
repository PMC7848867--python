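"""Circadian structure of activity volumes.

Takes per-(day, hour) activity counts -- tweet counts or hourly view
increments -- and computes smoothed daily series, normalized 24-hour
activity profiles, the before/after relative difference, and the
night/day x weekend/working-day rate decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

HOURS = np.arange(24)


@dataclass(frozen=True)
class CircadianProfile:
    """Normalized daily activity profile: the fraction ``f(h)`` of a
    period's total activity falling in each clock hour ``h``."""

    fractions: np.ndarray
    period: str = ""
    source: str = "events"
    support: float = 0.0

    def __post_init__(self) -> None:
        frac = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", frac)
        if frac.shape != (24,):
            raise ValueError("profile needs exactly 24 hour fractions")
        if np.any(frac < 0):
            raise ValueError("fractions must be non-negative")
        if self.support > 0 and abs(frac.sum() - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"hour": HOURS, "period": self.period, "source": self.source, "fraction": self.fractions}
        )


@dataclass(frozen=True)
class DaypartConfig:
    """Night/day and weekend/working-day split used by the rate decomposition.

    ``night_hours`` must leave a 24-hour partition with its complement;
    nights that wrap past midnight are attributed, for week-part
    classification, to the evening's calendar day (a Saturday 02:00 event
    belongs to Friday's -- working-day -- night).
    """

    night_hours: frozenset[int] = frozenset({23, 0, 1, 2, 3, 4, 5})
    weekend_days: frozenset[int] = frozenset({5, 6})  # Monday=0 .. Sunday=6

    def __post_init__(self) -> None:
        if not self.night_hours or not self.night_hours < set(range(24)):
            raise ValueError("night_hours must be a proper subset of 0..23")

    @property
    def day_hours(self) -> frozenset[int]:
        return frozenset(range(24)) - self.night_hours

    def part_of(self, hour: int) -> str:
        return "night" if hour in self.night_hours else "day"


#: Platform defaults: Twitter night 23:00-06:00, YouTube night 01:00-08:00
#: (both 7-hour nights, half-open).
TWITTER_DAYPARTS = DaypartConfig(night_hours=frozenset({23, 0, 1, 2, 3, 4, 5}))
YOUTUBE_DAYPARTS = DaypartConfig(night_hours=frozenset({1, 2, 3, 4, 5, 6, 7}))


# ---------------------------------------------------------------------------
# Aggregation helpers
# ---------------------------------------------------------------------------


def counts_by_day_hour(frame: pd.DataFrame, weight_col: str | None = None) -> pd.DataFrame:
    """Pivot a timestamped frame into a (calendar day) x (24 hour) count table.

    ``weight_col`` sums that column per cell (hourly view increments);
    otherwise rows are counted (events).  Missing cells are zero-filled and
    the day index is made contiguous.
    """
    if len(frame) == 0:
        return pd.DataFrame(0.0, index=pd.Index([], name="date"), columns=HOURS)
    ts = pd.to_datetime(frame["timestamp"])
    work = pd.DataFrame({"date": ts.dt.date, "hour": ts.dt.hour})
    if weight_col is None:
        work["w"] = 1.0
    else:
        work["w"] = frame[weight_col].to_numpy(dtype=float)
    table = work.pivot_table(index="date", columns="hour", values="w", aggfunc="sum", fill_value=0.0)
    table = table.reindex(columns=HOURS, fill_value=0.0)
    full_days = pd.date_range(min(table.index), max(table.index), freq="D").date
    table = table.reindex(index=full_days, fill_value=0.0)
    table.index.name = "date"
    return table


def daily_totals(counts: pd.DataFrame) -> pd.Series:
    """Total activity per calendar day from a day x hour count table."""
    return counts.sum(axis=1)


def rolling_daily_series(daily: pd.Series, window_days: int = 7) -> pd.Series:
    """Centered moving average of daily totals; endpoints use the partial window."""
    if window_days < 1 or window_days % 2 == 0:
        raise ValueError("window_days must be odd and positive")
    if len(daily) == 0:
        return daily.copy()
    return daily.rolling(window_days, center=True, min_periods=1).mean()


# ---------------------------------------------------------------------------
# Profiles and relative differences
# ---------------------------------------------------------------------------


def activity_profile(counts: pd.DataFrame, period: str = "", source: str = "events") -> CircadianProfile:
    """Normalized daily activity profile from a day x hour count table:

        f(h) = sum_d N(d, h) / sum_d sum_h N(d, h).
    """
    arr = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.atleast_2d(counts)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    by_hour = arr.sum(axis=0)
    total = by_hour.sum()
    if total <= 0:
        raise ValueError(f"undefined profile: no activity in period {period!r}")
    return CircadianProfile(by_hour / total, period=period, source=source, support=float(total))


def relative_difference(after: CircadianProfile, before: CircadianProfile) -> np.ndarray:
    """Relative profile change per hour:

        delta(h) = (f_after(h) - f_before(h)) / (f_after(h) + f_before(h)),

    bounded in [-1, 1] and antisymmetric under swapping the periods.  Hours
    with no activity in either period get delta = 0.
    """
    if after.source != before.source:
        raise ValueError(f"profiles from different sources: {after.source!r} vs {before.source!r}")
    fa, fb = after.fractions, before.fractions
    denom = fa + fb
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(denom > 0, (fa - fb) / np.where(denom > 0, denom, 1.0), 0.0)
    return delta


def relative_increment(a: float, b: float) -> float:
    """Percent-change style increment (a - b) / b between two rates."""
    if b == 0:
        raise ValueError("undefined relative increment: reference rate is zero")
    return (a - b) / b


# ---------------------------------------------------------------------------
# Night/day x weekend/working decomposition
# ---------------------------------------------------------------------------


def _attributed_date(day: date, hour: int, cfg: DaypartConfig) -> date:
    # post-midnight night hours belong to the previous evening's day
    if hour in cfg.night_hours and hour < 12:
        return day - timedelta(days=1)
    return day


def daypart_weekpart_rates(
    counts: pd.DataFrame,
    cfg: DaypartConfig | None = None,
    period: str = "",
) -> pd.DataFrame:
    """Average hourly activity in the four (night/day) x (weekend/working) cells.

    Each cell's pooled count is divided by the hours of exposure it actually
    received -- equivalently, by hours-in-part times contributing days, with
    partial nights at the window edges counted pro rata -- giving comparable
    per-hour-per-day rates.  Raises if a cell has no exposure.
    """
    cfg = cfg or DaypartConfig()
    n_hours = {"night": len(cfg.night_hours), "day": len(cfg.day_hours)}

    keys = [(p, w) for p in ("night", "day") for w in ("working", "weekend")]
    totals = {key: 0.0 for key in keys}
    exposure = {key: 0 for key in keys}  # hours of exposure per cell

    arr = counts.to_numpy(dtype=float)
    for i, day in enumerate(counts.index):
        for hour in HOURS:
            part = cfg.part_of(int(hour))
            anchor = _attributed_date(day, int(hour), cfg)
            weekpart = "weekend" if anchor.weekday() in cfg.weekend_days else "working"
            key = (part, weekpart)
            totals[key] += arr[i, hour]
            exposure[key] += 1

    rows = []
    for key in keys:
        part, weekpart = key
        if exposure[key] == 0:
            raise ValueError(f"no exposure for cell ({part}, {weekpart})")
        rows.append(
            {
                "period": period,
                "daypart": part,
                "weekpart": weekpart,
                "count": totals[key],
                "n_hours": n_hours[part],
                "n_days": exposure[key] / n_hours[part],
                "rate": totals[key] / exposure[key],
            }
        )
    return pd.DataFrame(rows)


def daypart_rate_increments(rates_after: pd.DataFrame, rates_before: pd.DataFrame) -> pd.DataFrame:
    """Relative increments (after - before)/before per decomposition cell."""
    key = ["daypart", "weekpart"]
    a = rates_after.set_index(key)["rate"]
    b = rates_before.set_index(key)["rate"]
    out = pd.DataFrame({"rate_before": b, "rate_after": a})
    out["increment"] = (a - b) / b
    return out.reset_index()
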