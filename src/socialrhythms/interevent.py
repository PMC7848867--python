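"""Per-user inter-event gap analysis and the go-to-sleep probability.

The time between two consecutive actions of the same user carries the
signature of sleep: night-time gaps are long when users go to bed.  The
go-to-sleep probability at a night hour is the probability that a
qualifying gap starting in that hour ends in the following morning window
rather than during the same night -- where a gap qualifies when it is
longer than a minimum threshold (isolating the last action of an activity
burst) and does not end after the close of the following morning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HOUR = pd.Timedelta(hours=1)


@dataclass(frozen=True)
class SleepEstimatorConfig:
    """Qualification rules for the go-to-sleep probability.

    ``min_gap_hours``: gaps at or below this length are activity-burst
    noise and are discarded (default 1 hour).  ``morning_window``: clock
    interval (start, end) counted as "the following morning" (default
    07:00-12:00, noon).  ``night_hours``: the gap start hours over which the
    estimate is reported (default 22:00-04:00, i.e. start hours 22..3).
    """

    min_gap_hours: float = 1.0
    morning_window: tuple[int, int] = (7, 12)
    night_hours: tuple[int, ...] = (22, 23, 0, 1, 2, 3)

    def __post_init__(self) -> None:
        lo, hi = self.morning_window
        if not 0 <= lo < hi <= 24:
            raise ValueError("morning_window must be an increasing clock interval")
        if set(range(lo, hi)) & set(self.night_hours):
            raise ValueError("morning_window must not overlap night_hours")
        if self.min_gap_hours <= 0:
            raise ValueError("min_gap_hours must be positive")


def compute_gaps(events: pd.DataFrame, period: str = "") -> pd.DataFrame:
    """One gap per consecutive event pair of the same user.

    Returns columns ``user_id``, ``t0`` (time of the earlier event),
    ``duration_hours`` (> 0; zero-duration pairs are dropped and counted in
    ``frame.attrs['n_zero_dropped']``) and ``start_hour``.
    """
    if len(events) == 0:
        out = pd.DataFrame(columns=["user_id", "t0", "duration_hours", "start_hour"])
        out.attrs["n_zero_dropped"] = 0
        return out
    ordered = events.sort_values(["user_id", "timestamp"], kind="stable")
    ts = pd.to_datetime(ordered["timestamp"])
    same_user = ordered["user_id"].eq(ordered["user_id"].shift(-1))
    duration = (ts.shift(-1) - ts).dt.total_seconds() / 3600.0
    valid = same_user & duration.notna()
    gaps = pd.DataFrame(
        {
            "user_id": ordered.loc[valid, "user_id"].to_numpy(),
            "t0": ts[valid].to_numpy(),
            "duration_hours": duration[valid].to_numpy(),
            "start_hour": ts[valid].dt.hour.to_numpy(),
        }
    )
    n_zero = int((gaps["duration_hours"] <= 0).sum())
    gaps = gaps[gaps["duration_hours"] > 0].reset_index(drop=True)
    gaps["period"] = period
    gaps.attrs["n_zero_dropped"] = n_zero
    return gaps


def hourly_gap_stats(gaps: pd.DataFrame, period: str = "") -> pd.DataFrame:
    """Mean, quartiles and count of gap durations per start hour (pooled
    over users); hours without gaps are omitted."""
    if len(gaps) == 0:
        return pd.DataFrame(
            columns=["period", "start_hour", "mean_gap_hours", "q1", "median", "q3", "n"]
        )
    grouped = gaps.groupby("start_hour")["duration_hours"]
    out = pd.DataFrame(
        {
            "mean_gap_hours": grouped.mean(),
            "q1": grouped.quantile(0.25),
            "median": grouped.median(),
            "q3": grouped.quantile(0.75),
            "n": grouped.size(),
        }
    ).reset_index()
    out.insert(0, "period", period)
    return out


def _morning_anchor(t0: pd.Series) -> pd.Series:
    """Date of "the following morning": the next calendar day for evening
    starts (hour >= 12), the same day for small-hours starts."""
    dates = t0.dt.normalize()
    return dates + pd.to_timedelta((t0.dt.hour >= 12).astype(int), unit="D")


def sleep_probability(
    gaps: pd.DataFrame,
    cfg: SleepEstimatorConfig | None = None,
    period: str = "",
) -> pd.DataFrame:
    """Go-to-sleep probability per night start-hour.

    For each configured night hour ``h``::

        P(h) = (# qualifying gaps starting in h ending in the following
                morning window) / (# qualifying gaps starting in h)

    where qualifying means duration > ``min_gap_hours`` and end not after
    the close of the following morning window.  The returned frame carries
    the full denominator accounting (``n_qualifying + n_short + n_late ==
    n_total`` per hour); hours with no qualifying gap get NaN and are
    flagged.
    """
    cfg = cfg or SleepEstimatorConfig()
    night = gaps[gaps["start_hour"].isin(cfg.night_hours)].copy()
    rows = []
    if len(night):
        t0 = pd.to_datetime(night["t0"])
        end = t0 + pd.to_timedelta(night["duration_hours"], unit="h")
        anchor = _morning_anchor(t0)
        open_ = anchor + pd.Timedelta(hours=cfg.morning_window[0])
        close = anchor + pd.Timedelta(hours=cfg.morning_window[1])
        short = night["duration_hours"] <= cfg.min_gap_hours
        late = ~short & (end > close)
        qualifying = ~short & ~late
        sleep = qualifying & (end >= open_)
        night["_short"], night["_late"] = short, late
        night["_qual"], night["_sleep"] = qualifying, sleep
        for hour in cfg.night_hours:
            sub = night[night["start_hour"] == hour]
            n_qual = int(sub["_qual"].sum())
            rows.append(
                {
                    "period": period,
                    "start_hour": hour,
                    "p_sleep": float(sub["_sleep"].sum() / n_qual) if n_qual else np.nan,
                    "n_qualifying": n_qual,
                    "n_short": int(sub["_short"].sum()),
                    "n_late": int(sub["_late"].sum()),
                    "n_total": int(len(sub)),
                }
            )
    else:
        for hour in cfg.night_hours:
            rows.append(
                {
                    "period": period,
                    "start_hour": hour,
                    "p_sleep": np.nan,
                    "n_qualifying": 0,
                    "n_short": 0,
                    "n_late": 0,
                    "n_total": 0,
                }
            )
    return pd.DataFrame(rows)
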