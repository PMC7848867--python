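"""Reading, validation, correction, windowing and filtering of raw data.

All timestamps in this package are timezone-naive wall-clock instants in
UTC+1 (Central European Time without a daylight-saving shift): the corpora
the package targets were collected at a fixed UTC+1 offset, so the spring
DST change is deliberately ignored.  An event at 13:59:59 belongs to clock
hour 13 (half-open ``[h, h+1)`` floor convention).

Events live in a :class:`pandas.DataFrame` with columns ``timestamp``
(datetime64), ``user_id`` (str), ``text`` (lower-cased token string) and
``hashtags`` (list of str).  View series live in a wide DataFrame with one
row per video: ``video_id``, ``publish_time``, ``title`` (optional) and
cumulative hourly totals ``h0`` .. ``h{H-1}``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("socialrhythms")

#: Fixed collection offset: Central European Time, no DST.
UTC_PLUS_1 = timezone(timedelta(hours=1), "UTC+01:00")

EVENT_COLUMNS = ("timestamp", "user_id", "text", "hashtags")

DEFAULT_HORIZON_HOURS = 168  # one week of hourly cumulative view totals


class FormatError(ValueError):
    """Raised when an input file is structurally unusable (>50% bad rows)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventRecord:
    """One timestamped user action (tweet-like), carrying text and hashtags."""

    timestamp: datetime
    user_id: str
    text: str
    hashtags: tuple[str, ...] = ()


@dataclass
class ParseReport:
    """Bookkeeping for a reader run: how many rows were kept or rejected."""

    n_read: int = 0
    n_parsed: int = 0
    n_rejected: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.n_rejected += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class AnalysisWindows:
    """Before / excluded-transition / after study windows (closed date ranges).

    Defaults are the spring-2020 French lockdown windows: three weeks before
    (Feb 17 - Mar 8), the two transition weeks around the lockdown onset
    (Mar 9 - Mar 22, discarded), and the lockdown weeks (Mar 23 - Apr 14).
    """

    before: tuple[date, date] = (date(2020, 2, 17), date(2020, 3, 8))
    after: tuple[date, date] = (date(2020, 3, 23), date(2020, 4, 14))

    def __post_init__(self) -> None:
        b0, b1 = self.before
        a0, a1 = self.after
        if not (b0 <= b1 < a0 <= a1):
            raise ValueError(
                "windows must be chronologically ordered and disjoint: "
                f"before={self.before}, after={self.after}"
            )

    @property
    def excluded(self) -> tuple[date, date]:
        """The dropped transition range strictly between the two windows."""
        return (self.before[1] + timedelta(days=1), self.after[0] - timedelta(days=1))

    def period_of(self, day: date) -> str | None:
        if self.before[0] <= day <= self.before[1]:
            return "before"
        if self.after[0] <= day <= self.after[1]:
            return "after"
        return None

    def days(self, period: str) -> list[date]:
        lo, hi = self.before if period == "before" else self.after
        return [lo + timedelta(days=i) for i in range((hi - lo).days + 1)]


@dataclass(frozen=True)
class UserFilterRules:
    """Rules isolating active, non-professional, locatable users.

    ``max_followers`` / ``max_weekly_tweets`` default to the corpus median
    (computed on the *unfiltered* population); retention requires strictly
    fewer followers / tweets-per-week than the threshold, at least
    ``min_total_tweets`` over the whole period, no professional keyword in
    the profile, and (when patterns are given) a matching location.
    """

    professional_keywords: frozenset[str] = frozenset(
        {"media", "blog", "official", "officiel", "journal", "radio", "presse"}
    )
    max_followers: float | None = None
    max_weekly_tweets: float | None = None
    min_total_tweets: int = 100
    location_patterns: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.min_total_tweets < 1:
            raise ValueError("min_total_tweets must be >= 1")
        for thr in (self.max_followers, self.max_weekly_tweets):
            if thr is not None and thr <= 0:
                raise ValueError("thresholds must be positive")


# ---------------------------------------------------------------------------
# Event I/O
# ---------------------------------------------------------------------------


def _parse_timestamp(value) -> datetime | None:
    """Parse an ISO-8601 instant to naive UTC+1 wall time; None if invalid."""
    try:
        ts = pd.Timestamp(value)
    except (ValueError, TypeError):
        return None
    if pd.isna(ts):
        return None
    if ts.tzinfo is not None:
        ts = ts.tz_convert(UTC_PLUS_1).tz_localize(None)
    return ts.to_pydatetime()


def _split_tags(raw) -> list[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return []
    if isinstance(raw, str):
        return [t for t in raw.split() if t]
    return [str(t) for t in raw]


def read_events(path: str | Path, format: str = "jsonl") -> tuple[pd.DataFrame, ParseReport]:
    """Read tweet-like event records from JSONL or CSV.

    Returns the parsed events (sorted by timestamp) and a :class:`ParseReport`
    counting rejected rows.  Raises :class:`FormatError` if more than half of
    the non-empty rows are malformed.
    """
    path = Path(path)
    if format not in {"csv", "jsonl"}:
        raise ValueError(f"unknown format {format!r}")
    report = ParseReport()
    rows: list[tuple] = []

    def add_row(ts_raw, user, text, tags) -> None:
        ts = _parse_timestamp(ts_raw)
        if ts is None:
            report.reject("bad_timestamp")
            return
        if user is None or str(user) == "":
            report.reject("missing_user")
            return
        rows.append((ts, str(user), "" if text is None else str(text), _split_tags(tags)))
        report.n_parsed += 1

    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                report.n_read += 1
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError:
                    report.reject("bad_json")
                    continue
                add_row(rec.get("timestamp"), rec.get("user_id"), rec.get("text"), rec.get("hashtags"))
    else:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = {"timestamp", "user_id"} - set(raw.columns)
        if missing:
            raise FormatError(f"CSV lacks required columns: {sorted(missing)}")
        for rec in raw.itertuples(index=False):
            report.n_read += 1
            add_row(rec.timestamp, rec.user_id, getattr(rec, "text", ""), getattr(rec, "hashtags", ""))

    if report.n_read == 0:
        logger.warning("read_events: %s is empty", path)
    elif report.n_rejected > report.n_read / 2:
        raise FormatError(
            f"{path}: {report.n_rejected}/{report.n_read} rows malformed"
        )
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if len(events):
        events["timestamp"] = pd.to_datetime(events["timestamp"])
        events = events.sort_values("timestamp", kind="stable").reset_index(drop=True)
    else:
        events["timestamp"] = pd.to_datetime(events["timestamp"])
    return events, report


def write_events(events: pd.DataFrame, path: str | Path, format: str = "jsonl") -> None:
    """Write events as JSONL (hashtags as array) or CSV (space-joined)."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in events.itertuples(index=False):
                fh.write(
                    json.dumps(
                        {
                            "timestamp": pd.Timestamp(rec.timestamp).isoformat() + "+01:00",
                            "user_id": rec.user_id,
                            "text": rec.text,
                            "hashtags": list(rec.hashtags),
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    elif format == "csv":
        out = events.copy()
        out["timestamp"] = out["timestamp"].map(lambda t: pd.Timestamp(t).isoformat() + "+01:00")
        out["hashtags"] = out["hashtags"].map(lambda tags: " ".join(tags))
        out.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# View-series I/O and correction
# ---------------------------------------------------------------------------


def view_total_columns(frame_or_h: pd.DataFrame | int) -> list[str]:
    if isinstance(frame_or_h, int):
        return [f"h{i}" for i in range(frame_or_h)]
    return [c for c in frame_or_h.columns if c.startswith("h") and c[1:].isdigit()]


def read_view_series(path: str | Path) -> pd.DataFrame:
    views = pd.read_csv(path)
    if "video_id" not in views.columns or "publish_time" not in views.columns:
        raise FormatError("view-series CSV needs video_id and publish_time columns")
    views["publish_time"] = views["publish_time"].map(_parse_timestamp)
    views["publish_time"] = pd.to_datetime(views["publish_time"])
    return views


def write_view_series(views: pd.DataFrame, path: str | Path) -> None:
    out = views.copy()
    out["publish_time"] = out["publish_time"].map(lambda t: pd.Timestamp(t).isoformat() + "+01:00")
    out.to_csv(path, index=False)


def correct_view_series(totals: np.ndarray, rescale_first: bool = True) -> np.ndarray:
    """Redistribute retroactive view removals uniformly over earlier hours.

    Platforms occasionally retract views they deem fake, which makes the
    cumulative total drop: whenever ``T[h+1] < T[h]`` the whole recorded
    prefix is rescaled by ``1 - p`` with ``p = (T[h] - T[h+1]) / T[h]``,
    applying corrections in chronological order.  The result is
    non-decreasing, preserves the final total, is idempotent, and may be
    non-integer.

    Because a later drop is never itself rescaled by an earlier prefix
    correction, the sequential replay collapses to a closed form: each entry
    is multiplied by the product of ``min(1, T[h+1]/T[h])`` over all drops at
    or after its position.  ``rescale_first=False`` leaves ``T[0]`` untouched
    (a literal reading of the correction's index range), at the price of a
    possibly non-monotone first step.

    Accepts a single series ``(H,)`` or a batch ``(n, H)``.
    """
    arr = np.asarray(totals, dtype=float)
    if np.any(arr < 0):
        raise ValueError("cumulative totals must be non-negative")
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    prev = arr[:, :-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(prev > 0, arr[:, 1:] / prev, 1.0)
    np.minimum(factors, 1.0, out=factors)
    # suffix product of the drop factors, aligned so entry j collects drops at h >= j
    suffix = np.ones_like(arr)
    suffix[:, :-1] = np.cumprod(factors[:, ::-1], axis=1)[:, ::-1]
    corrected = arr * suffix
    if not rescale_first:
        corrected[:, 0] = arr[:, 0]
    return corrected[0] if single else corrected


def correct_view_frame(views: pd.DataFrame, rescale_first: bool = True) -> pd.DataFrame:
    """Apply :func:`correct_view_series` to every row of a wide view table."""
    cols = view_total_columns(views)
    out = views.copy()
    out[cols] = correct_view_series(views[cols].to_numpy(dtype=float), rescale_first)
    return out


def view_increments(totals: np.ndarray) -> np.ndarray:
    """Hourly increments ``v_h = T_h - T_{h-1}`` with ``v_0 = T_0``."""
    arr = np.asarray(totals, dtype=float)
    return np.diff(arr, axis=-1, prepend=0.0)


def explode_view_increments(views: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-(video, wall-clock hour) view increments.

    Each video's 0..H-1 post-publication hours are mapped to absolute wall
    time (publication hour + offset), yielding columns ``video_id``,
    ``timestamp`` (hour-resolution) and ``views``.
    """
    cols = view_total_columns(views)
    inc = view_increments(views[cols].to_numpy(dtype=float))
    n, H = inc.shape
    base = views["publish_time"].dt.floor("h").to_numpy()
    stamps = base[:, None] + np.timedelta64(1, "h") * np.arange(H)[None, :]
    return pd.DataFrame(
        {
            "video_id": np.repeat(views["video_id"].to_numpy(), H),
            "timestamp": stamps.ravel(),
            "views": inc.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# Windowing and user filtering
# ---------------------------------------------------------------------------


def split_periods(
    frame: pd.DataFrame,
    windows: AnalysisWindows | None = None,
    timestamp_col: str = "timestamp",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Assign records to the before/after period by calendar date (UTC+1).

    Records in the excluded transition range, or outside all windows, are
    dropped and counted.  Returns ``(before, after, counts)`` with
    ``counts['before'] + counts['after'] + counts['dropped'] == len(frame)``.
    """
    windows = windows or AnalysisWindows()
    if len(frame) == 0:
        return frame.copy(), frame.copy(), {"before": 0, "after": 0, "dropped": 0}
    days = pd.to_datetime(frame[timestamp_col]).dt.date
    period = days.map(windows.period_of)
    before = frame[period == "before"].reset_index(drop=True)
    after = frame[period == "after"].reset_index(drop=True)
    counts = {
        "before": int(len(before)),
        "after": int(len(after)),
        "dropped": int(len(frame) - len(before) - len(after)),
    }
    return before, after, counts


def filter_users(user_stats: pd.DataFrame, rules: UserFilterRules | None = None) -> set[str]:
    """Return the user ids passing every retention rule.

    ``user_stats`` must be indexed by user id (or carry a ``user_id`` column)
    with columns ``followers``, ``weekly_tweets``, ``total_tweets``,
    ``profile`` and ``location``.  Median thresholds are computed on the full
    input population before any rule is applied.
    """
    rules = rules or UserFilterRules()
    stats = user_stats.set_index("user_id") if "user_id" in user_stats.columns else user_stats
    if len(stats) == 0:
        warnings.warn("filter_users: empty population", stacklevel=2)
        return set()

    max_followers = rules.max_followers
    if max_followers is None:
        max_followers = float(stats["followers"].median())
    max_weekly = rules.max_weekly_tweets
    if max_weekly is None:
        max_weekly = float(stats["weekly_tweets"].median())

    profile = stats["profile"].fillna("").str.lower()
    keep = ~profile.str.contains(
        "|".join(sorted(rules.professional_keywords)) or "(?!)", regex=True
    )
    keep &= stats["followers"] < max_followers
    keep &= stats["weekly_tweets"] < max_weekly
    keep &= stats["total_tweets"] >= rules.min_total_tweets
    if rules.location_patterns:
        location = stats["location"].fillna("").str.lower()
        keep &= location.str.contains("|".join(sorted(rules.location_patterns)), regex=True)
    return set(stats.index[keep])
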