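"""Synthetic corpora with the statistical structure the analyses assume.

The generator emulates two platforms around a lockdown-style regime change:

* tweet-like event streams -- per-user inhomogeneous hourly Poisson counts
  with a diurnal base rate, weekend modulation, an "after"-regime hour
  factor (night boost, morning damping), and sleep gating (each user draws
  a nightly bedtime and wake hour and emits nothing in between);
* video-like cumulative hourly view series over a fixed post-publication
  horizon, corrupted by occasional retroactive view removals (downward
  jumps), with the uncorrupted series kept as ground truth;
* a toy category lexicon whose stems double as the content vocabulary.

Event content follows a planted-category model: each event draws at most
one lexicon category from a per-hour, per-regime categorical distribution
(configured through labeled hour blocks) and realizes a few words of that
category, so planted hour structure, category volumes and category hour
shapes all have exact expected values.  The ``expected_*`` functions
compute those expectations by direct analysis of the configuration,
independently of the sampling code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .interevent import SleepEstimatorConfig
from .lexicon import DIMENSION_SCHEME, CategoryLexicon

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Diurnal base rate (expected events per awake user per hour), averaging
#: ~1.1/h (~26 events/day) -- an active but non-professional posting level.
DEFAULT_BASE_HOUR_RATES: tuple[float, ...] = (
    0.55, 0.35, 0.22, 0.15, 0.12, 0.15, 0.30, 0.60, 0.95, 1.25, 1.45, 1.55,
    1.60, 1.55, 1.50, 1.45, 1.50, 1.60, 1.70, 1.75, 1.65, 1.40, 1.05, 0.75,
)

#: Prefix-free synthetic stems per category (French-flavored, no stem is a
#: prefix of another so wildcard matching is unambiguous).
CATEGORY_SLUGS: dict[str, str] = {
    "Positive Affect": "posem",
    "Negative Affect": "negem",
    "Sadness": "trist",
    "Anger": "coler",
    "Anxiety": "angoi",
    "Accomplishment": "reussi",
    "Work": "travail",
    "Social life": "copain",
    "Religion": "eglise",
    "Death": "morta",
    "Leisure": "loisir",
    "Exclusion": "exclu",
    "Biology": "viro",
    "Money": "argent",
    "House": "maison",
    "Fun": "amuse",
}

_STEM_LETTERS = "abcdef"  # 6 stems per category; last two are exact words
_WILDCARD_SUFFIXES = ("", "ine", "eux")  # realized completions of a stem
_FILLER_VOCAB = tuple(f"plain{i:02d}" for i in range(40))


@dataclass(frozen=True)
class SleepModel:
    """Nightly sleep gating: bedtime and wake hour drawn per user per night.

    ``bedtime_probs`` is a categorical over hours on a noon-anchored axis
    (22 = 10 pm the same evening, 24 = midnight, 26 = 2 am the next day);
    ``wake_probs`` is a categorical over next-morning wall-clock hours.  The
    user emits no events from bedtime (inclusive) until the wake hour.
    """

    bedtime_probs: Mapping[int, float]
    wake_probs: Mapping[int, float]

    def __post_init__(self) -> None:
        for probs, lo, hi, name in (
            (self.bedtime_probs, 12, 36, "bedtime"),
            (self.wake_probs, 0, 12, "wake"),
        ):
            if not probs:
                raise ValueError(f"{name}_probs must be non-empty")
            if any(not lo <= int(k) < hi for k in probs):
                raise ValueError(f"{name} hours must lie in [{lo}, {hi})")
            if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1) > 1e-9:
                raise ValueError(f"{name}_probs must be a probability distribution")
        if max(self.bedtime_probs) >= 24 + min(self.wake_probs):
            raise ValueError("latest bedtime must precede earliest wake")

    def p_awake(self, hour: int) -> float:
        """Steady-state probability of being awake at clock hour ``hour``."""
        if hour >= 12:
            return sum(p for b, p in self.bedtime_probs.items() if b > hour)
        p_bed = sum(p for b, p in self.bedtime_probs.items() if b <= hour + 24)
        p_still = sum(p for w, p in self.wake_probs.items() if w > hour)
        return 1.0 - p_bed * p_still

    def to_dict(self) -> dict:
        return {
            "bedtime_probs": {int(k): v for k, v in self.bedtime_probs.items()},
            "wake_probs": {int(k): v for k, v in self.wake_probs.items()},
        }


#: Bedtime spreads carry a small night-owl tail so every night hour keeps
#: some awake population, as in real user pools.
DEFAULT_SLEEP_BEFORE = SleepModel(
    bedtime_probs={22: 0.18, 23: 0.32, 24: 0.25, 25: 0.12, 26: 0.06, 27: 0.04, 28: 0.02, 29: 0.01},
    wake_probs={6: 0.10, 7: 0.40, 8: 0.32, 9: 0.18},
)
#: Lockdown regime: bedtimes shift about an hour later, waking follows.
DEFAULT_SLEEP_AFTER = SleepModel(
    bedtime_probs={23: 0.18, 24: 0.30, 25: 0.22, 26: 0.12, 27: 0.08, 28: 0.06, 29: 0.04},
    wake_probs={6: 0.05, 7: 0.33, 8: 0.34, 9: 0.28},
)


@dataclass(frozen=True)
class ContentBlock:
    """A labeled block of hours with a category mixture per regime.

    Mixture weights are probabilities that an event in the block plants the
    given category; the remaining mass emits neutral filler-only text.
    """

    label: str
    hours: tuple[int, ...]
    mixture_before: Mapping[str, float]
    mixture_after: Mapping[str, float]

    def mixture(self, regime: str) -> Mapping[str, float]:
        return self.mixture_before if regime == "before" else self.mixture_after

    def __post_init__(self) -> None:
        for mix in (self.mixture_before, self.mixture_after):
            if any(p < 0 for p in mix.values()):
                raise ValueError("mixture weights must be non-negative")
            if sum(mix.values()) > 1 + 1e-9:
                raise ValueError(f"block {self.label!r}: mixture weights exceed 1")


#: Default daypart -> dominant-category plan (night is death/exclusion and
#: negative affect, mornings work and anxiety, ...).
_BLOCK_PLAN: tuple[tuple[str, tuple[int, ...], tuple[str, ...]], ...] = (
    ("0am-5am", tuple(range(0, 6)), ("Death", "Exclusion", "Negative Affect")),
    ("6am-9am", tuple(range(6, 10)), ("Work", "Accomplishment", "Anxiety")),
    ("10am-2pm", tuple(range(10, 15)), ("Biology", "Money", "Positive Affect")),
    ("3pm-6pm", tuple(range(15, 19)), ("Social life", "Leisure", "Anger")),
    ("7pm-12pm", tuple(range(19, 24)), ("Fun", "House", "Sadness", "Religion")),
)

#: Lockdown thematic drift: stay-at-home and crisis themes gain volume,
#: out-of-home themes lose it.
_LOCKDOWN_CATEGORY_SHIFT: dict[str, float] = {
    "Death": 1.6,
    "Biology": 1.5,
    "House": 1.5,
    "Religion": 1.3,
    "Anxiety": 1.4,
    "Social life": 0.7,
    "Leisure": 0.7,
    "Work": 0.8,
    "Money": 0.8,
    "Accomplishment": 0.8,
}


def _block_mixture(dominant: Sequence[str], dominant_mass=0.80, spill_mass=0.15) -> dict[str, float]:
    cats = [c for group in DIMENSION_SCHEME.values() for c in group]
    other = [c for c in cats if c not in dominant]
    mix = {c: dominant_mass / len(dominant) for c in dominant}
    mix.update({c: spill_mass / len(other) for c in other})
    return mix


def _shift_mixture(mix: Mapping[str, float], shift: Mapping[str, float]) -> dict[str, float]:
    raw = {c: p * shift.get(c, 1.0) for c, p in mix.items()}
    scale = sum(mix.values()) / sum(raw.values())
    return {c: p * scale for c, p in raw.items()}


def default_content_blocks() -> tuple[ContentBlock, ...]:
    """Five planted dayparts with a lockdown thematic drift in the after regime."""
    blocks = []
    for label, hours, dominant in _BLOCK_PLAN:
        before = _block_mixture(dominant)
        blocks.append(
            ContentBlock(
                label=label,
                hours=hours,
                mixture_before=before,
                mixture_after=_shift_mixture(before, _LOCKDOWN_CATEGORY_SHIFT),
            )
        )
    return tuple(blocks)


def volume_scaled_blocks(
    volumes_before: Mapping[str, float],
    volumes_after: Mapping[str, float],
    hour_shapes: Mapping[str, Sequence[float]],
) -> tuple[ContentBlock, ...]:
    """24 single-hour blocks where per-category hour shapes are fixed and
    only volume multipliers differ between regimes.

    The probability that an hour-``h`` event plants category ``c`` is
    ``volume[c] * shape[c][h]`` (shape in [0, 1]); slack mass emits filler
    only.  Because the shape factor is regime-invariant, each category's
    expected hour profile is identical before and after up to scale.
    """
    blocks = []
    for h in range(24):
        before = {c: volumes_before[c] * hour_shapes[c][h] for c in volumes_before}
        after = {c: volumes_after[c] * hour_shapes[c][h] for c in volumes_after}
        blocks.append(
            ContentBlock(label=f"h{h:02d}", hours=(h,), mixture_before=before, mixture_after=after)
        )
    return tuple(blocks)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpora.

    Defaults emulate the spring-2020 lockdown setting: three study weeks
    per regime around a discarded transition fortnight, ~500 active users,
    a diurnal posting rate, a 1.5x night boost and slight morning damping
    in the after regime, later lockdown bedtimes, and a planted five-block
    content day.
    """

    n_users: int = 500
    window_before: tuple[date, date] = (date(2020, 2, 17), date(2020, 3, 8))
    window_after: tuple[date, date] = (date(2020, 3, 23), date(2020, 4, 14))
    base_hour_rates: tuple[float, ...] = DEFAULT_BASE_HOUR_RATES
    night_boost: float = 1.5
    night_boost_hours: frozenset[int] = frozenset({23, 0, 1, 2, 3, 4, 5})
    morning_factor: float = 0.85
    morning_hours: frozenset[int] = frozenset({6, 7, 8, 9})
    weekend_factor: float = 0.9
    sleep_model_before: SleepModel | None = DEFAULT_SLEEP_BEFORE
    sleep_model_after: SleepModel | None = DEFAULT_SLEEP_AFTER
    content_blocks: tuple[ContentBlock, ...] = field(default_factory=default_content_blocks)
    tokens_per_event: int = 2
    filler_tokens_per_event: int = 3
    user_rate_sigma: float = 0.0
    n_videos: int = 2000
    video_horizon_hours: int = 168
    views_per_video_hour: float = 5.0
    video_popularity_sigma: float = 1.0
    video_age_halflife_hours: float = 36.0
    correction_rate: float = 0.02
    removal_frac_range: tuple[float, float] = (0.05, 0.30)
    generate_text: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        rates = np.asarray(self.base_hour_rates, dtype=float)
        if rates.shape != (24,):
            raise ValueError("base_hour_rates must have exactly 24 entries")
        if np.any(rates < 0) or not np.any(rates > 0):
            raise ValueError("base_hour_rates must be non-negative and not all zero")
        if self.n_users < 1:
            raise ValueError("n_users must be positive")
        for name in ("window_before", "window_after"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty")
        if self.window_before[1] >= self.window_after[0]:
            raise ValueError("window_before must end before window_after starts")
        if self.night_boost < 0 or self.morning_factor < 0 or self.weekend_factor < 0:
            raise ValueError("rate factors must be non-negative")
        if self.night_boost_hours & self.morning_hours:
            raise ValueError("night_boost_hours and morning_hours must be disjoint")
        covered = sorted(h for b in self.content_blocks for h in b.hours)
        if covered != list(range(24)):
            raise ValueError("content_blocks must cover all 24 hours exactly once")
        if not 0 <= self.correction_rate <= 1:
            raise ValueError("correction_rate must be in [0, 1]")
        lo, hi = self.removal_frac_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("removal_frac_range must be within [0, 1]")
        known = {c for group in DIMENSION_SCHEME.values() for c in group}
        for block in self.content_blocks:
            for mix in (block.mixture_before, block.mixture_after):
                unknown = set(mix) - known
                if unknown:
                    raise ValueError(f"block {block.label!r} references unknown categories {unknown}")

    # -- derived views of the configuration ---------------------------------

    def after_hour_factors(self) -> np.ndarray:
        factors = np.ones(24)
        factors[list(self.night_boost_hours)] *= self.night_boost
        factors[list(self.morning_hours)] *= self.morning_factor
        return factors

    def hour_rates(self, regime: str) -> np.ndarray:
        """Awake-state hourly rates (per user) for a regime, weekday-neutral."""
        rates = np.asarray(self.base_hour_rates, dtype=float)
        return rates * self.after_hour_factors() if regime == "after" else rates.copy()

    def sleep_model(self, regime: str) -> SleepModel | None:
        return self.sleep_model_before if regime == "before" else self.sleep_model_after

    def window_days(self, regime: str) -> list[date]:
        lo, hi = self.window_before if regime == "before" else self.window_after
        return [lo + timedelta(days=i) for i in range((hi - lo).days + 1)]

    def block_of_hour(self, hour: int) -> ContentBlock:
        for block in self.content_blocks:
            if hour in block.hours:
                return block
        raise ValueError(hour)

    def planted_partition(self) -> np.ndarray:
        """Hour -> block index labels of the planted content day."""
        labels = np.empty(24, dtype=int)
        for i, block in enumerate(self.content_blocks):
            for h in block.hours:
                labels[h] = i
        return labels


# ---------------------------------------------------------------------------
# Lexicon generation
# ---------------------------------------------------------------------------


def generate_lexicon(config: GeneratorConfig | None = None) -> CategoryLexicon:
    """Toy category lexicon over the standard three-dimension scheme.

    Each category carries six mutually disjoint synthetic stems: four
    wildcard patterns (``<slug><letter>*``) and two exact words.  The same
    vocabulary is what :func:`generate_event_stream` samples, so lexicon
    matching on generated text is exact by construction.
    """
    dimensions: dict[str, dict[str, tuple[str, ...]]] = {}
    for dim, cats in DIMENSION_SCHEME.items():
        dimensions[dim] = {}
        for cat in cats:
            slug = CATEGORY_SLUGS[cat]
            patterns = [f"{slug}{letter}*" for letter in _STEM_LETTERS[:4]]
            patterns += [f"{slug}{letter}o" for letter in _STEM_LETTERS[4:]]
            dimensions[dim][cat] = tuple(patterns)
    return CategoryLexicon(dimensions=dimensions, language="synthetic")


def realized_vocabulary(category: str) -> tuple[str, ...]:
    """All word forms of a category's stems that the generator may emit."""
    slug = CATEGORY_SLUGS[category]
    forms = [
        f"{slug}{letter}{suffix}" for letter in _STEM_LETTERS[:4] for suffix in _WILDCARD_SUFFIXES
    ]
    forms += [f"{slug}{letter}o" for letter in _STEM_LETTERS[4:]]
    return tuple(forms)


# ---------------------------------------------------------------------------
# Event-stream generation
# ---------------------------------------------------------------------------


def _study_days(config: GeneratorConfig) -> tuple[list[date], list[str]]:
    days = config.window_days("before") + config.window_days("after")
    regimes = ["before"] * len(config.window_days("before")) + ["after"] * len(
        config.window_days("after")
    )
    return days, regimes


def _sample_sleep(
    rng: np.random.Generator, model: SleepModel, size: int
) -> tuple[np.ndarray, np.ndarray]:
    beds = np.array(sorted(model.bedtime_probs))
    bed = rng.choice(beds, size=size, p=[model.bedtime_probs[b] for b in beds])
    wakes = np.array(sorted(model.wake_probs))
    wake = rng.choice(wakes, size=size, p=[model.wake_probs[w] for w in wakes])
    return bed, wake


def _awake_mask(
    rng: np.random.Generator, config: GeneratorConfig, days: list[date], regimes: list[str]
) -> np.ndarray:
    """(n_users, n_days, 24) awake indicator from per-night sleep draws."""
    U, D = config.n_users, len(days)
    awake = np.ones((U, D, 24), dtype=bool)
    if config.sleep_model_before is None and config.sleep_model_after is None:
        return awake

    def night_draws(anchor_day: date, regime: str):
        model = config.sleep_model(regime)
        if model is None:
            return None
        return _sample_sleep(rng, model, U)

    hours = np.arange(24)
    evening = hours >= 12
    prev: tuple[np.ndarray, np.ndarray] | None = None
    prev_day: date | None = None
    for j, (day, regime) in enumerate(zip(days, regimes)):
        if prev_day != day - timedelta(days=1):
            # window boundary: draw the pre-window night afresh
            prev = night_draws(day - timedelta(days=1), regime)
        tonight = night_draws(day, regime)
        if tonight is not None:
            bed, _ = tonight
            awake[:, j, evening] &= bed[:, None] > hours[None, evening]
        if prev is not None:
            bed_p, wake_p = prev
            asleep = (bed_p[:, None] <= hours[None, ~evening] + 24) & (
                hours[None, ~evening] < wake_p[:, None]
            )
            awake[:, j, ~evening] &= ~asleep
        prev, prev_day = tonight, day
    return awake


def _category_hour_probs(config: GeneratorConfig, regime: str) -> np.ndarray:
    """(24, n_categories) planted-category probabilities; remainder is filler."""
    cats = [c for group in DIMENSION_SCHEME.values() for c in group]
    probs = np.zeros((24, len(cats)))
    for block in config.content_blocks:
        mix = block.mixture(regime)
        for h in block.hours:
            for ci, cat in enumerate(cats):
                probs[h, ci] = mix.get(cat, 0.0)
    return probs


def _draw_texts(
    rng: np.random.Generator,
    config: GeneratorConfig,
    hours: np.ndarray,
    regime_is_after: np.ndarray,
    n_content: int,
    n_filler: int,
) -> tuple[list[str], list[list[str]], np.ndarray]:
    """Planted category index (-1 = none), text and hashtags per event."""
    cats = [c for group in DIMENSION_SCHEME.values() for c in group]
    vocab = [realized_vocabulary(c) for c in cats]
    probs = {
        "before": _category_hour_probs(config, "before"),
        "after": _category_hour_probs(config, "after"),
    }
    n = len(hours)
    planted = np.full(n, -1, dtype=int)
    u = rng.random(n)
    for regime, is_after in (("before", False), ("after", True)):
        mask = regime_is_after == is_after
        if not mask.any():
            continue
        p = probs[regime][hours[mask]]  # (m, K)
        cum = np.cumsum(p, axis=1)
        idx = (u[mask, None] < cum).argmax(axis=1)
        hit = u[mask] < cum[:, -1]
        planted[mask] = np.where(hit, idx, -1)

    filler_idx = rng.integers(0, len(_FILLER_VOCAB), size=(n, n_filler))
    word_idx = rng.integers(0, max(len(v) for v in vocab), size=(n, n_content))
    texts: list[str] = []
    hashtags: list[list[str]] = []
    for i in range(n):
        fillers = [_FILLER_VOCAB[k] for k in filler_idx[i]]
        if planted[i] >= 0:
            forms = vocab[planted[i]]
            content = [forms[k % len(forms)] for k in word_idx[i]]
        else:
            content = []
        texts.append(" ".join(content + fillers))
        hashtags.append(content)
    return texts, hashtags, planted


def generate_event_stream(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate the tweet-like corpus; returns (events, ground truth).

    Events carry ``timestamp`` (naive UTC+1, second precision), ``user_id``,
    ``text`` and ``hashtags``; the ground-truth dict records the regime
    parameters, exact expected hour profiles, the planted hour partition
    and per-(hour, regime) category probabilities for recovery tests.
    """
    rng = rng or np.random.default_rng(config.seed)
    days, regimes = _study_days(config)
    U, D = config.n_users, len(days)
    user_ids = np.array([f"u{i:05d}" for i in range(U)])

    mult = (
        rng.lognormal(-config.user_rate_sigma**2 / 2, config.user_rate_sigma, U)
        if config.user_rate_sigma > 0
        else np.ones(U)
    )
    awake = _awake_mask(rng, config, days, regimes)

    rate_by_regime = {r: config.hour_rates(r) for r in ("before", "after")}
    day_rates = np.stack(
        [
            rate_by_regime[regime]
            * (config.weekend_factor if day.weekday() >= 5 else 1.0)
            for day, regime in zip(days, regimes)
        ]
    )  # (D, 24)
    lam = mult[:, None, None] * day_rates[None, :, :] * awake
    counts = rng.poisson(lam)

    u_idx, d_idx, h_idx = np.nonzero(counts)
    reps = counts[u_idx, d_idx, h_idx]
    ev_u = np.repeat(u_idx, reps)
    ev_d = np.repeat(d_idx, reps)
    ev_h = np.repeat(h_idx, reps)
    jitter = rng.random(ev_u.size)

    day_starts = np.array([np.datetime64(d, "s") for d in days])
    seconds = (ev_h * 3600 + np.floor(jitter * 3600)).astype("timedelta64[s]")
    timestamps = day_starts[ev_d] + seconds
    regime_is_after = np.array([r == "after" for r in regimes])[ev_d]

    events = pd.DataFrame(
        {
            "timestamp": timestamps.astype("datetime64[ns]"),
            "user_id": user_ids[ev_u],
        }
    )
    if config.generate_text:
        texts, tags, planted = _draw_texts(
            rng, config, ev_h, regime_is_after,
            config.tokens_per_event, config.filler_tokens_per_event,
        )
        events["text"] = texts
        events["hashtags"] = tags
    else:
        events["text"] = ""
        events["hashtags"] = [[] for _ in range(len(events))]

    events = events.sort_values("timestamp", kind="stable").reset_index(drop=True)

    cats = [c for group in DIMENSION_SCHEME.values() for c in group]
    truth = {
        "n_events": int(len(events)),
        "hour_rates": {r: rate_by_regime[r].tolist() for r in ("before", "after")},
        "after_hour_factors": config.after_hour_factors().tolist(),
        "weekend_factor": config.weekend_factor,
        "expected_profile": {r: expected_profile(config, r).tolist() for r in ("before", "after")},
        "expected_delta": expected_delta(config).tolist(),
        "planted_partition": config.planted_partition().tolist(),
        "block_labels": [b.label for b in config.content_blocks],
        "category_order": cats,
        "category_hour_probs": {
            r: _category_hour_probs(config, r).tolist() for r in ("before", "after")
        },
        "sleep_models": {
            r: (m.to_dict() if (m := config.sleep_model(r)) else None)
            for r in ("before", "after")
        },
    }
    return events, truth


# ---------------------------------------------------------------------------
# View-series generation
# ---------------------------------------------------------------------------


def generate_view_series(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate video view series; returns (views, ground truth).

    Each video gets a publication instant, a popularity multiplier, and
    hourly view increments driven by the wall-clock hour-rate model with an
    age decay; the cumulative series is then corrupted by retroactive
    removals (at ``correction_rate`` per video-hour a fraction of all views
    counted so far is deleted, producing a downward jump).  The ground
    truth keeps the uncorrupted cumulative series.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    days, regimes = _study_days(config)
    n, H = config.n_videos, config.video_horizon_hours
    base = np.asarray(config.base_hour_rates, dtype=float)

    pub_day_idx = rng.integers(0, len(days), size=n)
    pub_hour = rng.choice(24, size=n, p=base / base.sum())
    pub_minute = rng.integers(0, 60, size=n)
    day_starts = np.array([np.datetime64(d, "s") for d in days])
    publish = day_starts[pub_day_idx] + (pub_hour * 3600 + pub_minute * 60).astype(
        "timedelta64[s]"
    )
    popularity = rng.lognormal(
        -config.video_popularity_sigma**2 / 2, config.video_popularity_sigma, n
    )

    # wall-clock hour and date for every (video, age-hour) cell
    ages = np.arange(H)
    wall_hour = (pub_hour[:, None] + ages[None, :]) % 24
    day_offset = (pub_hour[:, None] + ages[None, :]) // 24
    wall_dates = np.array([d.toordinal() for d in days])[pub_day_idx][:, None] + day_offset

    before_end = config.window_before[1].toordinal()
    is_after = wall_dates > before_end
    weekday = (wall_dates + 6) % 7  # ordinal 1 = Monday -> weekday 0 shift: Jan 1, 0001 was a Monday
    weekend = weekday >= 5

    factors_after = config.after_hour_factors()
    hour_rate = base[wall_hour] * np.where(is_after, factors_after[wall_hour], 1.0)
    hour_rate = hour_rate * np.where(weekend, config.weekend_factor, 1.0)
    decay = 0.5 ** (ages / config.video_age_halflife_hours)
    lam = (
        config.views_per_video_hour
        * popularity[:, None]
        * (hour_rate / base.mean())
        * decay[None, :]
    )
    increments = rng.poisson(lam).astype(float)
    clean = np.cumsum(increments, axis=1)

    corrupted = clean.copy()
    if config.correction_rate > 0:
        mask = rng.random((n, H)) < config.correction_rate
        fracs = rng.uniform(*config.removal_frac_range, size=(n, H))
        for i in np.nonzero(mask.any(axis=1))[0]:
            series = corrupted[i]
            for hc in np.nonzero(mask[i])[0]:
                removed = math.floor(fracs[i, hc] * series[hc])
                if removed > 0:
                    series[hc:] -= removed

    head: dict = {"video_id": [f"v{i:05d}" for i in range(n)]}
    head["publish_time"] = pd.to_datetime(publish.astype("datetime64[ns]"))
    if config.generate_text:
        texts, _, _ = _draw_texts(
            rng, config, pub_hour,
            np.array([r == "after" for r in regimes])[pub_day_idx],
            3, 3,
        )
        head["title"] = texts
    views = pd.concat(
        [pd.DataFrame(head), pd.DataFrame(corrupted, columns=[f"h{h}" for h in range(H)])],
        axis=1,
    )

    truth = {
        "clean_totals": clean.tolist(),
        "popularity": popularity.tolist(),
        "n_corrupted": int((corrupted != clean).any(axis=1).sum()),
    }
    return views, truth


# ---------------------------------------------------------------------------
# Exact expectations (analysis-side oracles)
# ---------------------------------------------------------------------------


def expected_hour_counts(config: GeneratorConfig, regime: str) -> np.ndarray:
    """Expected events per user per day at each hour, averaged over the
    regime's window days (weekday mix included, sleep gating exact)."""
    rates = config.hour_rates(regime)
    model = config.sleep_model(regime)
    p_awake = np.array([model.p_awake(h) if model else 1.0 for h in range(24)])
    days = config.window_days(regime)
    wk = np.array([config.weekend_factor if d.weekday() >= 5 else 1.0 for d in days])
    return rates * p_awake * wk.mean()


def expected_profile(config: GeneratorConfig, regime: str) -> np.ndarray:
    counts = expected_hour_counts(config, regime)
    return counts / counts.sum()


def expected_delta(config: GeneratorConfig) -> np.ndarray:
    """Exact expected relative profile difference delta(h) between regimes."""
    fa, fb = expected_profile(config, "after"), expected_profile(config, "before")
    denom = fa + fb
    return np.where(denom > 0, (fa - fb) / np.where(denom > 0, denom, 1.0), 0.0)


def expected_rate_delta(config: GeneratorConfig) -> np.ndarray:
    """Expected delta computed on unnormalized per-user-day hourly rates.

    With equal per-day exposure in both regimes this isolates the injected
    rate ratio: a pure night boost ``r`` gives (r-1)/(r+1) on boosted hours
    and exactly 0 elsewhere.
    """
    ca, cb = expected_hour_counts(config, "after"), expected_hour_counts(config, "before")
    denom = ca + cb
    return np.where(denom > 0, (ca - cb) / np.where(denom > 0, denom, 1.0), 0.0)


def expected_sleep_probability(
    config: GeneratorConfig,
    est: SleepEstimatorConfig | None = None,
    regime: str = "before",
    grid_per_hour: int = 240,
) -> dict[int, float]:
    """Model-implied go-to-sleep probability per night start-hour.

    Computed by direct numerical integration of the generator's stochastic
    model (piecewise-constant hourly Poisson rates gated by categorical
    bedtime/wake draws) on a noon-to-noon axis -- independent of the
    sampling code.  For a gap starting at an event in hour ``h``, the next
    event lands either before bedtime (an awake gap) or after the wake
    hour; the probability is the sleep-classified share of the qualifying
    mass (duration above the threshold, end not after the morning close).
    Requires ``weekend_factor == 1`` (a single night type).
    """
    est = est or SleepEstimatorConfig()
    if config.weekend_factor != 1.0:
        raise ValueError("the sleep oracle assumes weekend_factor == 1")
    model = config.sleep_model(regime)
    if model is None:
        raise ValueError(f"no sleep model in regime {regime!r}")
    rates = config.hour_rates(regime)

    dt = 1.0 / grid_per_hour
    edges = np.arange(12.0, 36.0 + dt / 2, dt)
    mids = edges[:-1] + dt / 2
    wall = (np.floor(mids).astype(int)) % 24
    r_wall = rates[wall]

    open_tau = est.morning_window[0] + 24.0
    close_tau = est.morning_window[1] + 24.0

    num = {h: 0.0 for h in est.night_hours}
    den = {h: 0.0 for h in est.night_hours}
    for b, pb in model.bedtime_probs.items():
        for w, pw in model.wake_probs.items():
            weight = pb * pw
            awake = (mids < b) | (mids >= w + 24)
            rate = r_wall * awake
            R_edges = np.concatenate([[0.0], np.cumsum(rate) * dt])
            A = rate * np.exp(-(R_edges[:-1] + rate * dt / 2))
            Acum = np.concatenate([[0.0], np.cumsum(A) * dt])

            def A_between(lo: np.ndarray, hi: float) -> np.ndarray:
                lo = np.minimum(np.maximum(lo, 12.0), 36.0)
                return np.interp(hi, edges, Acum) - np.interp(lo, edges, Acum)

            for h in est.night_hours:
                tau_h = h + 24.0 if h < 12 else float(h)
                sel = (mids >= tau_h) & (mids < tau_h + 1)
                if not sel.any():
                    continue
                t0 = mids[sel]
                w_ev = rate[sel]
                if not w_ev.any():
                    continue
                eR = np.exp(R_edges[:-1][sel] + rate[sel] * dt / 2)
                cut_q = t0 + est.min_gap_hours
                qual = eR * A_between(cut_q, close_tau)
                sleep = eR * A_between(np.maximum(cut_q, open_tau), close_tau)
                num[h] += weight * float(np.sum(w_ev * sleep) * dt)
                den[h] += weight * float(np.sum(w_ev * qual) * dt)
    return {h: (num[h] / den[h] if den[h] > 0 else float("nan")) for h in est.night_hours}
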