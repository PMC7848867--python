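"""End-to-end statistical validation scenarios.

Each function builds a controlled synthetic scenario, runs the relevant
analysis path on it, and measures how well the analysis recovers the
planted ground truth (or matches an independently coded oracle).  The
scenarios double as the package's acceptance checks: they are exercised by
the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import circadian, content_similarity, interevent, lexicon as lex
from .ingest import AnalysisWindows, correct_view_series, split_periods, view_total_columns
from .interevent import SleepEstimatorConfig
from .synthetic import (
    GeneratorConfig,
    SleepModel,
    expected_delta,
    expected_rate_delta,
    expected_sleep_probability,
    generate_event_stream,
    generate_lexicon,
    generate_view_series,
    volume_scaled_blocks,
)


def child_seed(seed: int, stream: int) -> int:
    """Deterministic sub-seed (below 2**31) for an independent scenario."""
    return int(np.random.SeedSequence([int(seed), int(stream)]).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# View-correction oracle
# ---------------------------------------------------------------------------


def replay_correction(totals: np.ndarray) -> np.ndarray:
    """Literal chronological replay of the view-correction rule.

    Scans the series once; at every downward jump ``T[h+1] < T[h]`` the
    recorded prefix ``T[0..h]`` is rescaled by ``1 - p`` with
    ``p = (T[h] - T[h+1]) / T[h]``.  Kept deliberately naive as the
    independent oracle for the vectorized implementation.
    """
    T = np.array(totals, dtype=float)
    for h in range(len(T) - 1):
        if T[h + 1] < T[h]:
            p = (T[h] - T[h + 1]) / T[h]
            T[: h + 1] *= 1.0 - p
    return T


def check_view_correction(seed: int, n_series: int = 1000) -> dict:
    """Corrected view series must equal the replay oracle exactly, be
    non-decreasing, and preserve final totals."""
    config = GeneratorConfig(
        n_users=1,
        n_videos=n_series,
        correction_rate=0.05,
        generate_text=False,
        seed=child_seed(seed, 1),
    )
    views, truth = generate_view_series(config)
    totals = views[view_total_columns(views)].to_numpy(dtype=float)
    corrected = correct_view_series(totals)
    oracle = np.stack([replay_correction(row) for row in totals])
    diffs = np.abs(corrected - oracle)
    per_series_ok = np.all(diffs <= 1e-9 * np.maximum(1.0, np.abs(oracle)), axis=1)
    monotone = np.all(np.diff(corrected, axis=1) >= -1e-9, axis=1)
    final_err = np.abs(corrected[:, -1] - totals[:, -1])
    return {
        "n_series": int(n_series),
        "n_with_corrections": int(truth["n_corrupted"]),
        "n_oracle_mismatch": int((~per_series_ok).sum()),
        "max_abs_diff_vs_oracle": float(diffs.max()),
        "n_nonmonotone": int((~monotone).sum()),
        "max_final_total_error": float(final_err.max()),
    }


# ---------------------------------------------------------------------------
# Relative-difference recovery
# ---------------------------------------------------------------------------


def delta_recovery_config(seed: int, n_users: int = 500) -> GeneratorConfig:
    """Controlled boost-only regime change: 21 days per regime, a 1.5x
    night boost and no other modulation, isolating the injected ratio.

    A flat base rate keeps every hour's count high enough that the
    Monte-Carlo standard error of delta (~0.006) is small relative to the
    injected effect."""
    return GeneratorConfig(
        n_users=n_users,
        window_before=(date(2020, 2, 17), date(2020, 3, 8)),
        window_after=(date(2020, 3, 23), date(2020, 4, 12)),
        base_hour_rates=(1.1,) * 24,
        night_boost=1.5,
        morning_factor=1.0,
        weekend_factor=1.0,
        sleep_model_before=None,
        sleep_model_after=None,
        generate_text=False,
        seed=child_seed(seed, 2),
    )


def check_delta_recovery(seed: int, n_users: int = 500) -> dict:
    config = delta_recovery_config(seed, n_users)
    events, _ = generate_event_stream(config)
    windows = AnalysisWindows(before=config.window_before, after=config.window_after)
    before, after, _ = split_periods(events, windows)
    profiles = {
        "before": circadian.activity_profile(circadian.counts_by_day_hour(before), "before"),
        "after": circadian.activity_profile(circadian.counts_by_day_hour(after), "after"),
    }
    delta_sim = circadian.relative_difference(profiles["after"], profiles["before"])
    delta_exp = expected_delta(config)

    # delta on raw per-hour counts (equal exposure both regimes): the pure
    # injected ratio, (1.5-1)/(1.5+1) = 0.2 on night hours, 0 elsewhere
    cb = circadian.counts_by_day_hour(before).sum(axis=0).to_numpy()
    ca = circadian.counts_by_day_hour(after).sum(axis=0).to_numpy()
    rate_delta = (ca - cb) / (ca + cb)
    rate_delta_exp = expected_rate_delta(config)
    night = sorted(config.night_boost_hours)
    day = [h for h in range(24) if h not in config.night_boost_hours]
    return {
        "n_events": int(len(events)),
        "max_abs_error_profile_delta": float(np.abs(delta_sim - delta_exp).max()),
        "max_abs_error_rate_delta": float(np.abs(rate_delta - rate_delta_exp).max()),
        "night_rate_delta_mean": float(rate_delta[night].mean()),
        "day_rate_delta_max_abs": float(np.abs(rate_delta[day]).max()),
        "expected_night_rate_delta": float(rate_delta_exp[night].mean()),
    }


# ---------------------------------------------------------------------------
# Similarity matrix oracle and planted-block clustering
# ---------------------------------------------------------------------------


def _brute_force_theta(sets: content_similarity.HourContentSets) -> np.ndarray:
    """Independent double loop over all (day, hour-pair) cells."""
    theta = np.zeros((24, 24))
    for h1 in range(24):
        for h2 in range(24):
            acc = 0.0
            for day in sets.days:
                a, b = sets.get(day, h1), sets.get(day, h2)
                union = len(a | b)
                acc += (len(a & b) / union) if union else 0.0
            theta[h1, h2] = acc / len(sets.days)
    return theta


def _small_corpus_config(seed: int, n_users: int, n_days: int) -> GeneratorConfig:
    return GeneratorConfig(
        n_users=n_users,
        window_before=(date(2020, 2, 17), date(2020, 2, 17 + n_days - 1)),
        window_after=(date(2020, 4, 13), date(2020, 4, 14)),
        weekend_factor=1.0,
        sleep_model_before=None,
        sleep_model_after=None,
        seed=seed,
    )


def check_similarity_and_clustering(seed: int, n_cluster_seeds: int = 20) -> dict:
    """Theta must equal a brute-force oracle on a 3-day toy corpus, and
    k-means on planted five-block content must recover the partition."""
    config = _small_corpus_config(child_seed(seed, 3), n_users=40, n_days=3)
    events, _ = generate_event_stream(config)
    before, _, _ = split_periods(
        events, AnalysisWindows(before=config.window_before, after=config.window_after)
    )
    sets = content_similarity.build_hour_sets(before, "before", "hashtag")
    theta = content_similarity.time_similarity_matrix(sets)
    theta_diff = float(np.abs(theta.theta - _brute_force_theta(sets)).max())

    aris = []
    for i in range(n_cluster_seeds):
        s = child_seed(seed, 100 + i)
        cfg = _small_corpus_config(s, n_users=80, n_days=6)
        ev, truth = generate_event_stream(cfg)
        bef, _, _ = split_periods(
            ev, AnalysisWindows(before=cfg.window_before, after=cfg.window_after)
        )
        hour_sets = content_similarity.build_hour_sets(bef, "before", "hashtag")
        th = content_similarity.time_similarity_matrix(hour_sets)
        labels = content_similarity.cluster_hours(th, k=5, seed=s)
        aris.append(adjusted_rand_score(truth["planted_partition"], labels))
    return {
        "theta_max_abs_diff_vs_oracle": theta_diff,
        "ari_min": float(np.min(aris)),
        "ari_mean": float(np.mean(aris)),
        "n_cluster_seeds": int(n_cluster_seeds),
    }


# ---------------------------------------------------------------------------
# KS null calibration
# ---------------------------------------------------------------------------


def _null_content_config(seed: int) -> GeneratorConfig:
    """Identical regimes with a single hour-block: every per-(day, hour)
    category-fraction sample is drawn from one common distribution."""
    mixture = {
        "Positive Affect": 0.35,
        "Negative Affect": 0.25,
        "Sadness": 0.05,
        "Work": 0.10,
        "Biology": 0.05,
    }
    from .synthetic import ContentBlock

    block = ContentBlock(
        label="all-day", hours=tuple(range(24)), mixture_before=mixture, mixture_after=mixture
    )
    return GeneratorConfig(
        n_users=40,
        window_before=(date(2020, 2, 17), date(2020, 2, 26)),
        window_after=(date(2020, 3, 23), date(2020, 4, 1)),
        base_hour_rates=(2.2,) * 24,
        night_boost=1.0,
        morning_factor=1.0,
        weekend_factor=1.0,
        sleep_model_before=None,
        sleep_model_after=None,
        content_blocks=(block,),
        filler_tokens_per_event=2,
        seed=seed,
    )


def check_ks_type_one_error(
    seed: int, n_reps: int = 200, alpha: float = 0.05, category: str = "Positive Affect"
) -> dict:
    """Under identical regimes the KS period comparison must reject at the
    nominal rate: the rejection fraction over replicates should sit inside
    the binomial band around alpha."""
    lexicon = generate_lexicon()
    rejections = 0
    for i in range(n_reps):
        config = _null_content_config(child_seed(seed, 1000 + i))
        events, _ = generate_event_stream(config)
        windows = AnalysisWindows(before=config.window_before, after=config.window_after)
        before, after, _ = split_periods(events, windows)
        samples = {}
        for period, frame in (("before", before), ("after", after)):
            assigned = lex.assign_items(frame, lexicon)
            samples[period] = lex.hourly_fraction_samples(
                assigned["General Affects"], frame["timestamp"], lexicon, "General Affects"
            )
        table = lex.compare_periods_ks(samples["before"], samples["after"], categories=[category])
        if float(table["ks_pvalue"].iloc[0]) < alpha:
            rejections += 1
    return {
        "rejection_rate": rejections / n_reps,
        "n_reps": int(n_reps),
        "alpha": alpha,
    }


# ---------------------------------------------------------------------------
# Sleep-probability recovery
# ---------------------------------------------------------------------------


def sleep_recovery_config(seed: int, n_users: int = 4000) -> GeneratorConfig:
    """Flat-rate regime with a broad bedtime spread so every estimator
    night hour receives events, and no other modulation."""
    return GeneratorConfig(
        n_users=n_users,
        window_before=(date(2020, 2, 17), date(2020, 3, 8)),
        window_after=(date(2020, 4, 13), date(2020, 4, 14)),
        base_hour_rates=(1.2,) * 24,
        night_boost=1.0,
        morning_factor=1.0,
        weekend_factor=1.0,
        sleep_model_before=SleepModel(
            bedtime_probs={22: 0.10, 23: 0.15, 24: 0.20, 25: 0.20, 26: 0.15, 27: 0.10, 28: 0.10},
            wake_probs={7: 0.40, 8: 0.30, 9: 0.30},
        ),
        sleep_model_after=None,
        generate_text=False,
        seed=child_seed(seed, 4),
    )


def check_sleep_recovery(seed: int, n_users: int = 4000) -> dict:
    config = sleep_recovery_config(seed, n_users)
    est = SleepEstimatorConfig()
    events, _ = generate_event_stream(config)
    windows = AnalysisWindows(before=config.window_before, after=config.window_after)
    before, _, _ = split_periods(events, windows)
    gaps = interevent.compute_gaps(before, "before")
    table = interevent.sleep_probability(gaps, est, "before")
    expected = expected_sleep_probability(config, est, "before")

    accounting = (
        table["n_qualifying"] + table["n_short"] + table["n_late"] == table["n_total"]
    ).all()
    errors = {
        int(row.start_hour): abs(row.p_sleep - expected[int(row.start_hour)])
        for row in table.itertuples()
        if np.isfinite(row.p_sleep)
    }
    return {
        "max_abs_error": float(max(errors.values())),
        "n_hours_estimated": int(len(errors)),
        "n_night_hours": int(len(est.night_hours)),
        "min_n_qualifying": int(table["n_qualifying"].min()),
        "accounting_identity_ok": bool(accounting),
        "estimated": {int(r.start_hour): float(r.p_sleep) for r in table.itertuples()},
        "expected": {h: float(p) for h, p in expected.items()},
    }


# ---------------------------------------------------------------------------
# Emotional shape resilience
# ---------------------------------------------------------------------------

_RESILIENCE_VOLUMES = {"Positive Affect": 0.30, "Anxiety": 0.10, "Work": 0.25, "Death": 0.05}
_RESILIENCE_ALPHAS = {"Positive Affect": 0.7, "Anxiety": 1.4, "Work": 0.6, "Death": 1.8}
_RESILIENCE_PEAKS = {"Positive Affect": 12, "Anxiety": 8, "Work": 9, "Death": 2}


def shape_resilience_config(seed: int, n_users: int = 300) -> GeneratorConfig:
    """Category volumes change between regimes, hour modulation does not.

    Each category's planting probability at hour h is volume * shape(h)
    with a fixed cosine-bump shape (floored away from zero), and only the
    volume multiplier differs after the change -- so each category's
    expected hour profile is exactly scale-invariant across regimes.
    """
    hours = np.arange(24)
    shapes = {
        cat: (0.25 + 0.75 * (1 + np.cos(2 * np.pi * (hours - peak) / 24)) / 2).tolist()
        for cat, peak in _RESILIENCE_PEAKS.items()
    }
    volumes_after = {c: v * _RESILIENCE_ALPHAS[c] for c, v in _RESILIENCE_VOLUMES.items()}
    return GeneratorConfig(
        n_users=n_users,
        window_before=(date(2020, 2, 17), date(2020, 3, 1)),
        window_after=(date(2020, 3, 23), date(2020, 4, 5)),
        base_hour_rates=(1.5,) * 24,
        night_boost=1.0,
        morning_factor=1.0,
        weekend_factor=1.0,
        sleep_model_before=None,
        sleep_model_after=None,
        content_blocks=volume_scaled_blocks(_RESILIENCE_VOLUMES, volumes_after, shapes),
        filler_tokens_per_event=2,
        seed=child_seed(seed, 5),
    )


def shape_z_threshold(n_cells: int) -> float:
    """Simultaneous 3-sigma band over ``n_cells`` comparisons.

    A per-cell 3-sigma rule applied jointly to every (category, hour) cell
    would fire by chance with probability ~1 - 0.9973**n_cells (about 25%
    at 96 cells), so the band is Sidak-adjusted to keep the family
    false-alarm rate at the 3-sigma level; a genuine shape change grows as
    sqrt(n) and clears any fixed band.
    """
    from scipy import stats

    family_alpha = 2 * stats.norm.sf(3.0)
    per_cell = 1.0 - (1.0 - family_alpha) ** (1.0 / n_cells)
    return float(stats.norm.isf(per_cell / 2.0))


def check_shape_resilience(seed: int, n_users: int = 300) -> dict:
    """Per-category hour profiles before vs after must agree up to scale
    within Monte-Carlo noise when only category volumes change."""
    config = shape_resilience_config(seed, n_users)
    lexicon = generate_lexicon()
    events, _ = generate_event_stream(config)
    windows = AnalysisWindows(before=config.window_before, after=config.window_after)
    before, after, _ = split_periods(events, windows)

    max_z = 0.0
    max_dev = 0.0
    min_support = np.inf
    for cat in _RESILIENCE_VOLUMES:
        dim = lexicon.dimension_of(cat)
        counts = {}
        for period, frame in (("before", before), ("after", after)):
            assigned = lex.assign_items(frame, lexicon)
            hours = pd.to_datetime(frame["timestamp"]).dt.hour
            mask = assigned[dim].to_numpy() == cat
            counts[period] = (
                pd.Series(hours[mask]).value_counts().reindex(range(24), fill_value=0).to_numpy()
            )
        nb, na = counts["before"].sum(), counts["after"].sum()
        min_support = min(min_support, nb, na)
        pb, pa = counts["before"] / nb, counts["after"] / na
        pooled = (counts["before"] + counts["after"]) / (nb + na)
        se = np.sqrt(np.maximum(pooled * (1 - pooled), 1e-12) * (1 / nb + 1 / na))
        z = np.abs(pa - pb) / se
        max_z = max(max_z, float(z.max()))
        max_dev = max(max_dev, float(np.abs(pa - pb).max()))
    n_cells = 24 * len(_RESILIENCE_VOLUMES)
    return {
        "max_abs_z": max_z,
        "z_threshold": shape_z_threshold(n_cells),
        "max_abs_profile_dev": max_dev,
        "min_category_support": int(min_support),
        "n_categories": len(_RESILIENCE_VOLUMES),
    }


# ---------------------------------------------------------------------------
# Qualitative lockdown sign pattern
# ---------------------------------------------------------------------------


def check_lockdown_sign_pattern(seed: int, n_users: int = 200) -> dict:
    """Default lockdown conditions must reproduce the qualitative profile
    change: positive night delta, negative morning delta."""
    config = GeneratorConfig(n_users=n_users, generate_text=False, seed=child_seed(seed, 6))
    events, _ = generate_event_stream(config)
    before, after, _ = split_periods(events, AnalysisWindows())
    prof_b = circadian.activity_profile(circadian.counts_by_day_hour(before), "before")
    prof_a = circadian.activity_profile(circadian.counts_by_day_hour(after), "after")
    delta = circadian.relative_difference(prof_a, prof_b)
    night = sorted(config.night_boost_hours)
    morning = sorted(config.morning_hours)
    return {
        "night_delta_mean": float(delta[night].mean()),
        "morning_delta_mean": float(delta[morning].mean()),
        "night_delta_min": float(delta[night].min()),
        "morning_delta_max": float(delta[morning].max()),
        "n_events": int(len(events)),
    }
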