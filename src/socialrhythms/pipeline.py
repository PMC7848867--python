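"""Pipeline orchestration: simulate -> ingest -> analyses -> tidy reports.

``run_simulate`` writes a synthetic corpus (events, view series, lexicon)
with its ground-truth sidecar and a manifest carrying the config hash;
``run_analyze`` runs every analysis stage on a corpus -- circadian
profiles and relative differences, daypart/weekpart rates, hour-content
similarity and clustering, lexicon category fractions with KS period
comparison, and inter-event sleep inference -- writing tidy CSV tables, a
JSON summary of headline statistics, and line-delimited JSON stage logs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import circadian, content_similarity, interevent
from . import lexicon as lex
from .ingest import (
    AnalysisWindows,
    correct_view_frame,
    explode_view_increments,
    read_events,
    read_view_series,
    split_periods,
    write_events,
    write_view_series,
)
from .interevent import SleepEstimatorConfig
from .synthetic import GeneratorConfig, generate_event_stream, generate_lexicon, generate_view_series

logger = logging.getLogger("socialrhythms")


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, windows and analysis parameters for one pipeline run."""

    outdir: Path = Path("socialrhythms_out")
    events_path: Path | None = None
    views_path: Path | None = None
    lexicon_path: Path | None = None
    windows: AnalysisWindows = field(default_factory=AnalysisWindows)
    dayparts_tweetlike: circadian.DaypartConfig = circadian.TWITTER_DAYPARTS
    dayparts_viewlike: circadian.DaypartConfig = circadian.YOUTUBE_DAYPARTS
    sleep_estimator: SleepEstimatorConfig = field(default_factory=SleepEstimatorConfig)
    cluster_k: int = 5
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        """Build a config from a YAML mapping (flat keys mirroring the
        dataclass fields; dates as ISO strings), with keyword overrides."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update(overrides)
        kwargs: dict[str, Any] = {}
        for key in ("outdir", "events_path", "views_path", "lexicon_path"):
            if key in raw and raw[key] is not None:
                kwargs[key] = Path(raw[key])
        if "windows" in raw:
            w = raw["windows"]
            kwargs["windows"] = AnalysisWindows(
                before=tuple(date.fromisoformat(str(d)) for d in w["before"]),
                after=tuple(date.fromisoformat(str(d)) for d in w["after"]),
            )
        for key in ("cluster_k", "seed"):
            if key in raw:
                kwargs[key] = int(raw[key])
        if "night_hours_tweetlike" in raw:
            kwargs["dayparts_tweetlike"] = circadian.DaypartConfig(
                night_hours=frozenset(raw["night_hours_tweetlike"])
            )
        if "night_hours_viewlike" in raw:
            kwargs["dayparts_viewlike"] = circadian.DaypartConfig(
                night_hours=frozenset(raw["night_hours_viewlike"])
            )
        if "generator" in raw:
            gen = dict(raw["generator"])
            for wkey in ("window_before", "window_after"):
                if wkey in gen:
                    gen[wkey] = tuple(date.fromisoformat(str(d)) for d in gen[wkey])
            kwargs["generator"] = GeneratorConfig(**gen)
        return cls(**kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True).encode()
        ).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (date, Path)):
        return str(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


class _StageLog:
    """Line-delimited JSON log of pipeline stages and record counts."""

    def __init__(self, path: Path):
        self.path = path
        path.write_text("", encoding="utf-8")

    def write(self, stage: str, **fields: Any) -> None:
        rec = {"stage": stage, **_jsonable(fields)}
        with self.path.open("a", encoding="utf-8") as fh:
            fh.write(json.dumps(rec) + "\n")
        logger.info("stage %s: %s", stage, fields)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def run_simulate(config: PipelineConfig) -> dict:
    """Generate a corpus into ``outdir``; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    gen = config.generator
    rng = np.random.default_rng(gen.seed)

    events, truth_events = generate_event_stream(gen, rng)
    views, truth_views = generate_view_series(gen, rng)
    lexicon = generate_lexicon(gen)

    write_events(events, out / "events.jsonl", "jsonl")
    write_view_series(views, out / "views.csv")
    lex.save_lexicon(lexicon, out / "lexicon.json", "json")
    lex.save_lexicon(lexicon, out / "lexicon.dic", "dic")
    truth = {"events": truth_events, "views": truth_views}
    (out / "truth.json").write_text(json.dumps(_jsonable(truth)), encoding="utf-8")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": gen.seed,
        "files": ["events.jsonl", "views.csv", "lexicon.json", "lexicon.dic", "truth.json"],
        "n_events": int(len(events)),
        "n_videos": int(len(views)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------


def _stage(log: _StageLog, name: str):
    """Context manager tagging stage failures with the stage name."""

    class _Ctx:
        def __enter__(self):
            return None

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def run_analyze(config: PipelineConfig) -> dict:
    """Run every analysis stage; returns the summary dict.

    Outputs in ``outdir``: profile/delta/daypart-rate tables, similarity
    matrices and hour clusters, category fractions with KS tables, inter-
    event tables, ``summary.json`` and ``log.jsonl``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out / "log.jsonl")
    windows = config.windows

    events_path = config.events_path or out / "events.jsonl"
    views_path = config.views_path or out / "views.csv"
    lexicon_path = config.lexicon_path or out / "lexicon.json"

    with _stage(log, "load"):
        events, report = read_events(events_path, "jsonl")
        views = read_view_series(views_path)
        lexicon = lex.load_lexicon(lexicon_path, "json")
        log.write("load", n_events=len(events), n_videos=len(views), parse=report.to_dict())

    with _stage(log, "correct_views"):
        views = correct_view_frame(views)
        increments = explode_view_increments(views)
        increments = increments[increments["views"] > 0].reset_index(drop=True)
        log.write("correct_views", n_increment_cells=len(increments))

    with _stage(log, "split_periods"):
        ev_before, ev_after, ev_counts = split_periods(events, windows)
        inc_before, inc_after, inc_counts = split_periods(increments, windows)
        log.write("split_periods", events=ev_counts, view_cells=inc_counts)

    datasets = {
        "tweetlike": {
            "before": ev_before,
            "after": ev_after,
            "weight_col": None,
            "dayparts": config.dayparts_tweetlike,
        },
        "viewlike": {
            "before": inc_before,
            "after": inc_after,
            "weight_col": "views",
            "dayparts": config.dayparts_viewlike,
        },
    }

    with _stage(log, "circadian"):
        profile_rows, delta_rows, rate_rows, incr_rows, daily_rows = [], [], [], [], []
        for source, ds in datasets.items():
            profiles = {}
            rates = {}
            for period in ("before", "after"):
                counts = circadian.counts_by_day_hour(ds[period], weight_col=ds["weight_col"])
                profiles[period] = circadian.activity_profile(counts, period, source)
                profile_rows.append(profiles[period].to_frame())
                rates[period] = circadian.daypart_weekpart_rates(counts, ds["dayparts"], period)
                rates[period]["source"] = source
                rate_rows.append(rates[period])
                daily = circadian.rolling_daily_series(circadian.daily_totals(counts))
                daily_rows.append(
                    pd.DataFrame(
                        {"date": daily.index, "period": period, "source": source, "smoothed": daily.to_numpy()}
                    )
                )
            delta = circadian.relative_difference(profiles["after"], profiles["before"])
            delta_rows.append(pd.DataFrame({"hour": circadian.HOURS, "source": source, "delta": delta}))
            incs = circadian.daypart_rate_increments(rates["after"], rates["before"])
            incs["source"] = source
            incr_rows.append(incs)
        pd.concat(profile_rows).to_csv(out / "profiles.csv", index=False)
        pd.concat(delta_rows).to_csv(out / "profile_delta.csv", index=False)
        pd.concat(rate_rows).to_csv(out / "daypart_rates.csv", index=False)
        pd.concat(incr_rows).to_csv(out / "daypart_rate_increments.csv", index=False)
        pd.concat(daily_rows).to_csv(out / "daily_smoothed.csv", index=False)
        log.write("circadian", n_profiles=len(profile_rows))

    with _stage(log, "content_similarity"):
        cluster_rows = []
        for source, ds in datasets.items():
            key_kind = "hashtag" if source == "tweetlike" else "video_id"
            for period in ("before", "after"):
                sets = content_similarity.build_hour_sets(ds[period], period, key_kind)
                theta = content_similarity.time_similarity_matrix(sets)
                theta.to_frame().to_csv(out / f"theta_{source}_{period}.csv")
                labels = content_similarity.cluster_hours(theta, k=config.cluster_k, seed=config.seed)
                frame = content_similarity.cluster_frame(labels, period)
                frame["source"] = source
                cluster_rows.append(frame)
        pd.concat(cluster_rows).to_csv(out / "hour_clusters.csv", index=False)
        log.write("content_similarity", n_matrices=len(cluster_rows))

    with _stage(log, "lexicon_content"):
        ks_rows, daypart_rows = [], []
        assign_ev = {
            p: lex.assign_items(datasets["tweetlike"][p], lexicon) for p in ("before", "after")
        }
        video_assign = lex.assign_items(views, lexicon, text_col="title") if "title" in views else None
        for dim in lexicon.dimensions:
            samples = {}
            for period in ("before", "after"):
                ev = datasets["tweetlike"][period]
                samples[period] = lex.hourly_fraction_samples(
                    assign_ev[period][dim], ev["timestamp"], lexicon, dim
                )
                daypart = lex.daypart_profile(
                    assign_ev[period][dim], ev["timestamp"], lexicon, dim, period=period
                )
                daypart["source"], daypart["dimension"] = "tweetlike", dim
                daypart_rows.append(daypart)
            ks = lex.compare_periods_ks(samples["before"], samples["after"])
            ks["source"], ks["dimension"] = "tweetlike", dim
            ks_rows.append(ks)
            if video_assign is not None:
                vsamples = {}
                for period in ("before", "after"):
                    inc = datasets["viewlike"][period].merge(
                        video_assign.join(views["video_id"]), on="video_id", how="left"
                    )
                    vsamples[period] = lex.hourly_fraction_samples(
                        inc[dim], inc["timestamp"], lexicon, dim, weights=inc["views"]
                    )
                    daypart = lex.daypart_profile(
                        inc[dim], inc["timestamp"], lexicon, dim, weights=inc["views"], period=period
                    )
                    daypart["source"], daypart["dimension"] = "viewlike", dim
                    daypart_rows.append(daypart)
                vks = lex.compare_periods_ks(vsamples["before"], vsamples["after"])
                vks["source"], vks["dimension"] = "viewlike", dim
                ks_rows.append(vks)
        pd.concat(ks_rows).to_csv(out / "category_ks.csv", index=False)
        pd.concat(daypart_rows).to_csv(out / "category_dayparts.csv", index=False)
        log.write("lexicon_content", n_ks_rows=sum(len(k) for k in ks_rows))

    with _stage(log, "interevent"):
        sleep_rows, stat_rows = [], []
        for period in ("before", "after"):
            gaps = interevent.compute_gaps(datasets["tweetlike"][period], period)
            stat_rows.append(interevent.hourly_gap_stats(gaps, period))
            sleep_rows.append(interevent.sleep_probability(gaps, config.sleep_estimator, period))
        pd.concat(stat_rows).to_csv(out / "interevent_stats.csv", index=False)
        sleep = pd.concat(sleep_rows)
        sleep.to_csv(out / "sleep_probability.csv", index=False)
        log.write("interevent", n_hours=len(sleep))

    summary = run_report(config)
    log.write("done")
    return summary


def build_summary(outdir: str | Path, config: PipelineConfig) -> dict:
    """Headline statistics recomputed from the cached intermediate tables.

    Deterministic given the intermediates, so regenerating a report from a
    finished run is byte-identical.
    """
    out = Path(outdir)
    summary: dict[str, Any] = {}
    delta = pd.read_csv(out / "profile_delta.csv")
    night = {
        "tweetlike": sorted(config.dayparts_tweetlike.night_hours),
        "viewlike": sorted(config.dayparts_viewlike.night_hours),
    }
    for source, sub in delta.groupby("source"):
        summary[f"{source}_max_abs_delta"] = float(sub["delta"].abs().max())
        sub = sub.set_index("hour")["delta"]
        summary[f"{source}_night_delta_mean"] = float(sub.loc[night[source]].mean())
    ks = pd.read_csv(out / "category_ks.csv")
    summary["n_significant_categories_p05"] = int((ks["ks_pvalue"] < 0.05).sum())
    sleep = pd.read_csv(out / "sleep_probability.csv")
    ok = sleep.dropna(subset=["p_sleep"])
    for period, sub in ok.groupby("period"):
        summary[f"sleep_p_mean_{period}"] = float(sub["p_sleep"].mean())
    return summary


def run_report(config: PipelineConfig) -> dict:
    """(Re)build ``summary.json`` from the cached intermediates of a run."""
    out = Path(config.outdir)
    summary = {"seed": config.seed, "config_hash": config.config_hash()}
    summary.update(build_summary(out, config))
    (out / "summary.json").write_text(
        json.dumps(_jsonable(summary), sort_keys=True, indent=1), encoding="utf-8"
    )
    return summary
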