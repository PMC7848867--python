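from datetime import date

import numpy as np
import pandas as pd
import pytest

from socialrhythms.ingest import correct_view_series, view_total_columns
from socialrhythms.lexicon import DIMENSION_SCHEME, assign_items
from socialrhythms.synthetic import (
    ContentBlock,
    GeneratorConfig,
    SleepModel,
    generate_event_stream,
    generate_view_series,
    realized_vocabulary,
)


def _flat_config(**over):
    defaults = dict(
        n_users=50,
        window_before=(date(2020, 2, 17), date(2020, 2, 26)),
        window_after=(date(2020, 3, 23), date(2020, 4, 1)),
        base_hour_rates=(1.0,) * 24,
        night_boost=1.0,
        morning_factor=1.0,
        weekend_factor=1.0,
        sleep_model_before=None,
        sleep_model_after=None,
        generate_text=False,
        seed=7,
    )
    defaults.update(over)
    return GeneratorConfig(**defaults)


class TestConfigValidation:
    def test_bad_rates(self):
        with pytest.raises(ValueError):
            _flat_config(base_hour_rates=(0.0,) * 24)
        with pytest.raises(ValueError):
            _flat_config(base_hour_rates=(-1.0,) + (1.0,) * 23)
        with pytest.raises(ValueError):
            _flat_config(base_hour_rates=(1.0,) * 23)

    def test_bad_windows(self):
        with pytest.raises(ValueError):
            _flat_config(window_before=(date(2020, 3, 1), date(2020, 2, 1)))
        with pytest.raises(ValueError):
            _flat_config(window_after=(date(2020, 2, 20), date(2020, 2, 28)))

    def test_blocks_must_tile_day(self):
        block = ContentBlock("half", tuple(range(12)), {}, {})
        with pytest.raises(ValueError, match="24 hours"):
            _flat_config(content_blocks=(block,))

    def test_sleep_model_validation(self):
        with pytest.raises(ValueError):
            SleepModel(bedtime_probs={22: 0.5, 23: 0.4}, wake_probs={7: 1.0})
        with pytest.raises(ValueError):
            SleepModel(bedtime_probs={32: 1.0}, wake_probs={7: 1.0})  # bed after wake


class TestEventStream:
    def test_seed_determinism(self):
        config = _flat_config(generate_text=True, n_users=10)
        e1, t1 = generate_event_stream(config)
        e2, t2 = generate_event_stream(config)
        pd.testing.assert_frame_equal(e1, e2)
        assert t1["n_events"] == t2["n_events"]

    def test_uniform_rate_limit(self):
        """Flat rates without gating give hour fractions at 1/24 within
        three Monte-Carlo standard errors."""
        config = _flat_config(n_users=200)
        events, _ = generate_event_stream(config)
        hours = events["timestamp"].dt.hour.value_counts().reindex(range(24), fill_value=0)
        n = len(events)
        frac = hours / n
        se = np.sqrt((1 / 24) * (1 - 1 / 24) / n)
        assert np.abs(frac - 1 / 24).max() < 3 * se

    def test_night_boost_extinction(self):
        config = _flat_config(night_boost=0.0)
        events, _ = generate_event_stream(config)
        after = events[events["timestamp"] >= pd.Timestamp("2020-03-23")]
        night_hours = sorted(config.night_boost_hours)
        assert not after["timestamp"].dt.hour.isin(night_hours).any()
        before = events[events["timestamp"] < pd.Timestamp("2020-03-01")]
        assert before["timestamp"].dt.hour.isin(night_hours).any()

    def test_rate_recovery_within_five_percent(self):
        """Empirical per-hour rates converge to configured rates at
        >= 10,000 user-days of exposure."""
        config = _flat_config(
            n_users=500,
            window_before=(date(2020, 2, 17), date(2020, 3, 8)),
            window_after=(date(2020, 4, 13), date(2020, 4, 14)),
        )
        events, _ = generate_event_stream(config)
        before = events[events["timestamp"] < pd.Timestamp("2020-03-09")]
        n_user_days = 500 * 21
        assert n_user_days >= 10_000
        per_hour = before["timestamp"].dt.hour.value_counts().reindex(range(24), fill_value=0)
        rel_err = np.abs(per_hour / n_user_days - 1.0)
        assert rel_err.max() < 0.05

    def test_timestamps_inside_windows(self):
        config = _flat_config(n_users=20)
        events, _ = generate_event_stream(config)
        days = events["timestamp"].dt.date
        in_before = (days >= config.window_before[0]) & (days <= config.window_before[1])
        in_after = (days >= config.window_after[0]) & (days <= config.window_after[1])
        assert (in_before | in_after).all()

    def test_sleep_gating_silences_gap(self):
        model = SleepModel(bedtime_probs={23: 1.0}, wake_probs={7: 1.0})
        config = _flat_config(sleep_model_before=model, sleep_model_after=model, n_users=40)
        events, _ = generate_event_stream(config)
        hours = events["timestamp"].dt.hour
        assert not hours.isin([23, 0, 1, 2, 3, 4, 5, 6]).any()
        assert hours.isin([7]).any()


class TestViewSeries:
    def test_no_corrections_non_decreasing(self):
        config = _flat_config(correction_rate=0.0, n_videos=50)
        views, truth = generate_view_series(config)
        totals = views[view_total_columns(views)].to_numpy()
        assert (np.diff(totals, axis=1) >= 0).all()
        assert truth["n_corrupted"] == 0

    def test_total_removal_collapses_series(self):
        config = _flat_config(correction_rate=1.0, removal_frac_range=(1.0, 1.0), n_videos=10)
        views, _ = generate_view_series(config)
        totals = views[view_total_columns(views)].to_numpy()
        assert np.all(totals == 0.0)

    def test_corruption_then_correction_postconditions(self):
        """Corrected series are non-decreasing and preserve the corrupted
        final totals (the correction never invents or loses final views)."""
        config = _flat_config(correction_rate=0.05, n_videos=80)
        views, truth = generate_view_series(config)
        totals = views[view_total_columns(views)].to_numpy()
        corrected = correct_view_series(totals)
        assert (np.diff(corrected, axis=1) >= -1e-9).all()
        np.testing.assert_allclose(corrected[:, -1], totals[:, -1])
        assert truth["n_corrupted"] > 0

    def test_seed_determinism(self):
        config = _flat_config(n_videos=20)
        v1, _ = generate_view_series(config)
        v2, _ = generate_view_series(config)
        pd.testing.assert_frame_equal(v1, v2)


class TestLexiconGeneration:
    def test_general_affects_has_two_categories(self, toy_lexicon):
        assert len(toy_lexicon.categories("General Affects")) == 2

    def test_scheme_and_stem_counts(self, toy_lexicon):
        for dim, cats in DIMENSION_SCHEME.items():
            assert toy_lexicon.categories(dim) == cats
            for cat in cats:
                assert len(toy_lexicon.dimensions[dim][cat]) >= 5

    def test_stems_disjoint_across_categories(self, toy_lexicon):
        seen = set()
        for dim, cats in toy_lexicon.dimensions.items():
            for cat, patterns in cats.items():
                overlap = seen & set(patterns)
                assert not overlap
                seen |= set(patterns)

    def test_no_stem_is_prefix_of_another(self, toy_lexicon):
        stems = [p.rstrip("*") for cats in toy_lexicon.dimensions.values() for ps in cats.values() for p in ps]
        for a in stems:
            for b in stems:
                if a != b:
                    assert not b.startswith(a)
        # hence a realized word matches only its own category's patterns
        matcher = toy_lexicon.matcher()
        for cat in ("Positive Affect", "Death", "Fun"):
            for word in realized_vocabulary(cat):
                assert matcher.categories_of(word) == (cat,)

    def test_pure_category_document_assignment(self, toy_lexicon):
        words = " ".join(realized_vocabulary("Positive Affect")[:4])
        items = pd.DataFrame({"text": [words]})
        out = assign_items(items, toy_lexicon)
        assert out["General Affects"].iloc[0] == "Positive Affect"
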