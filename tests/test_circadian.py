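import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_counts
from socialrhythms.circadian import (
    CircadianProfile,
    DaypartConfig,
    activity_profile,
    counts_by_day_hour,
    daily_totals,
    daypart_rate_increments,
    daypart_weekpart_rates,
    relative_difference,
    relative_increment,
    rolling_daily_series,
)


class TestActivityProfile:
    def test_uniform_counts_give_flat_profile(self):
        counts = make_counts(5, fill=3.0)
        prof = activity_profile(counts, "before")
        np.testing.assert_allclose(prof.fractions, np.full(24, 1 / 24))
        assert prof.support == 5 * 24 * 3

    def test_concentrated_counts(self):
        counts = make_counts(2)
        counts.iloc[0, 0] = 12
        counts.iloc[1, 12] = 36
        prof = activity_profile(counts)
        assert prof.fractions[0] == 0.25 and prof.fractions[12] == 0.75
        assert prof.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_hour(self):
        counts = make_counts(3)
        counts[0] = 5.0
        prof = activity_profile(counts)
        assert prof.fractions[0] == 1.0 and prof.fractions[1:].sum() == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="undefined profile"):
            activity_profile(make_counts(3))

    @given(st.lists(st.integers(0, 50), min_size=24, max_size=24).filter(lambda v: sum(v) > 0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalization_invariant(self, hour_counts):
        counts = make_counts(1)
        counts.iloc[0] = hour_counts
        prof = activity_profile(counts)
        assert abs(prof.fractions.sum() - 1) < 1e-12 and (prof.fractions >= 0).all()


class TestRollingDaily:
    def test_constant_series_unchanged(self):
        daily = pd.Series(100.0, index=pd.date_range("2020-02-17", periods=20))
        np.testing.assert_allclose(rolling_daily_series(daily), 100.0)

    def test_single_spike_spread_over_window(self):
        daily = pd.Series(0.0, index=pd.date_range("2020-02-17", periods=15))
        daily.iloc[7] = 70.0
        smoothed = rolling_daily_series(daily, 7)
        assert smoothed.iloc[7] == pytest.approx(10.0)
        assert smoothed.iloc[3] == 0.0 and smoothed.iloc[11] == 0.0

    def test_window_one_is_identity(self):
        daily = pd.Series([1.0, 5.0, 2.0], index=pd.date_range("2020-02-17", periods=3))
        pd.testing.assert_series_equal(rolling_daily_series(daily, 1), daily)

    def test_even_window_rejected(self):
        daily = pd.Series([1.0], index=pd.date_range("2020-02-17", periods=1))
        with pytest.raises(ValueError):
            rolling_daily_series(daily, 4)


class TestRelativeDifference:
    def _profile(self, fractions, period="x"):
        return CircadianProfile(np.asarray(fractions, float), period=period, support=1.0)

    def test_identical_profiles_give_zero(self):
        p = self._profile(np.full(24, 1 / 24))
        np.testing.assert_allclose(relative_difference(p, p), 0.0)

    def test_tripled_fraction_gives_half(self):
        """f_after(h) = 3 f_before(h) yields delta(h) = (3-1)/(3+1) = 0.5."""
        fa, fb = np.zeros(24), np.zeros(24)
        fa[3], fb[3] = 0.75, 0.25
        fa[0], fb[0] = 0.25, 0.75
        delta = relative_difference(self._profile(fa), self._profile(fb))
        assert delta[3] == pytest.approx(0.5)
        assert delta[0] == pytest.approx(-0.5)

    def test_boundary_and_empty_hours(self):
        fa, fb = np.zeros(24), np.zeros(24)
        fa[0], fb[1] = 1.0, 1.0
        delta = relative_difference(self._profile(fa), self._profile(fb))
        assert delta[0] == 1.0 and delta[1] == -1.0 and delta[2] == 0.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounds_and_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        fa = rng.dirichlet(np.ones(24))
        fb = rng.dirichlet(np.ones(24))
        a, b = self._profile(fa), self._profile(fb)
        delta = relative_difference(a, b)
        assert np.all(delta >= -1) and np.all(delta <= 1)
        np.testing.assert_allclose(delta, -relative_difference(b, a))

    def test_source_mismatch_rejected(self):
        a = CircadianProfile(np.full(24, 1 / 24), source="events", support=1)
        b = CircadianProfile(np.full(24, 1 / 24), source="views", support=1)
        with pytest.raises(ValueError):
            relative_difference(a, b)


class TestDaypartRates:
    def test_uniform_stream_gives_unit_rates(self):
        counts = make_counts(14, fill=1.0)  # exactly one event per hour
        rates = daypart_weekpart_rates(counts, DaypartConfig())
        np.testing.assert_allclose(rates["rate"], 1.0)
        assert set(zip(rates["daypart"], rates["weekpart"])) == {
            ("night", "working"), ("night", "weekend"), ("day", "working"), ("day", "weekend")
        }

    def test_night_attribution_to_previous_evening(self):
        """A Saturday 02:00 event belongs to Friday's (working-day) night."""
        counts = make_counts(14)
        saturday = [i for i, d in enumerate(counts.index) if d.weekday() == 5][0]
        counts.iloc[saturday, 2] = 10.0
        rates = daypart_weekpart_rates(counts, DaypartConfig())
        by_cell = rates.set_index(["daypart", "weekpart"])["count"]
        assert by_cell[("night", "working")] == 10.0
        assert by_cell[("night", "weekend")] == 0.0

    def test_doubling_one_cell_is_local(self):
        counts = make_counts(14, fill=1.0)
        cfg = DaypartConfig()
        base = daypart_weekpart_rates(counts, cfg).set_index(["daypart", "weekpart"])["rate"]
        boosted = counts.copy()
        for i, day in enumerate(boosted.index):
            if day.weekday() < 5:  # working-day evening night hour
                boosted.iloc[i, 23] *= 3
        rates = daypart_weekpart_rates(boosted, cfg).set_index(["daypart", "weekpart"])["rate"]
        assert rates[("night", "working")] > base[("night", "working")]
        for cell in [("night", "weekend"), ("day", "working"), ("day", "weekend")]:
            assert rates[cell] == base[cell]

    def test_aggregation_associativity(self):
        """Rates from pooled counts equal rates recombined from week chunks:
        per-cell counts and exposures both add across chunks."""
        rng = np.random.default_rng(5)
        counts = make_counts(14)
        counts.iloc[:, :] = rng.integers(0, 30, size=(14, 24))
        key = ["daypart", "weekpart"]
        whole = daypart_weekpart_rates(counts).set_index(key)
        first = daypart_weekpart_rates(counts.iloc[:7]).set_index(key)
        second = daypart_weekpart_rates(counts.iloc[7:]).set_index(key)
        count_sum = first["count"] + second["count"]
        exposure_sum = (first["n_days"] + second["n_days"]) * whole["n_hours"]
        pd.testing.assert_series_equal(whole["count"], count_sum, check_names=False)
        np.testing.assert_allclose(whole["rate"], count_sum / exposure_sum)

    def test_increments(self):
        counts = make_counts(14, fill=1.0)
        a = daypart_weekpart_rates(counts * 2)
        b = daypart_weekpart_rates(counts)
        incs = daypart_rate_increments(a, b)
        np.testing.assert_allclose(incs["increment"], 1.0)
        assert relative_increment(3.0, 2.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            relative_increment(1.0, 0.0)

    def test_night_day_partition_enforced(self):
        with pytest.raises(ValueError):
            DaypartConfig(night_hours=frozenset(range(24)))


def test_counts_by_day_hour_roundtrip():
    from conftest import make_events

    events = make_events(
        [("2020-02-17 13:10", "u1"), ("2020-02-17 13:59:59", "u2"), ("2020-02-18 00:00", "u1")]
    )
    counts = counts_by_day_hour(events)
    assert counts.iloc[0, 13] == 2  # floor-hour convention: 13:59:59 is hour 13
    assert counts.iloc[1, 0] == 1
    assert daily_totals(counts).tolist() == [2, 1]
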