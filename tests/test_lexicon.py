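import numpy as np
import pandas as pd
import pytest

from conftest import make_events
from socialrhythms.lexicon import (
    FIVE_DAYPARTS,
    UNCLASSIFIED,
    CategoryLexicon,
    assign_category,
    assign_items,
    category_fractions,
    compare_periods_ks,
    daypart_profile,
    hourly_fraction_samples,
    load_lexicon,
    match_tokens,
    save_lexicon,
    tokenize,
)


@pytest.fixture()
def mini_lexicon():
    return CategoryLexicon(
        dimensions={
            "General Affects": {
                "Positive Affect": ("happ*", "pretty", "good"),
                "Negative Affect": ("sad*", "bad"),
            },
            "Thematic": {"Fun": ("good", "play*"), "Work": ("job", "office")},
        }
    )


class TestTokenize:
    def test_lowercase_split_and_accents(self):
        assert tokenize("C'est l'été, déjà!") == ["c", "est", "l", "ete", "deja"]

    def test_accents_kept_when_disabled(self):
        assert tokenize("été", strip_accents=False) == ["été"]


class TestMatching:
    def test_stem_wildcard_matches_completions(self, mini_lexicon):
        counts = match_tokens(["happy", "happiness", "happ"], mini_lexicon)
        assert counts["Positive Affect"] == 3

    def test_worked_example(self, mini_lexicon):
        counts = match_tokens(["happy", "good", "day"], mini_lexicon)
        assert counts["Positive Affect"] == 2

    def test_empty_tokens(self, mini_lexicon):
        assert all(v == 0 for v in match_tokens([], mini_lexicon).values())

    def test_token_counted_in_both_dimensions(self, mini_lexicon):
        counts = match_tokens(["good"], mini_lexicon)
        assert counts["Positive Affect"] == 1 and counts["Fun"] == 1


class TestAssignment:
    def test_strict_majority_wins(self, mini_lexicon):
        counts = {"Positive Affect": 2, "Negative Affect": 1}
        assert assign_category(counts, "General Affects", mini_lexicon) == "Positive Affect"

    def test_tie_is_unclassified(self, mini_lexicon):
        counts = {"Positive Affect": 2, "Negative Affect": 2}
        assert assign_category(counts, "General Affects", mini_lexicon) == UNCLASSIFIED

    def test_no_matches_is_unclassified(self, mini_lexicon):
        assert assign_category({}, "General Affects", mini_lexicon) == UNCLASSIFIED

    def test_ratio_band_option(self, mini_lexicon):
        counts = {"Positive Affect": 11, "Negative Affect": 10}
        assert assign_category(counts, "General Affects", mini_lexicon) == "Positive Affect"
        assert (
            assign_category(counts, "General Affects", mini_lexicon, tie_ratio=1.1)
            == UNCLASSIFIED
        )

    def test_frame_assignment_matches_scalar(self, mini_lexicon):
        items = pd.DataFrame({"text": ["happy good day", "sad bad happy", "job office", ""]})
        out = assign_items(items, mini_lexicon)
        assert list(out["General Affects"]) == [
            "Positive Affect",
            "Negative Affect",
            UNCLASSIFIED,
            UNCLASSIFIED,
        ]
        assert list(out["Thematic"]) == ["Fun", UNCLASSIFIED, "Work", UNCLASSIFIED]
        assert list(out["affect_count"]) == [2, 3, 0, 0]  # positive + negative together


class TestDialects:
    @pytest.mark.parametrize("dialect", ["json", "dic", "tsv"])
    def test_round_trip(self, tmp_path, toy_lexicon, dialect):
        path = tmp_path / f"lexicon.{dialect}"
        save_lexicon(toy_lexicon, path, dialect)
        back = load_lexicon(path, dialect)
        assert back.dimensions == toy_lexicon.dimensions

    def test_dic_wildcard_semantics(self, tmp_path):
        path = tmp_path / "toy.dic"
        path.write_text("%\n1\tPositive Affect\n2\tNegative Affect\n%\nhapp*\t1\nbad\t2\n")
        lex = load_lexicon(path, "dic")
        counts = match_tokens(["happy", "happiness", "bad"], lex)
        assert counts["Positive Affect"] == 2 and counts["Negative Affect"] == 1

    def test_unknown_category_in_mapping_rejected(self, tmp_path):
        path = tmp_path / "toy.tsv"
        path.write_text("NotACategory\tword\n")
        with pytest.raises(ValueError, match="dimension mapping"):
            load_lexicon(path, "tsv")

    def test_duplicate_pattern_warns_and_dedupes(self, tmp_path):
        path = tmp_path / "toy.tsv"
        path.write_text("Positive Affect\thapp*\nPositive Affect\thapp*\n")
        with pytest.warns(UserWarning, match="duplicate"):
            lex = load_lexicon(path, "tsv")
        assert lex.dimensions["General Affects"]["Positive Affect"] == ("happ*",)


class TestFractions:
    def test_single_category_fraction_one(self, mini_lexicon):
        assignments = pd.Series(["Fun", "Fun", "Fun"])
        table = category_fractions(assignments, mini_lexicon, "Thematic")
        by_cat = table.set_index("category")["fraction"]
        assert by_cat["Fun"] == 1.0 and by_cat["Work"] == 0.0 and by_cat[UNCLASSIFIED] == 0.0

    def test_view_weighted_fractions(self, mini_lexicon):
        assignments = pd.Series(["Fun", "Work"])
        table = category_fractions(
            assignments, mini_lexicon, "Thematic", weights=np.array([30.0, 10.0])
        )
        by_cat = table.set_index("category")["fraction"]
        assert by_cat["Fun"] == pytest.approx(0.75)
        assert by_cat["Work"] == pytest.approx(0.25)

    def test_weight_scale_invariance(self, mini_lexicon):
        assignments = pd.Series(["Fun", "Work", UNCLASSIFIED])
        w = np.array([3.0, 1.0, 2.0])
        t1 = category_fractions(assignments, mini_lexicon, "Thematic", weights=w)
        t2 = category_fractions(assignments, mini_lexicon, "Thematic", weights=2 * w)
        pd.testing.assert_frame_equal(t1, t2)

    def test_fractions_sum_to_one_per_bin(self, mini_lexicon):
        rng = np.random.default_rng(0)
        assignments = pd.Series(rng.choice(["Fun", "Work", UNCLASSIFIED], size=60))
        bins = pd.Series(rng.choice(["b1", "b2", "b3"], size=60))
        table = category_fractions(assignments, mini_lexicon, "Thematic", bins=bins)
        sums = table.groupby("bin")["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0)


class TestKS:
    def test_identical_samples(self, mini_lexicon):
        frame = pd.DataFrame({"category": ["Fun"] * 10, "fraction": np.linspace(0, 1, 10)})
        table = compare_periods_ks(frame, frame.copy())
        assert table["ks_stat"].iloc[0] == 0.0
        assert table["ks_pvalue"].iloc[0] == 1.0

    def test_disjoint_supports(self, mini_lexicon):
        before = pd.DataFrame({"category": ["Fun"] * 8, "fraction": np.linspace(0.0, 0.2, 8)})
        after = pd.DataFrame({"category": ["Fun"] * 8, "fraction": np.linspace(0.8, 1.0, 8)})
        table = compare_periods_ks(before, after)
        assert table["ks_stat"].iloc[0] == 1.0
        assert table["avg_before"].iloc[0] < table["avg_during"].iloc[0]

    def test_too_few_samples_rejected(self):
        frame = pd.DataFrame({"category": ["Fun"], "fraction": [0.5]})
        with pytest.raises(ValueError):
            compare_periods_ks(frame, frame)


class TestDayparts:
    def test_default_blocks_tile_day(self):
        assert sum(len(h) for h in FIVE_DAYPARTS.values()) == 24
        assert sorted(h for hours in FIVE_DAYPARTS.values() for h in hours) == list(range(24))

    def test_uniform_mixture_gives_equal_block_fractions(self, mini_lexicon):
        # two items per hour, alternating categories: every block sees 50/50
        rows = []
        for h in range(24):
            rows.append((f"2020-02-17 {h:02d}:00", "u", "good"))
            rows.append((f"2020-02-17 {h:02d}:30", "u", "job"))
        events = make_events(rows)
        assigned = assign_items(events, mini_lexicon)
        table = daypart_profile(assigned["Thematic"], events["timestamp"], mini_lexicon, "Thematic")
        fun = table[table["category"] == "Fun"].set_index("bin")["fraction"]
        assert len(fun) == 5 and np.allclose(fun, 0.5)

    def test_non_partition_blocks_rejected(self, mini_lexicon):
        events = make_events([("2020-02-17 10:00", "u", "good")])
        assigned = assign_items(events, mini_lexicon)
        with pytest.raises(ValueError, match="partition"):
            daypart_profile(
                assigned["Thematic"],
                events["timestamp"],
                mini_lexicon,
                "Thematic",
                blocks={"only": tuple(range(10))},
            )


def test_hourly_fraction_samples_granularity(mini_lexicon):
    events = make_events(
        [
            ("2020-02-17 10:05", "u", "good"),
            ("2020-02-17 10:45", "u", "job"),
            ("2020-02-18 10:30", "u", "good"),
        ]
    )
    assigned = assign_items(events, mini_lexicon)
    samples = hourly_fraction_samples(
        assigned["Thematic"], events["timestamp"], mini_lexicon, "Thematic"
    )
    fun = samples[samples["category"] == "Fun"].sort_values("bin")
    assert list(fun["fraction"]) == [0.5, 1.0]  # one sample per (day, hour) cell
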