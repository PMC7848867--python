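"""Lexicon-based emotion and theme categorization.

A category lexicon (LIWC-style) maps named categories -- grouped into the
three dimensions General Affects, Specific Emotions and Thematic -- to word
patterns, where a trailing ``*`` marks a stem that matches any completion
("happ*" matches "happy" and "happiness").  Items (tweets, or video
titles+descriptions) are assigned, per dimension, to the category with the
strictly largest number of matching terms; no matches or a tie leave the
item unclassified.  Category prevalence is then measured as count-weighted
fractions for tweet-like items and view-weighted fractions for video-like
items, per period and time bin, and compared across periods with two-sample
Kolmogorov-Smirnov tests on per-(day, hour) fraction samples.
"""

from __future__ import annotations

import json
import unicodedata
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DIMENSIONS = ("General Affects", "Specific Emotions", "Thematic")

#: Standard category -> dimension scheme used by the analyses.
DIMENSION_SCHEME: dict[str, tuple[str, ...]] = {
    "General Affects": ("Positive Affect", "Negative Affect"),
    "Specific Emotions": ("Sadness", "Anger", "Anxiety", "Accomplishment"),
    "Thematic": (
        "Work",
        "Social life",
        "Religion",
        "Death",
        "Leisure",
        "Exclusion",
        "Biology",
        "Money",
        "House",
        "Fun",
    ),
}

UNCLASSIFIED = "unclassified"

#: Five dayparts segmenting the 24 hours: late night, morning, midday,
#: afternoon, evening (19:00-24:00).
FIVE_DAYPARTS: dict[str, tuple[int, ...]] = {
    "0am-5am": tuple(range(0, 6)),
    "6am-9am": tuple(range(6, 10)),
    "10am-2pm": tuple(range(10, 15)),
    "3pm-6pm": tuple(range(15, 19)),
    "7pm-12pm": tuple(range(19, 24)),
}


# ---------------------------------------------------------------------------
# Lexicon container and dialects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategoryLexicon:
    """Word patterns per category, grouped into named dimensions."""

    dimensions: dict[str, dict[str, tuple[str, ...]]]
    language: str = "synthetic"

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for dim, cats in self.dimensions.items():
            for cat, patterns in cats.items():
                if cat in seen:
                    raise ValueError(f"category {cat!r} appears in both {seen[cat]!r} and {dim!r}")
                seen[cat] = dim
                if not patterns:
                    raise ValueError(f"category {cat!r} has no patterns")
                for pat in patterns:
                    if not pat or pat != pat.lower():
                        raise ValueError(f"patterns must be non-empty lowercase: {pat!r}")

    def categories(self, dimension: str) -> tuple[str, ...]:
        return tuple(self.dimensions[dimension])

    @property
    def all_categories(self) -> tuple[str, ...]:
        return tuple(c for cats in self.dimensions.values() for c in cats)

    def dimension_of(self, category: str) -> str:
        for dim, cats in self.dimensions.items():
            if category in cats:
                return dim
        raise KeyError(category)

    def matcher(self) -> "LexiconMatcher":
        return LexiconMatcher(self)


class LexiconMatcher:
    """Precompiled matcher: exact words in a dict, stems by prefix scan.

    Token lookups are memoized, so matching cost is governed by vocabulary
    size rather than corpus size.
    """

    def __init__(self, lexicon: CategoryLexicon):
        self.lexicon = lexicon
        self.exact: dict[str, tuple[str, ...]] = {}
        stems: list[tuple[str, str]] = []
        for dim, cats in lexicon.dimensions.items():
            for cat, patterns in cats.items():
                for pat in patterns:
                    if pat.endswith("*"):
                        stems.append((pat[:-1], cat))
                    else:
                        self.exact[pat] = self.exact.get(pat, ()) + (cat,)
        self.stems = tuple(stems)
        self._cache: dict[str, tuple[str, ...]] = {}

    def categories_of(self, token: str) -> tuple[str, ...]:
        hit = self._cache.get(token)
        if hit is None:
            cats = list(self.exact.get(token, ()))
            for stem, cat in self.stems:
                if token.startswith(stem) and cat not in cats:
                    cats.append(cat)
            hit = tuple(cats)
            self._cache[token] = hit
        return hit


def _dedupe(patterns: Iterable[str], cat: str) -> tuple[str, ...]:
    seen: list[str] = []
    for pat in patterns:
        if pat in seen:
            warnings.warn(f"duplicate pattern {pat!r} in category {cat!r}", stacklevel=3)
        else:
            seen.append(pat)
    return tuple(seen)


def _group_by_dimension(
    flat: Mapping[str, Sequence[str]], dimension_map: Mapping[str, str] | None
) -> dict[str, dict[str, tuple[str, ...]]]:
    cat_to_dim: dict[str, str] = {}
    for dim, cats in DIMENSION_SCHEME.items():
        for cat in cats:
            cat_to_dim[cat] = dim
    if dimension_map:
        cat_to_dim.update(dimension_map)
    grouped: dict[str, dict[str, tuple[str, ...]]] = {}
    for cat, patterns in flat.items():
        dim = cat_to_dim.get(cat)
        if dim is None:
            raise ValueError(f"category {cat!r} has no dimension mapping")
        grouped.setdefault(dim, {})[cat] = _dedupe(patterns, cat)
    return grouped


def load_lexicon(
    path: str | Path,
    dialect: str = "json",
    dimension_map: Mapping[str, str] | None = None,
    language: str = "unknown",
) -> CategoryLexicon:
    """Load a lexicon in the ``json``, ``dic`` (LIWC-style) or ``tsv`` dialect.

    The JSON dialect is either ``{dimension: {category: [patterns]}}`` or a
    flat ``{category: [patterns]}``; flat dialects (.dic, .tsv, flat JSON)
    map categories onto dimensions via :data:`DIMENSION_SCHEME`, extended or
    overridden by ``dimension_map``.
    """
    path = Path(path)
    if dialect == "json":
        data = json.loads(path.read_text(encoding="utf-8"))
        if data and all(isinstance(v, dict) for v in data.values()):
            grouped = {
                dim: {cat: _dedupe(pats, cat) for cat, pats in cats.items()}
                for dim, cats in data.items()
            }
            return CategoryLexicon(dimensions=grouped, language=language)
        return CategoryLexicon(_group_by_dimension(data, dimension_map), language=language)
    if dialect == "dic":
        return _load_dic(path, dimension_map, language)
    if dialect == "tsv":
        flat: dict[str, list[str]] = {}
        for line in path.read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cat, pattern = line.split("\t")
            flat.setdefault(cat, []).append(pattern)
        return CategoryLexicon(_group_by_dimension(flat, dimension_map), language=language)
    raise ValueError(f"unknown lexicon dialect {dialect!r}")


def _load_dic(path: Path, dimension_map, language: str) -> CategoryLexicon:
    """LIWC-style .dic: a %-delimited header of ``id<TAB>name`` lines, then
    ``word<TAB>id [id...]`` lines."""
    text = path.read_text(encoding="utf-8")
    parts = text.split("%")
    if len(parts) < 3:
        raise ValueError(f"{path}: not a LIWC-style .dic (missing % header)")
    id_to_cat: dict[str, str] = {}
    for line in parts[1].strip().splitlines():
        if not line.strip():
            continue
        cat_id, name = line.split("\t", 1)
        id_to_cat[cat_id.strip()] = name.strip()
    flat: dict[str, list[str]] = {name: [] for name in id_to_cat.values()}
    for line in "%".join(parts[2:]).strip().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        word, ids = fields[0].strip(), fields[1:]
        for cat_id in ids:
            cat_id = cat_id.strip()
            if cat_id not in id_to_cat:
                raise ValueError(f"{path}: word {word!r} references unknown category id {cat_id}")
            flat[id_to_cat[cat_id]].append(word)
    return CategoryLexicon(_group_by_dimension(flat, dimension_map), language=language)


def save_lexicon(lexicon: CategoryLexicon, path: str | Path, dialect: str = "json") -> None:
    path = Path(path)
    if dialect == "json":
        data = {
            dim: {cat: list(pats) for cat, pats in cats.items()}
            for dim, cats in lexicon.dimensions.items()
        }
        path.write_text(json.dumps(data, indent=1, ensure_ascii=False), encoding="utf-8")
    elif dialect == "dic":
        cats = lexicon.all_categories
        ids = {cat: str(i + 1) for i, cat in enumerate(cats)}
        lines = ["%"]
        lines += [f"{ids[cat]}\t{cat}" for cat in cats]
        lines.append("%")
        word_ids: dict[str, list[str]] = {}
        for dim_cats in lexicon.dimensions.values():
            for cat, pats in dim_cats.items():
                for pat in pats:
                    word_ids.setdefault(pat, []).append(ids[cat])
        lines += [f"{word}\t" + "\t".join(idlist) for word, idlist in word_ids.items()]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif dialect == "tsv":
        lines = [
            f"{cat}\t{pat}"
            for dim_cats in lexicon.dimensions.values()
            for cat, pats in dim_cats.items()
            for pat in pats
        ]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown lexicon dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Tokenization and matching
# ---------------------------------------------------------------------------


def tokenize(text: str, strip_accents: bool = True) -> list[str]:
    """Lowercase and split on non-alphanumeric characters.

    Accent stripping is on by default (word-form matching against a French
    lexicon treats "é" and "e" alike).
    """
    text = text.lower()
    if strip_accents:
        text = "".join(
            c for c in unicodedata.normalize("NFKD", text) if not unicodedata.combining(c)
        )
    tokens, current = [], []
    for ch in text:
        if ch.isalnum():
            current.append(ch)
        elif current:
            tokens.append("".join(current))
            current = []
    if current:
        tokens.append("".join(current))
    return tokens


def match_tokens(
    tokens: Sequence[str], lexicon: CategoryLexicon | LexiconMatcher
) -> dict[str, int]:
    """Count, per category, how many of the tokens match one of its patterns.

    A token can contribute to several categories (in the same or different
    dimensions) if it matches patterns of each.
    """
    matcher = lexicon if isinstance(lexicon, LexiconMatcher) else lexicon.matcher()
    counts = {cat: 0 for cat in matcher.lexicon.all_categories}
    for token in tokens:
        for cat in matcher.categories_of(token):
            counts[cat] += 1
    return counts


def assign_category(
    counts: Mapping[str, int],
    dimension: str,
    lexicon: CategoryLexicon,
    tie_ratio: float = 1.0,
) -> str:
    """Prevalent-category assignment within one dimension.

    The winning category must have a strictly maximal match count; zero
    matches, an exact tie, or (with ``tie_ratio > 1``) a top-two ratio at or
    below ``tie_ratio`` ("similar proportions") leave the item unclassified.
    """
    cats = lexicon.categories(dimension)
    values = np.array([counts.get(c, 0) for c in cats], dtype=float)
    order = np.argsort(values)
    best, second = values[order[-1]], values[order[-2]] if len(cats) > 1 else 0.0
    if best == 0 or best == second:
        return UNCLASSIFIED
    if tie_ratio > 1.0 and second > 0 and best / second <= tie_ratio:
        return UNCLASSIFIED
    return cats[int(order[-1])]


def assign_items(
    items: pd.DataFrame,
    lexicon: CategoryLexicon,
    text_col: str = "text",
    strip_accents: bool = True,
    tie_ratio: float = 1.0,
) -> pd.DataFrame:
    """Categorize every item on all three dimensions (vectorized).

    Returns a frame aligned with ``items`` carrying one assignment column
    per dimension plus ``affect_count`` (positive + negative matches
    together, the global emotional level of the item).
    """
    matcher = lexicon.matcher()
    n = len(items)
    token_lists = [tokenize(t, strip_accents) for t in items[text_col].fillna("")]

    # explode to a token table once, map tokens to categories via the cache
    lengths = np.array([len(toks) for toks in token_lists])
    owner = np.repeat(np.arange(n), lengths)
    flat = [tok for toks in token_lists for tok in toks]
    cat_rows: dict[str, np.ndarray] = {}
    all_cats = lexicon.all_categories
    counts = np.zeros((n, len(all_cats)), dtype=np.int64)
    cat_index = {c: j for j, c in enumerate(all_cats)}
    for i, tok in zip(owner, flat):
        for cat in matcher.categories_of(tok):
            counts[i, cat_index[cat]] += 1

    out = pd.DataFrame(index=items.index)
    for dim in lexicon.dimensions:
        cats = lexicon.categories(dim)
        sub = counts[:, [cat_index[c] for c in cats]]
        best_idx = np.argmax(sub, axis=1)
        best = sub[np.arange(n), best_idx] if n else np.array([], dtype=int)
        sub_sorted = np.sort(sub, axis=1)
        second = sub_sorted[:, -2] if sub.shape[1] > 1 else np.zeros(n, dtype=int)
        labels = np.array([cats[i] for i in best_idx], dtype=object) if n else np.array([], object)
        unclass = (best == 0) | (best == second)
        if tie_ratio > 1.0:
            with np.errstate(divide="ignore", invalid="ignore"):
                unclass |= (second > 0) & (best / np.maximum(second, 1) <= tie_ratio)
        labels[unclass] = UNCLASSIFIED
        out[dim] = labels
    pos = counts[:, cat_index["Positive Affect"]] if "Positive Affect" in cat_index else 0
    neg = counts[:, cat_index["Negative Affect"]] if "Negative Affect" in cat_index else 0
    out["affect_count"] = pos + neg
    return out


# ---------------------------------------------------------------------------
# Fractions, period comparison, daypart profiles
# ---------------------------------------------------------------------------


def category_fractions(
    assignments: pd.Series,
    lexicon: CategoryLexicon,
    dimension: str,
    weights: np.ndarray | pd.Series | None = None,
    bins: pd.Series | None = None,
    period: str = "",
) -> pd.DataFrame:
    """Weighted fraction of items per category (and unclassified) per bin.

    ``weights`` is 1 per tweet-like item or the item's view count in the
    bin for video-like items; ``bins`` labels each item's time bin (omit for
    a single whole-period bin).  Within each bin the category fractions plus
    the unclassified fraction sum to 1; zero-weight bins are flagged NaN.
    """
    labels = list(lexicon.categories(dimension)) + [UNCLASSIFIED]
    w = np.ones(len(assignments)) if weights is None else np.asarray(weights, dtype=float)
    frame = pd.DataFrame(
        {
            "category": assignments.to_numpy(),
            "bin": "all" if bins is None else bins.to_numpy(),
            "w": w,
        }
    )
    pivot = frame.pivot_table(index="bin", columns="category", values="w", aggfunc="sum", fill_value=0.0)
    pivot = pivot.reindex(columns=labels, fill_value=0.0)
    totals = pivot.sum(axis=1)
    if (totals == 0).any():
        warnings.warn("zero total weight in some bins; fractions undefined (NaN)", stacklevel=2)
    fractions = pivot.div(totals.replace(0.0, np.nan), axis=0)
    tidy = fractions.reset_index().melt(id_vars="bin", var_name="category", value_name="fraction")
    tidy["period"] = period
    return tidy[["category", "period", "bin", "fraction"]]


def hourly_fraction_samples(
    assignments: pd.Series,
    timestamps: pd.Series,
    lexicon: CategoryLexicon,
    dimension: str,
    weights: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-(day, hour) weighted category fractions -- the samples on which
    the before/during distributional comparison operates."""
    ts = pd.to_datetime(timestamps)
    bins = ts.dt.strftime("%Y-%m-%d:%H")
    tidy = category_fractions(assignments, lexicon, dimension, weights=weights, bins=bins)
    return tidy.dropna(subset=["fraction"])


def compare_periods_ks(
    before_samples: pd.DataFrame,
    after_samples: pd.DataFrame,
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Two-sample Kolmogorov-Smirnov comparison of per-(day, hour) category
    fractions before vs during the study event.

    Returns one row per category with the mean fraction in each period and
    the KS statistic and p-value, mirroring a category / avg-before /
    avg-during / p-value results table.
    """
    if categories is None:
        categories = sorted(set(before_samples["category"]) | set(after_samples["category"]))
    rows = []
    for cat in categories:
        b = before_samples.loc[before_samples["category"] == cat, "fraction"].to_numpy()
        a = after_samples.loc[after_samples["category"] == cat, "fraction"].to_numpy()
        if len(b) < 2 or len(a) < 2:
            raise ValueError(f"need at least 2 samples per period for category {cat!r}")
        res = stats.ks_2samp(b, a)
        rows.append(
            {
                "category": cat,
                "avg_before": float(b.mean()),
                "avg_during": float(a.mean()),
                "ks_stat": float(res.statistic),
                "ks_pvalue": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)


def daypart_profile(
    assignments: pd.Series,
    timestamps: pd.Series,
    lexicon: CategoryLexicon,
    dimension: str,
    weights: np.ndarray | pd.Series | None = None,
    blocks: Mapping[str, Sequence[int]] | None = None,
    period: str = "",
) -> pd.DataFrame:
    """Category fractions within each configured daypart block.

    ``blocks`` must partition the 24 hours (default: the five dayparts
    0am-5am / 6am-9am / 10am-2pm / 3pm-6pm / 7pm-12pm).
    """
    blocks = dict(blocks) if blocks is not None else dict(FIVE_DAYPARTS)
    covered = [h for hours in blocks.values() for h in hours]
    if sorted(covered) != list(range(24)):
        raise ValueError("daypart blocks must partition hours 0..23")
    hour_to_block = {h: name for name, hours in blocks.items() for h in hours}
    bins = pd.to_datetime(timestamps).dt.hour.map(hour_to_block)
    return category_fractions(
        assignments, lexicon, dimension, weights=weights, bins=bins, period=period
    )


def daypart_profile_delta(before: pd.DataFrame, after: pd.DataFrame) -> pd.DataFrame:
    """Before -> after change of daypart fractions (per category and block)."""
    key = ["category", "bin"]
    b = before.set_index(key)["fraction"]
    a = after.set_index(key)["fraction"]
    out = pd.DataFrame({"fraction_before": b, "fraction_after": a})
    out["delta"] = a - b
    return out.reset_index()
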