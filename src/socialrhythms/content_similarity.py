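"""Hour-content similarity: which hours of the day share the same content?

For each day ``d`` and hour ``h`` a content set ``K(d, h)`` is built --
hashtags posted in that hour for tweet-like data, ids of videos watched in
that hour for view-like data.  The 24x24 time-similarity matrix averages
the Jaccard similarity of the two hours' sets over days,

    Theta(h1, h2) = (1 / N_days) * sum_d J(K(d, h1), K(d, h2)),

and k-means on the rows of Theta segments the day into content regimes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .circadian import HOURS


@dataclass(frozen=True)
class HourContentSets:
    """Per-(day, hour) content-key sets over one period."""

    sets: dict[tuple[date, int], frozenset[str]]
    days: tuple[date, ...]
    period: str = ""
    key_kind: str = "hashtag"

    def get(self, day: date, hour: int) -> frozenset[str]:
        return self.sets.get((day, hour), frozenset())


@dataclass(frozen=True)
class HourSimilarityMatrix:
    """Day-averaged Jaccard similarity between the 24 hours' content sets."""

    theta: np.ndarray
    n_days: int
    period: str = ""

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", theta)
        if theta.shape != (24, 24):
            raise ValueError("theta must be 24x24")
        if np.any(theta < -1e-12) or np.any(theta > 1 + 1e-12):
            raise ValueError("theta entries must lie in [0, 1]")
        if not np.allclose(theta, theta.T):
            raise ValueError("theta must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=HOURS, columns=HOURS)


def build_hour_sets(
    frame: pd.DataFrame,
    period: str = "",
    key_kind: str = "hashtag",
) -> HourContentSets:
    """Collect the content keys seen in each (day, hour) cell.

    ``key_kind='hashtag'`` unions the ``hashtags`` lists of tweet-like
    events; ``key_kind='video_id'`` collects ids of videos with a positive
    ``views`` increment in the cell.  Cells without content get empty sets.
    """
    if key_kind not in {"hashtag", "video_id"}:
        raise ValueError(f"unknown key_kind {key_kind!r}")
    sets: dict[tuple[date, int], set[str]] = {}
    if len(frame):
        ts = pd.to_datetime(frame["timestamp"])
        days_col = ts.dt.date.to_numpy()
        hours_col = ts.dt.hour.to_numpy()
        if key_kind == "hashtag":
            for day, hour, tags in zip(days_col, hours_col, frame["hashtags"]):
                if tags:
                    sets.setdefault((day, int(hour)), set()).update(tags)
        else:
            mask = frame["views"].to_numpy(dtype=float) > 0
            for day, hour, vid in zip(
                days_col[mask], hours_col[mask], frame.loc[mask, "video_id"]
            ):
                sets.setdefault((day, int(hour)), set()).add(str(vid))
        days = tuple(sorted(set(days_col)))
    else:
        days = ()
    frozen = {cell: frozenset(keys) for cell, keys in sets.items()}
    n_empty = len(days) * 24 - len(frozen)
    if n_empty:
        warnings.warn(f"{n_empty} empty (day, hour) content cells", stacklevel=2)
    return HourContentSets(sets=frozen, days=days, period=period, key_kind=key_kind)


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """Jaccard similarity |A & B| / |A | B|; two empty sets give 0."""
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def time_similarity_matrix(sets: HourContentSets) -> HourSimilarityMatrix:
    """Entrywise day-average of Jaccard similarities between hour sets.

    Every day counts in the ``N_days`` normalization, including days where a
    cell is empty (empty-vs-anything similarity is 0).
    """
    if not sets.days:
        raise ValueError("need at least one day of content sets")
    theta = np.zeros((24, 24))
    for day in sets.days:
        day_sets = [sets.get(day, h) for h in range(24)]
        for h1 in range(24):
            theta[h1, h1] += jaccard(day_sets[h1], day_sets[h1])
            for h2 in range(h1 + 1, 24):
                sim = jaccard(day_sets[h1], day_sets[h2])
                theta[h1, h2] += sim
                theta[h2, h1] += sim
    theta /= len(sets.days)
    return HourSimilarityMatrix(theta=theta, n_days=len(sets.days), period=sets.period)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters in order of first appearance (hour 0 upward)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_hours(
    matrix: HourSimilarityMatrix | np.ndarray,
    k: int = 5,
    seed: int = 0,
    n_init: int = 10,
) -> np.ndarray:
    """Partition the 24 hours into ``k`` content clusters.

    The rows of Theta are the feature vectors; k-means is restarted
    ``n_init`` times with a fixed seed and labels are canonicalized by first
    appearance, so a given (matrix, k, seed) is fully deterministic.
    """
    theta = matrix.theta if isinstance(matrix, HourSimilarityMatrix) else np.asarray(matrix, float)
    if not 2 <= k <= 24:
        raise ValueError("k must be in [2, 24]")
    if np.allclose(theta, theta.flat[0]):
        warnings.warn("degenerate similarity matrix: all hours identical, single cluster", stacklevel=2)
        return np.zeros(24, dtype=int)
    if k == 24:
        return np.arange(24)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(theta)
    return _canonical_labels(labels)


def cluster_frame(labels: np.ndarray, period: str = "") -> pd.DataFrame:
    return pd.DataFrame({"hour": HOURS, "period": period, "cluster": labels})
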