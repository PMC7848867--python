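from datetime import date, datetime

import numpy as np
import pandas as pd
import pytest

from socialrhythms.synthetic import GeneratorConfig, generate_lexicon


@pytest.fixture(scope="session")
def toy_lexicon():
    return generate_lexicon()


@pytest.fixture()
def small_config():
    """A small two-regime corpus configuration for fast end-to-end tests."""
    return GeneratorConfig(
        n_users=30,
        n_videos=40,
        window_before=(date(2020, 2, 17), date(2020, 2, 23)),
        window_after=(date(2020, 3, 23), date(2020, 3, 29)),
        seed=123,
    )


def make_events(rows):
    """Events frame from (timestamp, user, text, hashtags) tuples."""
    return pd.DataFrame(
        {
            "timestamp": pd.to_datetime([r[0] for r in rows], format="mixed"),
            "user_id": [r[1] for r in rows],
            "text": [r[2] if len(r) > 2 else "" for r in rows],
            "hashtags": [list(r[3]) if len(r) > 3 else [] for r in rows],
        }
    )


def make_counts(days, fill=0.0):
    """Day x hour count table over consecutive dates starting Mon 2020-02-17."""
    idx = pd.date_range("2020-02-17", periods=days, freq="D").date
    return pd.DataFrame(fill, index=pd.Index(idx, name="date"), columns=np.arange(24))
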