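import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from newsaffect.lexicon import RawLexiconEntry, standardize
from newsaffect.preprocess import DailyPool, TokenAffect

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture
def tiny_entries():
    """Five-word lexicon with hand-picked, non-degenerate raw ratings."""
    rows = [
        ("calm", 7.0, 2.0, 6.0),
        ("panic", 2.5, 8.0, 3.0),
        ("virus", 3.0, 6.5, 4.0),
        ("hope", 7.5, 5.0, 6.5),
        ("tax", 4.0, 4.5, 5.0),
    ]
    return [RawLexiconEntry(w, v, a, d) for w, v, a, d in rows]


@pytest.fixture
def tiny_lexicon(tiny_entries):
    return standardize(tiny_entries)


def make_pool(vectors, state="AA", date=dt.date(2020, 4, 1), n_raw=None):
    """Build a DailyPool directly from (V, A, D) token vectors."""
    tokens = tuple(
        TokenAffect(f"w{i}", float(v), float(a), float(d))
        for i, (v, a, d) in enumerate(vectors)
    )
    return DailyPool(
        state=state, date=date, tokens=tokens,
        n_raw_tokens=len(tokens) if n_raw is None else n_raw,
    )


def write_lexicon_csv(path, rows, header="word,valence,arousal,dominance"):
    path.write_text(header + "\n" + "\n".join(",".join(map(str, r)) for r in rows) + "\n")
    return path
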