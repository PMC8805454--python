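"""Headline cleaning, lexicon mapping, and state/day pooling.

The cleaning rules mirror the standard dictionary-scoring recipe: lowercase,
strip every non-alphabetic character, drop stop words. Surviving tokens are
matched against the standardized affect lexicon by exact string; words a day
uses repeatedly count once per occurrence (token weighting), so daily means
and spreads reflect actual exposure rather than vocabulary size.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._stopwords import ENGLISH_STOPWORDS
from .lexicon import AffectLexicon

__all__ = [
    "HeadlineRecord",
    "TokenAffect",
    "DailyPool",
    "preprocess_title",
    "map_tokens",
    "pool_daily",
    "mapping_rate",
    "load_headlines",
    "default_stopwords",
]

log = logging.getLogger(__name__)

_NON_ALPHA = re.compile(r"[^a-z]+")


@dataclass(frozen=True)
class HeadlineRecord:
    state: str
    date: dt.date
    title: str


@dataclass(frozen=True)
class TokenAffect:
    """A single mapped token with its lexicon z-scores."""

    word: str
    V: float
    A: float
    D: float


@dataclass(frozen=True)
class DailyPool:
    """All mapped tokens for one (state, date), repeats kept.

    ``n_raw_tokens`` counts cleaned non-stop-word tokens before lexicon
    mapping, so ``len(tokens) / n_raw_tokens`` is the day's mapping rate.
    """

    state: str
    date: dt.date
    tokens: tuple[TokenAffect, ...]
    n_raw_tokens: int

    @property
    def n_mapped(self) -> int:
        return len(self.tokens)


def default_stopwords(additions: str | Path | None = None) -> frozenset[str]:
    """The built-in English stop list, optionally extended from a text file.

    The additions file holds one word per line (blank lines and ``#`` comments
    ignored); words are lowercased before inclusion.
    """
    words = set(ENGLISH_STOPWORDS)
    if additions is not None:
        for line in Path(additions).read_text().splitlines():
            word = line.strip().lower()
            if word and not word.startswith("#"):
                words.add(word)
    return frozenset(words)


def preprocess_title(title: str, stopwords: Iterable[str] | None = None) -> list[str]:
    """Clean one headline into lowercase alphabetic non-stop-word tokens.

    Splitting happens on any run of non-alphabetic characters, so hyphenated
    or digit-attached forms ("covid-19") shed their non-letter parts. Tokens
    emptied entirely by stripping are dropped; order is preserved.
    """
    stop = ENGLISH_STOPWORDS if stopwords is None else set(stopwords)
    tokens = _NON_ALPHA.split(title.lower())
    return [tok for tok in tokens if tok and tok not in stop]


def map_tokens(tokens: Sequence[str], lexicon: AffectLexicon) -> list[TokenAffect]:
    """Look tokens up in the lexicon; out-of-vocabulary tokens are dropped.

    Duplicates are retained as separate elements — pooling is token-weighted.
    """
    mapped = []
    for tok in tokens:
        if tok in lexicon:
            v, a, d = lexicon[tok]
            mapped.append(TokenAffect(tok, v, a, d))
    return mapped


def pool_daily(
    headlines: Sequence[HeadlineRecord],
    lexicon: AffectLexicon,
    stopwords: Iterable[str] | None = None,
) -> list[DailyPool]:
    """Pool mapped tokens by (state, date) across all of that day's headlines.

    Every (state, date) with at least one headline yields a pool, even when no
    token maps (the pool is then empty and downstream features are missing).
    The corpus-level mapping rate is logged as a diagnostic.
    """
    stop = ENGLISH_STOPWORDS if stopwords is None else frozenset(stopwords)
    buckets: dict[tuple[str, dt.date], tuple[list[TokenAffect], int]] = {}
    for rec in headlines:
        toks = preprocess_title(rec.title, stop)
        mapped = map_tokens(toks, lexicon)
        key = (rec.state, rec.date)
        if key not in buckets:
            buckets[key] = ([], 0)
        bucket, _ = buckets[key]
        bucket.extend(mapped)
        buckets[key] = (bucket, buckets[key][1] + len(toks))
    pools = [
        DailyPool(state=s, date=d, tokens=tuple(toks), n_raw_tokens=nraw)
        for (s, d), (toks, nraw) in sorted(buckets.items())
    ]
    n_raw = sum(p.n_raw_tokens for p in pools)
    n_mapped = sum(p.n_mapped for p in pools)
    if n_raw:
        log.info(
            "lexicon mapping rate: %d/%d tokens (%.2f%%)",
            n_mapped, n_raw, 100.0 * n_mapped / n_raw,
        )
    return pools


def mapping_rate(pools: Sequence[DailyPool]) -> float:
    """Corpus mapping rate n_mapped / n_raw over a set of pools (0 when empty)."""
    n_raw = sum(p.n_raw_tokens for p in pools)
    if n_raw == 0:
        return 0.0
    return sum(p.n_mapped for p in pools) / n_raw


def load_headlines(path: str | Path) -> list[HeadlineRecord]:
    """Read a headline table (CSV with columns state, date, title; ISO dates).

    Rows with an empty title after whitespace trimming are rejected.
    """
    table = pd.read_csv(path, dtype={"state": str, "title": str})
    required = {"state", "date", "title"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"headline file {path} missing columns: {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        title = str(row["title"]).strip()
        if not title:
            raise ValueError(
                f"empty headline title for state={row['state']} date={row['date']}"
            )
        records.append(
            HeadlineRecord(
                state=str(row["state"]),
                date=pd.Timestamp(row["date"]).date(),
                title=title,
            )
        )
    return records
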