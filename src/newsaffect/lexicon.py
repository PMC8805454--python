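"""Valence/arousal/dominance affect lexicon: loading, validation, z-standardization.

The scoring dictionary is a word table with crowdsourced ratings of valence
(pleasantness), arousal (intensity) and dominance (control) on a 1-9 scale.
Before any scoring, every dimension is z-standardized over the lexicon's own
entries, so downstream affect values are in SD units relative to the dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawLexiconEntry",
    "AffectLexicon",
    "LexiconFormatError",
    "LexiconValidationError",
    "DegenerateLexiconError",
    "load_lexicon",
    "standardize",
    "write_standardized",
]

DIMENSIONS = ("valence", "arousal", "dominance")

#: default column names expected in a lexicon file; override with ``columns=``
DEFAULT_COLUMNS: dict[str, str] = {
    "word": "word",
    "valence": "valence",
    "arousal": "arousal",
    "dominance": "dominance",
}


class LexiconFormatError(ValueError):
    """Raised when the lexicon file cannot be parsed into the expected table."""


class LexiconValidationError(ValueError):
    """Raised when a parsed row violates a lexicon invariant."""


class DegenerateLexiconError(ValueError):
    """Raised when a rating dimension has zero spread and cannot be standardized."""


@dataclass(frozen=True)
class RawLexiconEntry:
    """One word with raw 1-9 ratings on the three affect dimensions."""

    word: str
    valence_raw: float
    arousal_raw: float
    dominance_raw: float

    def ratings(self) -> tuple[float, float, float]:
        return (self.valence_raw, self.arousal_raw, self.dominance_raw)


@dataclass(frozen=True)
class AffectLexicon:
    """Word -> (V, A, D) z-scores plus the raw moments used for the transform.

    ``standardization`` maps each dimension name to the ``(mean_raw, sd_raw)``
    pair applied, so the provenance of every z-score is auditable.
    """

    entries: Mapping[str, tuple[float, float, float]]
    standardization: Mapping[str, tuple[float, float]]
    ddof: int = field(default=1)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __getitem__(self, word: str) -> tuple[float, float, float]:
        return self.entries[word]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def words(self) -> list[str]:
        return list(self.entries)

    def vectors(self) -> np.ndarray:
        """(n, 3) array of z-scores in V, A, D order, in insertion order."""
        return np.asarray(list(self.entries.values()), dtype=float)


def load_lexicon(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> list[RawLexiconEntry]:
    """Read a delimited (TSV or CSV, auto-detected) word-rating table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    columns
        Optional mapping from the logical names ``word``/``valence``/``arousal``/
        ``dominance`` to the actual column headers in the file (the published
        norms ship with nonstandard headers).

    Raises
    ------
    LexiconFormatError
        Missing columns or an empty/unparseable file.
    LexiconValidationError
        Duplicate words, non-alphabetic words, or ratings outside [1, 9].
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    import csv

    try:
        table = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise LexiconFormatError(f"unparseable or empty lexicon file: {path}") from exc
    missing = [v for v in colmap.values() if v not in table.columns]
    if missing:
        raise LexiconFormatError(
            f"lexicon file {path} is missing required columns: {missing}"
        )
    if len(table) == 0:
        raise LexiconFormatError(f"lexicon file {path} has a header but no rows")

    entries: list[RawLexiconEntry] = []
    seen: set[str] = set()
    for _, row in table.iterrows():
        word = str(row[colmap["word"]]).strip().lower()
        if not word or not word.isalpha():
            raise LexiconValidationError(
                f"lexicon word {word!r} is not a nonempty purely-alphabetic token"
            )
        if word in seen:
            raise LexiconValidationError(f"duplicate lexicon word: {word!r}")
        seen.add(word)
        ratings = []
        for dim in DIMENSIONS:
            val = float(row[colmap[dim]])
            if not (1.0 <= val <= 9.0) or not np.isfinite(val):
                raise LexiconValidationError(
                    f"{dim} rating {val} for word {word!r} outside [1, 9]"
                )
            ratings.append(val)
        entries.append(RawLexiconEntry(word, *ratings))
    return entries


def standardize(entries: Sequence[RawLexiconEntry], ddof: int = 1) -> AffectLexicon:
    """z-transform raw ratings over the supplied entries, per dimension.

    ``ddof=1`` (sample SD) is the package-wide convention for every SD; it is
    a parameter so the convention can be flipped in sensitivity checks.
    """
    if len(entries) < 2:
        raise DegenerateLexiconError("standardization needs at least 2 entries")
    raw = np.array([e.ratings() for e in entries], dtype=float)
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=ddof)
    for dim, sd in zip(DIMENSIONS, sds):
        if sd <= 0.0:
            raise DegenerateLexiconError(f"constant {dim} ratings: sd_raw = 0")
    z = (raw - means) / sds
    mapping = {e.word: tuple(z[i]) for i, e in enumerate(entries)}
    standardization = {
        dim: (float(m), float(s)) for dim, m, s in zip(DIMENSIONS, means, sds)
    }
    return AffectLexicon(entries=mapping, standardization=standardization, ddof=ddof)


def write_standardized(lexicon: AffectLexicon, path: str | Path) -> None:
    """Write the standardized lexicon as TSV with columns word, V, A, D."""
    frame = pd.DataFrame(
        lexicon.vectors(), columns=["V", "A", "D"], index=pd.Index(lexicon.words, name="word")
    )
    frame.to_csv(path, sep="\t")
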