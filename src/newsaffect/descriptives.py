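"""Pandemic phase windows and per-state temporal descriptives of daily affect.

The collection period (2020-01-23 .. 2020-10-22, 274 days) splits into five
windows over three phases: Pre-pandemic (50 d, up to the national-emergency
declaration), Early Response (26 d, up to the last statewide stay-at-home
order), and Mid-pandemic (198 d) cut into three equal 66-day partitions.
Within each window, a state's daily mean affect series is summarized by its
mean, sample variance, and RMSSD (root mean square of successive differences,
a day-to-day volatility measure); RMSSD uses only calendar-adjacent day pairs
where both days are observed, so data gaps never masquerade as daily change.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .circumplex import UndefinedStatisticError
from .preprocess import DailyPool
from .lexicon import AffectLexicon

__all__ = [
    "PhaseWindow",
    "default_phase_windows",
    "COLLECTION_START",
    "COLLECTION_END",
    "rmssd",
    "phase_stats",
    "percentile_rank",
    "frequent_words",
]

COLLECTION_START = dt.date(2020, 1, 23)
COLLECTION_END = dt.date(2020, 10, 22)


@dataclass(frozen=True)
class PhaseWindow:
    name: str
    start_date: dt.date
    end_date: dt.date  # inclusive

    @property
    def length_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, self.end_date, freq="D")


def default_phase_windows() -> list[PhaseWindow]:
    """The five study windows: 50 + 26 + 3x66 = 274 contiguous days."""
    return [
        PhaseWindow("Pre-pandemic", dt.date(2020, 1, 23), dt.date(2020, 3, 12)),
        PhaseWindow("Early Response", dt.date(2020, 3, 13), dt.date(2020, 4, 7)),
        PhaseWindow("Mid-pandemic 1", dt.date(2020, 4, 8), dt.date(2020, 6, 12)),
        PhaseWindow("Mid-pandemic 2", dt.date(2020, 6, 13), dt.date(2020, 8, 17)),
        PhaseWindow("Mid-pandemic 3", dt.date(2020, 8, 18), dt.date(2020, 10, 22)),
    ]


def rmssd(series: Sequence[float]) -> float:
    """Root mean square of successive differences over adjacent non-missing pairs.

    The input is an ordered daily series that may contain NaN; a pair
    contributes only when both of two consecutive positions are observed.
    """
    x = np.asarray(series, dtype=float)
    diffs = np.diff(x)
    diffs = diffs[np.isfinite(diffs)]
    if diffs.size == 0:
        raise UndefinedStatisticError("RMSSD needs at least one adjacent observed pair")
    return float(np.sqrt(np.mean(diffs**2)))


def phase_stats(
    daily: pd.DataFrame,
    windows: Sequence[PhaseWindow] | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per (state, window, dimension) mean, variance and RMSSD of daily affect.

    ``daily`` is a features frame with at least state, date, mean_V/A/D.
    Each state's series is re-indexed onto the window's calendar before the
    RMSSD so that missing days break adjacency rather than collapsing it.
    """
    if windows is None:
        windows = default_phase_windows()
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    rows = []
    for state, group in daily.groupby("state", sort=True):
        group = group.set_index("date").sort_index()
        for window in windows:
            segment = group.reindex(window.dates())
            for dim in "VAD":
                series = segment[f"mean_{dim}"].to_numpy(dtype=float)
                observed = series[np.isfinite(series)]
                mean = float(observed.mean()) if observed.size else np.nan
                var = float(np.var(observed, ddof=ddof)) if observed.size >= 2 else np.nan
                try:
                    vol = rmssd(series)
                except UndefinedStatisticError:
                    vol = np.nan
                rows.append(
                    {
                        "state": state,
                        "window": window.name,
                        "dimension": dim,
                        "n_days": int(observed.size),
                        "mean": mean,
                        "variance": var,
                        "rmssd": vol,
                    }
                )
    return pd.DataFrame(rows)


def percentile_rank(values: Mapping[str, float]) -> dict[str, float]:
    """Cross-state percentile ranks in [0, 100], midrank ties, NaN-tolerant.

    With n >= 2 the minimum maps to 0 and the maximum to 100; a single state
    (or all-tied values) sits at 50 by convention.
    """
    keys = [k for k, v in values.items() if np.isfinite(v)]
    if not keys:
        raise ValueError("percentile_rank: no non-missing values")
    vals = np.array([values[k] for k in keys], dtype=float)
    if len(keys) == 1:
        return {keys[0]: 50.0}
    ranks = rankdata(vals, method="average")
    pct = (ranks - 1.0) / (len(keys) - 1.0) * 100.0
    if np.all(vals == vals[0]):
        pct = np.full_like(pct, 50.0)
    return dict(zip(keys, pct.tolist()))


def frequent_words(
    pools: Sequence[DailyPool],
    lexicon: AffectLexicon | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """High-frequency mapped words for one state's concatenated pools.

    Selects word types whose total occurrence count is at least 2 sample SDs
    above the mean type count, and returns them with counts and (V, A)
    coordinates for circumplex plotting tables. With uniform counts the SD is
    0 and no word strictly exceeds its own mean + 0, so selection is empty.
    """
    counts: dict[str, int] = {}
    coords: dict[str, tuple[float, float]] = {}
    for pool in pools:
        for tok in pool.tokens:
            counts[tok.word] = counts.get(tok.word, 0) + 1
            coords[tok.word] = (tok.V, tok.A)
    if len(counts) < 2:
        raise ValueError("frequent_words needs >= 2 distinct word types")
    values = np.array(list(counts.values()), dtype=float)
    threshold = values.mean() + 2.0 * values.std(ddof=ddof)
    rows = [
        {"word": w, "count": c, "V": coords[w][0], "A": coords[w][1]}
        for w, c in sorted(counts.items())
        if c >= threshold and c > values.mean()
    ]
    return pd.DataFrame(rows, columns=["word", "count", "V", "A"])
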