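"""Denormalizing search-interest data into estimated absolute counts.

Search-interest platforms report a term's activity normalized to 0-100 within
a query window rather than raw counts. Pairing each mental-health term with a
same-day comparator term whose absolute volume tier is published lets the
normalized series be rescaled to estimated counts:

    MH_AdjTot   = MH_NormTot * COMP_SV / COMP_NormTot
    MH_AdjState = MH_AdjTot * (MH_NormState / MH_NormTot)
                            * (POP_State / POP_Tot),   floored to an integer

where COMP_SV is the lowest value of the comparator's published tier (a tier
"50,000+" contributes 50,000). Days whose comparator shows zero normalized
activity are unusable (the rescale is undefined) and are dropped.

The 17 tracked terms group into four outcome clusters (All, Depression,
Anxiety, Nonspecific) whose per-day state-level sums are the modeled counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UnusableComparatorError",
    "InconsistentRecordError",
    "TIER_FLOORS",
    "tier_floor",
    "CLUSTERS",
    "adjust_total",
    "apportion_state",
    "estimate_counts",
    "cluster_sums",
    "load_populations",
]

log = logging.getLogger(__name__)


class UnusableComparatorError(ValueError):
    """Comparator normalized total is zero: the day cannot be rescaled."""


class InconsistentRecordError(ValueError):
    """State-level and national normalized values contradict each other."""


#: published absolute-volume tier floors for trending comparator terms
TIER_FLOORS: tuple[int, ...] = (
    20_000, 50_000, 100_000, 200_000, 500_000, 1_000_000, 2_000_000, 5_000_000,
)

#: search-term clusters; Depression/Anxiety/Nonspecific partition the 17 terms
CLUSTERS: dict[str, frozenset[str]] = {
    "Depression": frozenset(
        {"apathy", "depression", "hopeless", "suicidal", "suicide", "tired", "worthless"}
    ),
    "Anxiety": frozenset(
        {"afraid", "anxiety", "avoiding", "restless", "tense", "worried"}
    ),
    "Nonspecific": frozenset({"angry", "insomnia", "irritable", "scattered"}),
}
CLUSTERS["All"] = CLUSTERS["Depression"] | CLUSTERS["Anxiety"] | CLUSTERS["Nonspecific"]


def tier_floor(volume: float) -> int:
    """Lowest value of the published tier containing ``volume``."""
    eligible = [t for t in TIER_FLOORS if t <= volume]
    if not eligible:
        raise ValueError(f"volume {volume} below the smallest published tier")
    return max(eligible)


def adjust_total(
    mh_norm_total: float, comp_search_volume: float, comp_norm_total: float
) -> float:
    """National adjusted count for a term-day (summative across states)."""
    if comp_norm_total <= 0:
        raise UnusableComparatorError(
            "comparator normalized total is zero; day cannot be denormalized"
        )
    return mh_norm_total * comp_search_volume / comp_norm_total


def apportion_state(
    mh_adj_tot: float,
    mh_norm_state: float,
    mh_norm_total: float,
    pop_state: float,
    pop_tot: float,
) -> int:
    """State share of the national adjusted count, floored to an integer."""
    if pop_tot <= 0:
        raise ValueError("total population must be positive")
    if mh_norm_total <= 0:
        if mh_norm_state > 0:
            raise InconsistentRecordError(
                "state normalized value nonzero while national total is zero"
            )
        return 0
    value = mh_adj_tot * (mh_norm_state / mh_norm_total) * (pop_state / pop_tot)
    return int(math.floor(value + 1e-9 * max(1.0, value)))


def load_populations(path: str | Path) -> pd.DataFrame:
    """Read a (state, population) CSV; states unique, populations positive."""
    pops = pd.read_csv(path, dtype={"state": str})
    if pops["state"].duplicated().any():
        raise ValueError("duplicate states in population table")
    if (pops["population"] <= 0).any():
        raise ValueError("populations must be positive")
    return pops


def _long_form(trends: pd.DataFrame) -> pd.DataFrame:
    """Accept long format directly, or pivot a wide per-state layout to long.

    Long format: date, term, state, mh_norm_state, mh_norm_total,
    comp_norm_total, comp_search_volume. Wide format replaces the
    state/mh_norm_state pair with one ``state_<code>`` column per state.
    """
    if "mh_norm_state" in trends.columns:
        return trends
    state_cols = [c for c in trends.columns if c.startswith("state_")]
    if not state_cols:
        raise ValueError("trends table is neither long nor wide per-state format")
    melted = trends.melt(
        id_vars=[c for c in trends.columns if c not in state_cols],
        value_vars=state_cols,
        var_name="state",
        value_name="mh_norm_state",
    )
    melted["state"] = melted["state"].str.removeprefix("state_")
    return melted


def estimate_counts(trends: pd.DataFrame, populations: pd.DataFrame) -> pd.DataFrame:
    """Estimated absolute counts per (state, date, term) via the two-step rescale.

    Term-days with a zero comparator normalized total are dropped (and
    counted in the log); all other rows yield floored integer counts.
    """
    trends = _long_form(trends).copy()
    pop = dict(zip(populations["state"], populations["population"].astype(float)))
    pop_tot = float(sum(pop.values()))

    usable = trends["comp_norm_total"] > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.warning("dropping %d term-day rows with unusable comparator", n_dropped)
    trends = trends[usable]

    adj_tot = (
        trends["mh_norm_total"]
        * trends["comp_search_volume"]
        / trends["comp_norm_total"]
    )
    norm_tot = trends["mh_norm_total"].to_numpy(dtype=float)
    norm_state = trends["mh_norm_state"].to_numpy(dtype=float)
    if np.any((norm_tot <= 0) & (norm_state > 0)):
        raise InconsistentRecordError(
            "state normalized value nonzero while national total is zero"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(norm_tot > 0, norm_state / np.where(norm_tot > 0, norm_tot, 1.0), 0.0)
    pop_share = trends["state"].map(pop).to_numpy(dtype=float) / pop_tot
    values = adj_tot.to_numpy(dtype=float) * share * pop_share
    # floor with a relative epsilon: values integral up to float rounding
    # must not be pushed down a whole count
    counts = np.floor(values + 1e-9 * np.maximum(1.0, values)).astype(int)

    out = trends[["state", "date", "term"]].copy()
    out["count"] = counts
    return out.sort_values(["state", "date", "term"]).reset_index(drop=True)


def cluster_sums(
    counts: pd.DataFrame,
    clusters: Mapping[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Per (state, date, cluster) sums of term counts.

    A (state, date) missing some — but not all — of a cluster's terms signals
    upstream corruption and raises; wholly absent days are simply absent.
    """
    if clusters is None:
        clusters = CLUSTERS
    frames = []
    for name, terms in clusters.items():
        subset = counts[counts["term"].isin(terms)]
        grouped = subset.groupby(["state", "date"], sort=True).agg(
            count=("count", "sum"), n_terms=("term", "nunique")
        )
        partial = grouped[grouped["n_terms"] != len(terms)]
        if not partial.empty:
            key = partial.index[0]
            raise ValueError(
                f"cluster {name!r}: partial term coverage on (state, date) {key}"
            )
        grouped = grouped.reset_index()[["state", "date", "count"]]
        grouped.insert(2, "cluster", name)
        frames.append(grouped)
    return pd.concat(frames, ignore_index=True).sort_values(
        ["state", "date", "cluster"]
    ).reset_index(drop=True)
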