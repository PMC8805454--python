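#!/usr/bin/env python
"""Phase-window descriptives of daily affect.

Splits the collection period into the five study windows (50 + 26 + 3x66
days), computes per-state mean/variance/RMSSD of daily affect in each
window, ranks states by RMSSD percentile, and extracts each state's
high-frequency words with their circumplex coordinates.
"""

import argparse
from pathlib import Path

import pandas as pd

from newsaffect.descriptives import frequent_words, percentile_rank, phase_stats
from newsaffect.lexicon import load_lexicon, standardize
from newsaffect.preprocess import load_headlines, pool_daily


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    daily = pd.read_csv(args.outdir / "features.csv", parse_dates=["date"])
    stats = phase_stats(daily)
    stats.to_csv(args.outdir / "phase_stats.csv", index=False)

    pct_rows = []
    for (window, dim), grp in stats.groupby(["window", "dimension"]):
        ranks = percentile_rank(dict(zip(grp["state"], grp["rmssd"])))
        pct_rows += [{"window": window, "dimension": dim, "state": s, "percentile": p}
                     for s, p in ranks.items()]
    pd.DataFrame(pct_rows).to_csv(args.outdir / "rmssd_percentiles.csv", index=False)

    by_phase = stats[stats["dimension"] == "V"].groupby("window")["rmssd"].mean()
    print("mean valence RMSSD by window (volatility course of daily affect):")
    print(by_phase.round(3).to_string())

    inputs = args.outdir / "inputs"
    lexicon = standardize(load_lexicon(inputs / "lexicon.csv"))
    pools = pool_daily(load_headlines(inputs / "headlines.csv"), lexicon)
    by_state: dict[str, list] = {}
    for p in pools:
        by_state.setdefault(p.state, []).append(p)
    tables = []
    for state, state_pools in sorted(by_state.items()):
        table = frequent_words(state_pools)
        table.insert(0, "state", state)
        tables.append(table)
    freq = pd.concat(tables, ignore_index=True)
    freq.to_csv(args.outdir / "frequent_words.csv", index=False)
    print(f"{len(freq)} high-frequency words across {len(by_state)} states")


if __name__ == "__main__":
    main()
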