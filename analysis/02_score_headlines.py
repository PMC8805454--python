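#!/usr/bin/env python
"""Standardize the lexicon and map headline words to it.

Reports the corpus mapping diagnostic (share of cleaned non-stop-word
tokens that the lexicon can score — in the original study only about a
third of tokens mapped) and writes the standardized lexicon plus the daily
token pools in long form.
"""

import argparse
from pathlib import Path

import pandas as pd

from newsaffect.lexicon import load_lexicon, standardize, write_standardized
from newsaffect.preprocess import load_headlines, mapping_rate, pool_daily


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    inputs = args.outdir / "inputs"
    entries = load_lexicon(inputs / "lexicon.csv")
    lexicon = standardize(entries)
    write_standardized(lexicon, args.outdir / "lexicon_standardized.tsv")

    headlines = load_headlines(inputs / "headlines.csv")
    pools = pool_daily(headlines, lexicon)
    rate = mapping_rate(pools)
    n_raw = sum(p.n_raw_tokens for p in pools)
    n_mapped = sum(p.n_mapped for p in pools)
    print(f"{len(headlines)} headlines over {len(pools)} state-days")
    print(f"{n_mapped}/{n_raw} tokens mapped to the lexicon ({100 * rate:.2f}%)")

    rows = [
        {"state": p.state, "date": p.date, "word": t.word,
         "V": t.V, "A": t.A, "D": t.D}
        for p in pools for t in p.tokens
    ]
    pd.DataFrame(rows).to_csv(args.outdir / "daily_tokens.csv", index=False)
    print(f"wrote {len(rows)} scored tokens to daily_tokens.csv")


if __name__ == "__main__":
    main()
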