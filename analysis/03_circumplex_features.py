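#!/usr/bin/env python
"""Compute daily circumplex dynamics per state.

From each state-day's pooled word cloud: mean V/A/D, flux along each
dimension, and pulse/spin in the VA, VD and AD planes. Days with fewer
than two mapped words carry missing dynamics (an SD needs n >= 2).
"""

import argparse
from pathlib import Path

from newsaffect.circumplex import features_frame
from newsaffect.lexicon import load_lexicon, standardize
from newsaffect.preprocess import load_headlines, pool_daily


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--angle-mode", choices=["literal", "signed"],
                        default="literal")
    args = parser.parse_args()

    inputs = args.outdir / "inputs"
    lexicon = standardize(load_lexicon(inputs / "lexicon.csv"))
    pools = pool_daily(load_headlines(inputs / "headlines.csv"), lexicon)
    features = features_frame(pools, angle_mode=args.angle_mode)
    features.to_csv(args.outdir / "features.csv", index=False)

    complete = features.dropna()
    print(f"{len(features)} state-days, {len(complete)} with full dynamics")
    print("feature medians:")
    print(
        complete[["mean_V", "mean_A", "Flux_V", "Flux_A",
                  "Pulse_VA", "Spin_VA"]].median().round(3).to_string()
    )


if __name__ == "__main__":
    main()
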