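"""Synthetic-data generator: moments, determinism, regime control, round trips."""

import datetime as dt
import json

import numpy as np
import pandas as pd
import pytest

from newsaffect import simulate
from newsaffect.circumplex import features_frame
from newsaffect.lexicon import standardize
from newsaffect.preprocess import pool_daily
from newsaffect.simulate import (
    DayRegime,
    GeneratorConfig,
    generate_all,
    generate_headlines,
    generate_lexicon,
    generate_populations,
    generate_trends,
    simulate_features,
)
from newsaffect.trends import cluster_sums, estimate_counts


SHORT = dict(
    n_states=3,
    start_date=dt.date(2020, 3, 24),
    end_date=dt.date(2020, 4, 22),
)


class TestLexiconGeneration:
    def test_moments_match_published_scale_at_large_n(self):
        cfg = GeneratorConfig(seed=1, lexicon_size=1000)
        entries = generate_lexicon(cfg)
        raw = np.array([e.ratings() for e in entries])
        assert raw.mean(axis=0) == pytest.approx([5.064, 4.211, 5.185], abs=0.1)
        assert raw.min() >= 1.0 and raw.max() <= 9.0
        assert len({e.word for e in entries}) == 1000

    def test_same_seed_identical(self):
        cfg = GeneratorConfig(seed=7, lexicon_size=50)
        assert generate_lexicon(cfg) == generate_lexicon(cfg)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(
                seed=0, lexicon_moments={"valence": (5.0, 0.0),
                                         "arousal": (4.2, 1.0),
                                         "dominance": (5.2, 0.9)}
            )

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            generate_lexicon(GeneratorConfig(seed=0, lexicon_size=5))


class TestHeadlineGeneration:
    def _realized(self, cfg, regime_fn=None):
        streams = cfg.substreams()
        entries = generate_lexicon(cfg, streams["lexicon"])
        heads = generate_headlines(cfg, entries, regime_fn, streams["headlines"])
        pools = pool_daily(heads, standardize(entries))
        return heads, features_frame(pools)

    def test_same_seed_identical_corpus(self):
        cfg = GeneratorConfig(seed=11, lexicon_size=300, n_states=2,
                              start_date=dt.date(2020, 4, 1),
                              end_date=dt.date(2020, 4, 5))
        h1, _ = self._realized(cfg)
        h2, _ = self._realized(cfg)
        assert h1 == h2

    def test_zero_angular_spread_realizes_near_zero_spin(self):
        cfg = GeneratorConfig(seed=13, lexicon_size=800, n_states=1,
                              start_date=dt.date(2020, 4, 1),
                              end_date=dt.date(2020, 4, 10))
        regime = DayRegime(
            mean=(0.5, 0.5, 0.0), spread=(0.5, 0.5, 0.5),
            angular_spread=0.0, angular_center=40.0,
        )
        _, feats = self._realized(cfg, lambda s, d: regime)
        assert (feats["Spin_VA"].dropna() < 10.0).all()

    def test_wide_regime_has_higher_flux_than_tight_regime_every_day(self):
        base = dict(lexicon_size=800, n_states=1,
                    start_date=dt.date(2020, 4, 1), end_date=dt.date(2020, 4, 10))
        wide = GeneratorConfig(seed=17, within_day_spread=1.3, **base)
        tight = GeneratorConfig(seed=17, within_day_spread=0.4, **base)
        _, f_wide = self._realized(wide)
        _, f_tight = self._realized(tight)
        assert (f_wide["Flux_V"].to_numpy() > f_tight["Flux_V"].to_numpy()).all()
        assert (f_wide["Flux_A"].to_numpy() > f_tight["Flux_A"].to_numpy()).all()

    def test_mapping_rate_below_one(self):
        cfg = GeneratorConfig(seed=19, lexicon_size=400, n_states=1,
                              start_date=dt.date(2020, 4, 1),
                              end_date=dt.date(2020, 4, 7))
        streams = cfg.substreams()
        entries = generate_lexicon(cfg, streams["lexicon"])
        heads = generate_headlines(cfg, entries, rng=streams["headlines"])
        pools = pool_daily(heads, standardize(entries))
        from newsaffect.preprocess import mapping_rate

        assert 0.15 < mapping_rate(pools) < 0.6


class TestTrendsGeneration:
    def test_near_poisson_when_theta_huge(self):
        cfg = GeneratorConfig(seed=23, theta=1e8, sigma_b=0.0, n_states=5,
                              start_date=dt.date(2020, 3, 24),
                              end_date=dt.date(2020, 9, 30),
                              true_beta={t: 0.0 for t in simulate.DEFAULT_TRUE_BETA},
                              cluster_intercepts={"Depression": np.log(10.0),
                                                  "Anxiety": np.log(10.0),
                                                  "Nonspecific": np.log(10.0)})
        feats = simulate_features(cfg)
        _, truth = generate_trends(cfg, feats)
        dep = truth.cluster_counts.query("cluster == 'Depression'")["count"]
        n = len(dep)
        assert n > 500
        # mean 10, Poisson SE sqrt(10/n)
        assert dep.mean() == pytest.approx(10.0, abs=3 * np.sqrt(10.0 / n))
        assert dep.var() == pytest.approx(10.0, rel=0.15)

    def test_term_split_conserves_cluster_sums(self):
        cfg = GeneratorConfig(seed=29, **SHORT)
        feats = simulate_features(cfg)
        _, truth = generate_trends(cfg, feats)
        resummed = cluster_sums(truth.term_counts)
        merged = resummed.merge(
            truth.cluster_counts, on=["state", "date", "cluster"], suffixes=("_r", "_t")
        )
        assert (merged["count_r"] == merged["count_t"]).all()

    def test_lossless_round_trip_recovers_true_counts(self):
        cfg = GeneratorConfig(seed=31, normalization="lossless", **SHORT)
        feats = simulate_features(cfg)
        trends, truth = generate_trends(cfg, feats)
        pops = generate_populations(cfg)
        est = estimate_counts(trends, pops)
        merged = est.merge(
            truth.term_counts, on=["state", "date", "term"], suffixes=("_est", "_true")
        )
        assert len(merged) == len(truth.term_counts)
        diff = merged["count_est"] - merged["count_true"]
        # flooring can only lose up to one count on float representation error
        assert diff.abs().max() <= 1
        assert (diff <= 0).all()

    def test_platform_mode_distorts_but_preserves_signal(self):
        """Integer 0-100 rounding and tier-floored comparator volumes lose
        information: the estimates track the truth but are no longer exact."""
        cfg = GeneratorConfig(seed=37, normalization="platform", **SHORT)
        feats = simulate_features(cfg)
        trends, truth = generate_trends(cfg, feats)
        est = estimate_counts(trends, generate_populations(cfg))
        merged = est.merge(
            truth.term_counts, on=["state", "date", "term"], suffixes=("_est", "_true")
        )
        corr = np.corrcoef(merged["count_est"], merged["count_true"])[0, 1]
        assert corr > 0.4
        assert (merged["count_est"] != merged["count_true"]).any()

    def test_same_seed_identical_records(self):
        cfg = GeneratorConfig(seed=41, **SHORT)
        feats = simulate_features(cfg)
        t1, _ = generate_trends(cfg, feats)
        t2, _ = generate_trends(cfg, feats)
        pd.testing.assert_frame_equal(t1, t2)


class TestGenerateAll:
    def test_outputs_validate_against_consuming_readers(self, tmp_path):
        from newsaffect.lexicon import load_lexicon
        from newsaffect.preprocess import load_headlines
        from newsaffect.trends import load_populations

        cfg = GeneratorConfig(seed=43, lexicon_size=300, n_states=2,
                              start_date=dt.date(2020, 3, 24),
                              end_date=dt.date(2020, 4, 7))
        manifest = generate_all(cfg, tmp_path)
        entries = load_lexicon(tmp_path / "lexicon.csv")
        assert len(entries) == 300
        heads = load_headlines(tmp_path / "headlines.csv")
        assert heads and heads[0].state == "AA"
        pops = load_populations(tmp_path / "populations.csv")
        assert len(pops) == 2
        trends = pd.read_csv(tmp_path / "trends.csv", parse_dates=["date"])
        est = estimate_counts(trends, pops)
        assert (est["count"] >= 0).all()
        assert set(manifest["outputs"]) == {
            "lexicon", "headlines", "populations", "trends", "ground_truth"
        }
        truth_params = json.loads(
            (tmp_path / "ground_truth_params.json").read_text()
        )
        assert truth_params["theta"] == cfg.theta
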