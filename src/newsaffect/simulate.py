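"""Synthetic inputs with known ground truth for every pipeline stage.

No raw inputs of the original study (scraped headlines, live search-interest
records) are redistributable, so this module generates statistically
analogous stand-ins:

* a lexicon whose raw 1-9 rating moments match the published crowdsourced
  norms (valence 5.064/1.275, arousal 4.211/0.986, dominance 5.185/0.938);
* per-state, per-day headline corpora whose mapped-word clouds realize
  controllable affect regimes (daily mean, within-day spread, optional
  angular spread), with out-of-vocabulary filler and stop words mixed in so
  mapping rates resemble real corpora (~35%);
* daily state-level search counts drawn from a known negative binomial
  mixed model on the realized circumplex features, then re-normalized into
  0-100 search-interest records with a daily comparator term — so the whole
  denormalize -> model chain can be validated against ground truth.

A single seed drives independent per-module substreams; identical configs
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._stopwords import ENGLISH_STOPWORDS
from .circumplex import features_frame
from .descriptives import COLLECTION_END, COLLECTION_START, default_phase_windows
from .glmm import MODEL_ORIGIN, MODEL_END, VA_TERMS, VAD_TERMS, _TERM_TO_COLUMN
from .lexicon import RawLexiconEntry, standardize
from .preprocess import HeadlineRecord
from .trends import CLUSTERS, tier_floor

__all__ = [
    "GeneratorConfig",
    "DayRegime",
    "GroundTruth",
    "InfeasibleRegimeError",
    "generate_lexicon",
    "generate_populations",
    "generate_headlines",
    "simulate_features",
    "generate_trends",
    "generate_all",
]

#: raw-scale (mean, sd) per dimension matching the published norms
DEFAULT_LEXICON_MOMENTS: dict[str, tuple[float, float]] = {
    "valence": (5.064, 1.275),
    "arousal": (4.211, 0.986),
    "dominance": (5.185, 0.938),
}

#: ground-truth fixed-effect slopes of the count model (VA set, per feature
#: unit: z-scores for means/flux/pulse, degrees for spin, days for t)
DEFAULT_TRUE_BETA: dict[str, float] = {
    "t": -0.004,
    "V": -0.06,
    "A": -0.01,
    "Spin_VA": -0.008,
    "Pulse_VA": 0.13,
    "Flux_V": 0.02,
    "Flux_A": 0.22,
}

#: per-cluster baseline intercepts (log expected daily state counts at
#: feature values 0, chosen so realized counts sit in the hundreds)
DEFAULT_CLUSTER_INTERCEPTS: dict[str, float] = {
    "Depression": 6.1,
    "Anxiety": 5.9,
    "Nonspecific": 4.9,
}


class InfeasibleRegimeError(RuntimeError):
    """A day's affect-regime targets could not be realized from the lexicon."""


@dataclass(frozen=True)
class DayRegime:
    """Targets for one day's mapped word cloud.

    ``mean`` and ``spread`` are per-dimension (V, A, D) in z units. When
    ``angular_spread`` (degrees) is set, the valence-arousal components are
    instead drawn as magnitude/angle pairs around ``angular_center`` so that
    spin and pulse are directly controllable.
    """

    mean: tuple[float, float, float]
    spread: tuple[float, float, float]
    angular_spread: float | None = None
    angular_center: float = 45.0
    magnitude_mean: float = 1.2
    magnitude_spread: float = 0.4


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_states: int = 50
    start_date: dt.date = COLLECTION_START
    end_date: dt.date = COLLECTION_END
    lexicon_size: int = 2000
    lexicon_moments: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LEXICON_MOMENTS)
    )
    headlines_per_day: float = 12.0
    tokens_per_headline: tuple[int, int] = (4, 9)
    oov_rate: float = 0.63  # fraction of content tokens left unmapped
    within_day_spread: float = 0.9  # targets flux, z units
    regime_tolerance: float = 0.10
    feature_set: str = "VA"
    true_beta: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_BETA)
    )
    cluster_intercepts: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_INTERCEPTS)
    )
    sigma_b: float = 0.35
    theta: float = 8.0
    normalization: str = "lossless"  # or "platform"
    comparator_volume_range: tuple[int, int] = (60_000, 4_000_000)

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("dispersion theta must be positive")
        if self.end_date < self.start_date:
            raise ValueError("date range is empty")
        for dim, (_, sd) in self.lexicon_moments.items():
            if sd <= 0:
                raise ValueError(f"degenerate lexicon: zero {dim} spread")

    def substreams(self) -> dict[str, np.random.Generator]:
        names = ("lexicon", "headlines", "trends", "populations", "features")
        seqs = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


@dataclass
class GroundTruth:
    """Generating parameters and latent quantities persisted for recovery tests."""

    beta: dict[str, float]
    cluster_intercepts: dict[str, float]
    sigma_b: float
    theta: float
    random_modes: dict[str, float]
    cluster_counts: pd.DataFrame  # state, date, cluster, count
    term_counts: pd.DataFrame  # state, date, term, count

    def save(self, outdir: Path) -> list[Path]:
        outdir = Path(outdir)
        params = {
            "beta": self.beta,
            "cluster_intercepts": self.cluster_intercepts,
            "sigma_b": self.sigma_b,
            "theta": self.theta,
            "random_modes": self.random_modes,
        }
        paths = [
            outdir / "ground_truth_params.json",
            outdir / "ground_truth_cluster_counts.csv",
            outdir / "ground_truth_term_counts.csv",
        ]
        paths[0].write_text(json.dumps(params, indent=2, sort_keys=True))
        self.cluster_counts.to_csv(paths[1], index=False)
        self.term_counts.to_csv(paths[2], index=False)
        return paths


def _random_words(
    rng: np.random.Generator,
    n: int,
    exclude: set[str],
    lengths: tuple[int, int] = (4, 8),
) -> list[str]:
    letters = np.array(list(string.ascii_lowercase))
    words: list[str] = []
    seen = set(exclude)
    while len(words) < n:
        length = int(rng.integers(lengths[0], lengths[1] + 1))
        word = "".join(rng.choice(letters, size=length))
        if word not in seen:
            seen.add(word)
            words.append(word)
    return words


def generate_lexicon(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[RawLexiconEntry]:
    """Random lexicon with the configured raw-scale moments, clipped to [1, 9]."""
    if config.lexicon_size < 10:
        raise ValueError("lexicon_size must be >= 10")
    if rng is None:
        rng = config.substreams()["lexicon"]
    words = _random_words(rng, config.lexicon_size, set(ENGLISH_STOPWORDS))
    ratings = {}
    for dim in ("valence", "arousal", "dominance"):
        mean, sd = config.lexicon_moments[dim]
        ratings[dim] = np.clip(
            rng.normal(mean, sd, size=config.lexicon_size), 1.0, 9.0
        )
    return [
        RawLexiconEntry(
            word=w,
            valence_raw=float(ratings["valence"][i]),
            arousal_raw=float(ratings["arousal"][i]),
            dominance_raw=float(ratings["dominance"][i]),
        )
        for i, w in enumerate(words)
    ]


def generate_populations(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """State population table: lognormal sizes, US-like total magnitude."""
    if rng is None:
        rng = config.substreams()["populations"]
    raw = rng.lognormal(mean=15.0, sigma=0.85, size=config.n_states)
    pops = np.maximum(100_000, raw.astype(int))
    return pd.DataFrame({"state": _state_codes(config.n_states), "population": pops})


def _state_codes(n: int) -> list[str]:
    alphabet = string.ascii_uppercase
    codes = [a + b for a in alphabet for b in alphabet]
    return codes[:n]


def _default_regime_fn(
    config: GeneratorConfig, rng: np.random.Generator
) -> Callable[[str, dt.date], DayRegime]:
    """Per-state affect trajectories emulating the study's descriptive shape.

    Means hover in 0..0.5; day-to-day volatility of the daily mean is high in
    the pre-pandemic window, drops sharply in the early-response window, and
    ramps back up across the three mid-pandemic partitions (the RMSSD
    'rubber-banding' pattern).
    """
    windows = default_phase_windows()
    day_sd = {w.name: s for w, s in zip(windows, (0.35, 0.10, 0.15, 0.20, 0.25))}
    states = _state_codes(config.n_states)
    base = {s: rng.normal(0.25, 0.10, size=3) for s in states}
    offsets: dict[tuple[str, dt.date], np.ndarray] = {}

    spreads: dict[tuple[str, dt.date], np.ndarray] = {}

    def regime(state: str, date: dt.date) -> DayRegime:
        key = (state, date)
        if key not in offsets:
            sd = next(
                (day_sd[w.name] for w in windows if w.start_date <= date <= w.end_date),
                0.2,
            )
            offsets[key] = rng.normal(0.0, sd, size=3)
            # within-day spread (the flux target) varies day to day and
            # independently per dimension, so the flux features decorrelate
            spreads[key] = np.clip(rng.normal(1.0, 0.15, size=3), 0.5, 1.5)
        mu = base[state] + offsets[key]
        return DayRegime(
            mean=tuple(mu), spread=tuple(config.within_day_spread * spreads[key])
        )

    return regime


def _draw_day_vectors(
    regime: DayRegime, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Latent (n, 3) affect vectors realizing the day's regime targets.

    Independent-normal draws are affinely re-moored to the exact target mean
    and spread (dictionary snapping then perturbs them slightly); angular
    regimes draw magnitude/angle pairs in the VA plane instead.
    """
    if regime.angular_spread is None:
        x = rng.normal(size=(n, 3))
        if n >= 2:
            x = (x - x.mean(axis=0)) / np.maximum(x.std(axis=0, ddof=1), 1e-12)
        out = x * np.asarray(regime.spread) + np.asarray(regime.mean)
        return out
    angles = np.radians(
        regime.angular_center + rng.normal(0.0, regime.angular_spread, size=n)
    )
    mags = np.abs(rng.normal(regime.magnitude_mean, regime.magnitude_spread, size=n))
    out = np.empty((n, 3))
    out[:, 0] = mags * np.cos(angles)
    out[:, 1] = mags * np.sin(angles)
    out[:, 2] = rng.normal(regime.mean[2], regime.spread[2], size=n)
    return out


def _regime_deviation(words_z: np.ndarray, regime: DayRegime, tol: float) -> float:
    """Worst deviation of realized day features from targets, in tolerance units.

    <= 1 means every checked feature sits within its allowed band; values
    much above 1 indicate the lexicon cannot express the regime.
    """
    if len(words_z) < 2:
        return 0.0
    if regime.angular_spread is not None:
        va = words_z[:, :2]
        nonzero = va[(va[:, 0] != 0) | (va[:, 1] != 0)]
        if len(nonzero) < 2:
            return math.inf
        ang = np.degrees(
            np.arccos(
                np.clip(np.abs(nonzero[:, 0]) / np.hypot(nonzero[:, 0], nonzero[:, 1]), 0, 1)
            )
        )
        realized = float(np.std(ang, ddof=1))
        band = max(5.0, tol * regime.angular_spread)
        return abs(realized - regime.angular_spread) / band
    spread = np.asarray(regime.spread)
    mean_dev = np.abs(words_z.mean(axis=0) - np.asarray(regime.mean)) / np.maximum(
        0.06, tol * spread
    )
    flux_dev = np.abs(words_z.std(axis=0, ddof=1) - spread) / (tol * spread + 0.05)
    return float(max(mean_dev.max(), flux_dev.max()))


def generate_headlines(
    config: GeneratorConfig,
    lexicon_entries: Sequence[RawLexiconEntry],
    regime_fn: Callable[[str, dt.date], DayRegime] | None = None,
    rng: np.random.Generator | None = None,
) -> list[HeadlineRecord]:
    """Compose per-state, per-day headline corpora realizing affect regimes.

    Mapped words are chosen by snapping latent regime draws to their nearest
    lexicon entries in z space (rejection-resampled until the realized day
    features sit within the configured tolerance of the targets); filler
    words outside the lexicon and stop words are mixed in so preprocessing
    and mapping behave as on real text.
    """
    if rng is None:
        rng = config.substreams()["headlines"]
    lexicon = standardize(lexicon_entries)
    words = np.array(lexicon.words)
    lex_z = lexicon.vectors()
    tree = cKDTree(lex_z)
    if regime_fn is None:
        regime_fn = _default_regime_fn(config, rng)
    fillers = np.array(
        _random_words(rng, 3000, set(ENGLISH_STOPWORDS) | set(words.tolist()),
                      lengths=(5, 9))
    )
    stop_pool = np.array(sorted(ENGLISH_STOPWORDS))
    lo, hi = config.tokens_per_headline
    decorations = ("", "", "", ": live updates", " - 2020", ", officials say")

    records: list[HeadlineRecord] = []
    for state in _state_codes(config.n_states):
        for date in pd.date_range(config.start_date, config.end_date, freq="D"):
            day = date.date()
            regime = regime_fn(state, day)
            n_headlines = 3 + int(rng.poisson(max(config.headlines_per_day - 3, 0.0)))
            lengths = rng.integers(lo, hi + 1, size=n_headlines)
            n_content = int(lengths.sum())
            n_mapped = int(rng.binomial(n_content, 1.0 - config.oov_rate))

            mapped_words: list[str] = []
            if n_mapped > 0:
                best_idx, best_dev = None, math.inf
                for _ in range(30):
                    latent = _draw_day_vectors(regime, n_mapped, rng)
                    _, idx = tree.query(latent)
                    dev = _regime_deviation(lex_z[idx], regime, config.regime_tolerance)
                    if dev < best_dev:
                        best_idx, best_dev = idx, dev
                    if dev <= 1.0:
                        break
                if best_dev > 3.0:
                    raise InfeasibleRegimeError(
                        f"regime for {state} {day} not realizable from lexicon "
                        f"(best deviation {best_dev:.2f} tolerance units)"
                    )
                mapped_words = words[best_idx].tolist()
            content = mapped_words + list(
                rng.choice(fillers, size=n_content - n_mapped)
            )
            rng.shuffle(content)
            n_stop = int(round(0.5 * n_content))
            tokens = content + list(rng.choice(stop_pool, size=n_stop))
            rng.shuffle(tokens)
            bounds = np.linspace(0, len(tokens), n_headlines + 1).astype(int)
            for h in range(n_headlines):
                chunk = tokens[bounds[h]:bounds[h + 1]]
                if not chunk:
                    chunk = [str(fillers[int(rng.integers(len(fillers)))])]
                title = " ".join(chunk).capitalize()
                title += decorations[int(rng.integers(len(decorations)))]
                records.append(HeadlineRecord(state=state, date=day, title=title))
    return records


def simulate_features(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw a daily-features frame directly, bypassing text generation.

    Used when only the count-model stages are under study: scales match what
    the text pipeline realizes (means in z units, flux ~0.9, pulse ~0.5,
    spin ~25 degrees) but no headline corpus is materialized.
    """
    if rng is None:
        rng = config.substreams()["features"]
    states = _state_codes(config.n_states)
    dates = pd.date_range(config.start_date, config.end_date, freq="D")
    n = len(states) * len(dates)
    idx = pd.MultiIndex.from_product([states, dates], names=["state", "date"])
    frame = pd.DataFrame(index=idx).reset_index()
    frame["n_mapped"] = rng.integers(15, 45, size=n)
    for dim in "VAD":
        frame[f"mean_{dim}"] = rng.normal(0.25, 0.18, size=n)
        frame[f"Flux_{dim}"] = np.abs(rng.normal(0.9, 0.15, size=n))
    for plane in ("VA", "VD", "AD"):
        frame[f"Pulse_{plane}"] = np.abs(rng.normal(0.55, 0.12, size=n))
        frame[f"Spin_{plane}"] = np.clip(rng.normal(25.0, 5.0, size=n), 2.0, 80.0)
    return frame


def _design_from_features(
    features: pd.DataFrame, terms: Sequence[str]
) -> tuple[pd.DataFrame, np.ndarray]:
    feats = features.copy()
    feats["date"] = pd.to_datetime(feats["date"])
    feats = feats[
        (feats["date"] >= pd.Timestamp(MODEL_ORIGIN))
        & (feats["date"] <= pd.Timestamp(MODEL_END))
    ].copy()
    feats["t"] = (feats["date"] - pd.Timestamp(MODEL_ORIGIN)).dt.days
    cols = [_TERM_TO_COLUMN[t] for t in terms]
    feats = feats.dropna(subset=cols).sort_values(["state", "date"]).reset_index(drop=True)
    X = feats[cols].to_numpy(dtype=float)
    return feats, X


def generate_trends(
    config: GeneratorConfig,
    features: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw counts from the known NB mixed model and emit normalized records.

    Cluster counts are NB2 draws with log-mean ``X beta + intercept_c + b_s``;
    per-term counts are a multinomial split within each cluster, so cluster
    sums reproduce the generative draw exactly. Normalization is either
    ``lossless`` (comparator tier floor equals its true volume; state shares
    exactly invertible) or ``platform`` (integer-rounded 0-100 values,
    per-capita state scaling, tier-floored comparator volume).
    """
    if rng is None:
        rng = config.substreams()["trends"]
    terms_model = VA_TERMS if config.feature_set == "VA" else VAD_TERMS
    beta = np.array([config.true_beta[t] for t in terms_model])
    feats, X = _design_from_features(features, terms_model)
    eta_fixed = X @ beta

    states = _state_codes(config.n_states)
    b = dict(zip(states, rng.normal(0.0, config.sigma_b, size=len(states))))
    b_row = feats["state"].map(b).to_numpy()

    base_clusters = ["Depression", "Anxiety", "Nonspecific"]
    cluster_rows = []
    term_rows = []
    for cname in base_clusters:
        mu = np.exp(
            np.clip(eta_fixed + config.cluster_intercepts[cname] + b_row, -30, 30)
        )
        counts = rng.negative_binomial(
            n=config.theta, p=config.theta / (config.theta + mu)
        )
        cluster_rows.append(
            pd.DataFrame(
                {
                    "state": feats["state"],
                    "date": feats["date"],
                    "cluster": cname,
                    "count": counts,
                }
            )
        )
        cterms = sorted(CLUSTERS[cname])
        split = rng.multinomial(counts, np.full(len(cterms), 1.0 / len(cterms)))
        for j, term in enumerate(cterms):
            term_rows.append(
                pd.DataFrame(
                    {
                        "state": feats["state"],
                        "date": feats["date"],
                        "term": term,
                        "count": split[:, j],
                    }
                )
            )
    cluster_counts = pd.concat(cluster_rows, ignore_index=True)
    all_cluster = (
        cluster_counts.groupby(["state", "date"], as_index=False)["count"]
        .sum()
        .assign(cluster="All")[["state", "date", "cluster", "count"]]
    )
    cluster_counts = pd.concat([cluster_counts, all_cluster], ignore_index=True)
    term_counts = pd.concat(term_rows, ignore_index=True)

    trends = _normalize_records(config, term_counts, rng)
    truth = GroundTruth(
        beta=dict(zip(terms_model, beta.tolist())),
        cluster_intercepts=dict(config.cluster_intercepts),
        sigma_b=config.sigma_b,
        theta=config.theta,
        random_modes={s: float(v) for s, v in b.items()},
        cluster_counts=cluster_counts.sort_values(
            ["state", "date", "cluster"]
        ).reset_index(drop=True),
        term_counts=term_counts.sort_values(["state", "date", "term"]).reset_index(
            drop=True
        ),
    )
    return trends, truth


def _normalize_records(
    config: GeneratorConfig, term_counts: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Convert true term counts into per-day normalized search-interest rows."""
    pops = generate_populations(config)
    pop_share = dict(
        zip(pops["state"], pops["population"] / pops["population"].sum())
    )
    dates = sorted(term_counts["date"].unique())
    lo, hi = config.comparator_volume_range
    comp_volume = {d: int(rng.integers(lo, hi)) for d in dates}
    comp_name = {d: f"topic{i:04d}" for i, d in enumerate(dates)}

    lossless = config.normalization == "lossless"
    rows = []
    for (date, term), grp in term_counts.groupby(["date", "term"], sort=True):
        c = grp["count"].to_numpy(dtype=float)
        st = grp["state"].to_numpy()
        total = float(c.sum())
        K = float(comp_volume[date])
        basis = max(total, K)
        norm_tot = 100.0 * total / basis
        comp_norm_tot = 100.0 * K / basis
        shares = np.array([pop_share[s] for s in st])
        if lossless:
            with np.errstate(divide="ignore", invalid="ignore"):
                norm_state = np.where(
                    total > 0, norm_tot * c / (total * shares), 0.0
                )
            comp_sv = int(K)
        else:
            percap = np.where(shares > 0, c / shares, 0.0)
            peak = percap.max()
            norm_state = np.round(100.0 * percap / peak) if peak > 0 else percap
            # integer 0-100 reporting; a nonzero total never rounds below 1
            norm_tot = max(1.0, round(norm_tot)) if total > 0 else 0.0
            comp_norm_tot = max(1.0, round(comp_norm_tot))
            comp_sv = tier_floor(K)
        for s, ns in zip(st, norm_state):
            rows.append(
                {
                    "date": date,
                    "term": term,
                    "state": s,
                    "mh_norm_state": float(ns),
                    "mh_norm_total": float(norm_tot),
                    "comparator_term": comp_name[date],
                    "comp_norm_total": float(comp_norm_tot),
                    "comp_search_volume": comp_sv,
                }
            )
    return pd.DataFrame(rows)


def generate_all(config: GeneratorConfig, outdir: str | Path) -> dict:
    """Generate every pipeline input into ``outdir``; returns the manifest.

    Writes lexicon.csv, headlines.csv, populations.csv, trends.csv, the
    ground-truth files, and manifest.json recording the config and outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = config.substreams()

    entries = generate_lexicon(config, streams["lexicon"])
    lex_path = outdir / "lexicon.csv"
    pd.DataFrame(
        {
            "word": [e.word for e in entries],
            "valence": [e.valence_raw for e in entries],
            "arousal": [e.arousal_raw for e in entries],
            "dominance": [e.dominance_raw for e in entries],
        }
    ).to_csv(lex_path, index=False)

    headlines = generate_headlines(config, entries, rng=streams["headlines"])
    head_path = outdir / "headlines.csv"
    pd.DataFrame(
        {
            "state": [h.state for h in headlines],
            "date": [h.date.isoformat() for h in headlines],
            "title": [h.title for h in headlines],
        }
    ).to_csv(head_path, index=False)

    pops = generate_populations(config, streams["populations"])
    pop_path = outdir / "populations.csv"
    pops.to_csv(pop_path, index=False)

    from .preprocess import pool_daily

    lexicon = standardize(entries)
    pools = pool_daily(headlines, lexicon)
    features = features_frame(pools)
    trends, truth = generate_trends(config, features, streams["trends"])
    trends_path = outdir / "trends.csv"
    trends.to_csv(trends_path, index=False)
    truth_paths = truth.save(outdir)

    manifest = {
        "seed": config.seed,
        "config": {
            k: (v.isoformat() if isinstance(v, dt.date) else v)
            for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, dict)
        },
        "regime_tolerance": config.regime_tolerance,
        "outputs": {
            "lexicon": lex_path.name,
            "headlines": head_path.name,
            "populations": pop_path.name,
            "trends": trends_path.name,
            "ground_truth": [p.name for p in truth_paths],
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
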