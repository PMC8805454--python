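"""Circumplex dynamics of a day's pooled word affect: flux, pulse, and spin.

Each mapped word is a point in z-scored affect space. Within a 2D plane of
that space (valence-arousal, valence-dominance, arousal-dominance), the day's
word cloud is summarized by three SD-type statistics:

* **flux** — SD of the scalar scores along one dimension: variability of
  affect intensity, blind to direction;
* **pulse** — SD of word-vector Euclidean magnitudes: variability of
  affective extremity (distance from the neutral origin);
* **spin** — SD of word-vector angular displacements from the horizontal
  axis: variability of affective tone, blind to intensity.

Every SD is the ordinary sample SD (denominator n-1), consistently with the
lexicon standardization; spin uses the linear SD of angles in degrees, not a
circular statistic. Two angle conventions are provided (see ``word_angle``).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, fields
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .preprocess import DailyPool

__all__ = [
    "UndefinedStatisticError",
    "DailyStateAffect",
    "PLANES",
    "flux",
    "vector_magnitude",
    "pulse",
    "word_angle",
    "spin",
    "compute_daily_features",
    "features_frame",
]

AngleMode = Literal["literal", "signed"]

#: 2D planes of the affect space, as (x-dimension, y-dimension) index pairs
#: into (V, A, D) token vectors.
PLANES: dict[str, tuple[int, int]] = {"VA": (0, 1), "VD": (0, 2), "AD": (1, 2)}


class UndefinedStatisticError(ValueError):
    """An SD-type statistic was requested on fewer than 2 usable values."""


@dataclass(frozen=True)
class DailyStateAffect:
    """One (state, date) row of daily means and circumplex dynamics.

    Features are NaN when undefined: means need >= 1 mapped token, the
    dynamics statistics need >= 2 (spin additionally needs >= 2 tokens with a
    nonzero vector in the plane). Spin is in degrees; everything else is in
    lexicon z-score units.
    """

    state: str
    date: dt.date
    n_mapped: int
    mean_V: float
    mean_A: float
    mean_D: float
    Flux_V: float
    Flux_A: float
    Flux_D: float
    Pulse_VA: float
    Pulse_VD: float
    Pulse_AD: float
    Spin_VA: float
    Spin_VD: float
    Spin_AD: float


FEATURE_COLUMNS = [f.name for f in fields(DailyStateAffect)][3:]


def _sample_sd(values: np.ndarray, ddof: int = 1) -> float:
    if values.size < 2:
        raise UndefinedStatisticError(
            f"SD needs >= 2 values, got {values.size}"
        )
    return float(np.std(values, ddof=ddof))


def flux(scores: Sequence[float], ddof: int = 1) -> float:
    """Sample SD of scalar z-scores along one affect dimension."""
    return _sample_sd(np.asarray(scores, dtype=float), ddof)


def vector_magnitude(ax: float, ay: float) -> float:
    """Euclidean distance from the origin to (ax, ay)."""
    return math.hypot(ax, ay)


def pulse(points: Sequence[tuple[float, float]], ddof: int = 1) -> float:
    """Sample SD of word-vector magnitudes in a 2D affect plane."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return _sample_sd(np.hypot(pts[:, 0], pts[:, 1]), ddof)


def word_angle(ax: float, ay: float, mode: AngleMode = "literal") -> float:
    """Angle (degrees) of the word vector (ax, ay) from the horizontal axis.

    ``literal`` folds every quadrant into [0, 90]: it is the angle between
    u = (ax, 0) and v = (ax, ay), i.e. arccos(|ax| / ||v||). ``signed``
    is the geometric displacement |atan2(ay, ax)| in [0, 180], which keeps
    left and right half-planes distinct. ax = 0 with ay != 0 gives 90 in both
    modes (the limit of either formula); the zero vector has no angle.
    """
    if ax == 0.0 and ay == 0.0:
        raise UndefinedStatisticError("zero vector has no angular displacement")
    if mode == "literal":
        return math.degrees(math.acos(min(1.0, abs(ax) / math.hypot(ax, ay))))
    if mode == "signed":
        return abs(math.degrees(math.atan2(ay, ax)))
    raise ValueError(f"unknown angle mode: {mode!r}")


def spin(
    points: Sequence[tuple[float, float]],
    mode: AngleMode = "literal",
    ddof: int = 1,
) -> float:
    """Sample SD (degrees) of word-vector angles; zero vectors are excluded."""
    angles = [
        word_angle(ax, ay, mode)
        for ax, ay in np.asarray(points, dtype=float).reshape(-1, 2)
        if not (ax == 0.0 and ay == 0.0)
    ]
    return _sample_sd(np.asarray(angles), ddof)


def compute_daily_features(
    pool: DailyPool,
    angle_mode: AngleMode = "literal",
    ddof: int = 1,
) -> DailyStateAffect:
    """Daily means plus flux/pulse/spin for one (state, date) token pool.

    Means are token-weighted over the pool. With fewer than 2 mapped tokens
    the dynamics statistics are NaN (an SD of a singleton is undefined under
    the sample-SD convention); with 0 tokens the means are NaN too.
    """
    vecs = np.array([(t.V, t.A, t.D) for t in pool.tokens], dtype=float).reshape(-1, 3)
    n = len(pool.tokens)
    out: dict[str, float] = {}
    for i, dim in enumerate("VAD"):
        out[f"mean_{dim}"] = float(vecs[:, i].mean()) if n >= 1 else math.nan
        out[f"Flux_{dim}"] = flux(vecs[:, i], ddof) if n >= 2 else math.nan
    for plane, (ix, iy) in PLANES.items():
        pts = vecs[:, (ix, iy)]
        out[f"Pulse_{plane}"] = pulse(pts, ddof) if n >= 2 else math.nan
        try:
            out[f"Spin_{plane}"] = spin(pts, angle_mode, ddof) if n >= 2 else math.nan
        except UndefinedStatisticError:
            out[f"Spin_{plane}"] = math.nan
    return DailyStateAffect(state=pool.state, date=pool.date, n_mapped=n, **out)


def features_frame(
    pools: Iterable[DailyPool],
    angle_mode: AngleMode = "literal",
    ddof: int = 1,
) -> pd.DataFrame:
    """DataFrame of daily features, one row per pool (missing as NaN)."""
    rows = [compute_daily_features(p, angle_mode, ddof) for p in pools]
    frame = pd.DataFrame([r.__dict__ for r in rows])
    if not frame.empty:
        frame["date"] = pd.to_datetime(frame["date"])
        frame = frame.sort_values(["state", "date"]).reset_index(drop=True)
    return frame
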