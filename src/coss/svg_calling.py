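"""Binary spatially-variable calls from continuous scores.

The score-vs-rank curve of a scored sample is typically steeply decreasing
then flat; the cutoff rank is placed at the knee of that curve using the
kneedle construction (normalized difference from the chord), implemented
here directly on the discrete curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .scoring import CoSSResult, results_to_frame

logger = logging.getLogger(__name__)

MIN_CURVE_POINTS = 5


@dataclass
class RankCurve:
    ranks: np.ndarray   # 1..n
    scores: np.ndarray  # nonincreasing

    @classmethod
    def from_scores(cls, scores: Sequence[float]) -> "RankCurve":
        s = np.asarray(scores, dtype=float)
        if np.any(np.diff(s) > 0):
            raise UsageError("scores must be sorted in nonincreasing order")
        return cls(ranks=np.arange(1, len(s) + 1), scores=s)


def kneedle_cutoff(
    curve: RankCurve,
    sensitivity: float = 1.0,
    smoothing_window: int = 1,
) -> Optional[int]:
    """Rank of the knee of a decreasing convex-shaped curve, or None.

    Both axes are min-max normalized; the difference between the chord
    (from first to last point) and the curve is scanned for its first local
    maximum that survives the sensitivity threshold
    ``d_max - sensitivity / (n - 1)`` before the difference next rises.
    """
    if sensitivity <= 0:
        raise UsageError("sensitivity must be > 0")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise UsageError("smoothing_window must be a positive odd integer")
    y = curve.scores.astype(float)
    n = len(y)
    if n < MIN_CURVE_POINTS:
        return None
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        pad = smoothing_window // 2
        y = np.convolve(np.pad(y, pad, mode="edge"), kernel, mode="valid")
    rng = y[0] - y[-1]
    if rng <= 0:
        return None
    x_norm = (curve.ranks - curve.ranks[0]) / (curve.ranks[-1] - curve.ranks[0])
    y_norm = (y - y[-1]) / rng
    diff = (1.0 - x_norm) - y_norm  # gap below the chord; >= 0 on convex curves

    threshold_drop = sensitivity * np.mean(np.diff(x_norm))
    maxima = [
        i
        for i in range(1, n - 1)
        if diff[i] >= diff[i - 1] and diff[i] > diff[i + 1] and diff[i] > 0
    ]
    for idx, i in enumerate(maxima):
        t = diff[i] - threshold_drop
        stop = maxima[idx + 1] if idx + 1 < len(maxima) else n
        for j in range(i + 1, stop):
            if diff[j] < t:
                return int(curve.ranks[i])
    return None


def max_curvature_rank(curve: RankCurve) -> Optional[int]:
    """Discrete maximum-curvature search on the normalized curve
    (independent cross-check for the kneedle cutoff)."""
    y = curve.scores.astype(float)
    n = len(y)
    if n < MIN_CURVE_POINTS or y[0] == y[-1]:
        return None
    x = (curve.ranks - curve.ranks[0]) / (curve.ranks[-1] - curve.ranks[0])
    yn = (y - y[-1]) / (y[0] - y[-1])
    h = x[1] - x[0]
    d1 = np.gradient(yn, h)
    d2 = np.gradient(d1, h)
    curvature = np.abs(d2) / (1 + d1**2) ** 1.5
    return int(curve.ranks[int(np.argmax(curvature))])


def call_svgs(
    results: Sequence[CoSSResult],
    sensitivity: float = 1.0,
    smoothing_window: int = 1,
    cutoff_rank: Optional[int] = None,
    cutoff_score: Optional[float] = None,
) -> pd.DataFrame:
    """Scores table augmented with ``rank`` and boolean ``sv`` columns.

    Ranks are assigned in descending score order (ties broken by feature
    id); features with rank <= K are called spatially variable. A
    practitioner-supplied ``cutoff_rank`` or ``cutoff_score`` (sv when
    score >= cutoff_score) overrides the automatic knee. Unscored features
    get sv=False and no rank.
    """
    df = results_to_frame(results)
    scored = df["coss"].notna()
    nscored = int(scored.sum())
    df["rank"] = pd.array([None] * len(df), dtype="Int64")
    df.loc[scored, "rank"] = np.arange(1, nscored + 1)
    df["sv"] = False

    if cutoff_rank is not None and cutoff_score is not None:
        raise UsageError("give at most one of cutoff_rank / cutoff_score")
    if cutoff_rank is not None:
        if not (1 <= cutoff_rank <= nscored):
            raise UsageError(
                f"cutoff_rank {cutoff_rank} out of range 1..{nscored}"
            )
        df.loc[scored, "sv"] = df.loc[scored, "rank"] <= cutoff_rank
        return df
    if cutoff_score is not None:
        df.loc[scored, "sv"] = df.loc[scored, "coss"] >= cutoff_score
        return df

    if nscored >= MIN_CURVE_POINTS:
        curve = RankCurve.from_scores(df.loc[scored, "coss"].to_numpy())
        k = kneedle_cutoff(curve, sensitivity=sensitivity, smoothing_window=smoothing_window)
    else:
        k = None
    if k is None:
        logger.warning("no knee detected in the score-rank curve; zero SV calls")
        return df
    df.loc[scored, "sv"] = df.loc[scored, "rank"] <= k
    return df
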