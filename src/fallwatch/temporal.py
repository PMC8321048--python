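"""Change-period detection on posture-feature series.

The fall signature is an abrupt, sustained change in a posture feature.
It is localized in three steps:

1. smooth the series with a centered moving average of width ``2N + 1``
   (``MA``); boundary windows are truncated and renormalized;
2. form the *modified difference* ``MD(t) = S(t + N0 + N1) - S(t - N0 - N1)``
   where ``S`` is the series smoothed with half-window ``N1`` — a smoothed
   symmetric derivative whose extrema mark abrupt transitions;
3. take the dominant extremum of ``MD`` and measure its full width at
   half extremum: walking outward from the extremum frame ``t*``, the
   half-level crossings ``f1`` and ``f2`` bound the candidate event and
   ``v_hw = |f1 - f2|`` estimates its duration.

Polarity is feature-specific: the centroid-to-ground distance ``d``
drops in a fall (minimum), the aspect ratio ``r`` rises (maximum), and
the area ``a`` can do either depending on fall direction, so for ``a``
both polarities are evaluated and the larger-magnitude one kept.

Event widths classify whole videos: with ``alpha1`` the smallest width
among fall videos and ``alpha2`` the largest among normal videos, the
midpoint ``PD = (alpha1 + alpha2) / 2`` is the per-feature decision
threshold — a video whose width reaches ``PD`` is labelled a fall video
(``l1``), otherwise normal (``l2``).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Literal, Mapping

import numpy as np

from .config import RunConfig

__all__ = [
    "ExtremumEvent",
    "PeriodThresholds",
    "FEATURES",
    "FEATURE_POLARITY",
    "moving_average",
    "modified_difference",
    "find_extremum",
    "half_width",
    "learn_period_thresholds",
    "classify_width",
    "classify_video",
    "analyze_video",
    "VideoAnalysis",
]

logger = logging.getLogger(__name__)

#: The three posture features the detector runs on.
FEATURES = ("d", "a", "r")

#: Extremum polarity per feature; ``both`` keeps the larger-magnitude one.
FEATURE_POLARITY: Mapping[str, str] = {"d": "min", "r": "max", "a": "both"}

Polarity = Literal["max", "min"]


@dataclasses.dataclass(frozen=True)
class ExtremumEvent:
    """Dominant extremum of a modified-difference series with its half-width.

    ``f1``/``f2`` are real-valued frame positions of the half-level
    crossings (linear interpolation between frames); ``v_hw = |f2 - f1|``.
    """

    polarity: Polarity
    frame: int
    value: float
    f1: float = np.nan
    f2: float = np.nan
    v_hw: float = np.nan

    def with_width(self, f1: float, f2: float) -> "ExtremumEvent":
        return dataclasses.replace(self, f1=f1, f2=f2, v_hw=abs(f2 - f1))


@dataclasses.dataclass(frozen=True)
class PeriodThresholds:
    """Per-feature width thresholds ``alpha1`` (min fall), ``alpha2`` (max normal), ``pd``."""

    alpha1: dict[str, float]
    alpha2: dict[str, float]
    pd: dict[str, float]


def moving_average(series: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with half-window ``n`` (window ``2n + 1``).

    Boundary windows are truncated to the available frames and divided by
    the actual sample count, so the output has the input's length and a
    constant series is reproduced exactly everywhere.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.size == 0:
        raise ValueError("empty series")
    if n < 0:
        raise ValueError("half-window must be >= 0")
    if n == 0:
        return x.copy()
    # cumulative-sum windowed mean with per-position effective counts
    csum = np.concatenate(([0.0], np.cumsum(x)))
    t = np.arange(x.size)
    lo = np.maximum(t - n, 0)
    hi = np.minimum(t + n, x.size - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def modified_difference(series: np.ndarray, n0: int, n1: int) -> np.ndarray:
    """Smoothed symmetric difference ``S(t + n0 + n1) - S(t - n0 - n1)``.

    ``S`` is the input smoothed with half-window ``n1``; look-ahead and
    look-back indices are clamped to the series ends, so the output keeps
    the input's length. The series must be longer than ``2(n0 + n1)`` so
    at least one frame sees both an unclamped past and future value.
    """
    x = np.asarray(series, dtype=float)
    if n1 < 1:
        raise ValueError("n1 must be >= 1")
    if n0 < 0:
        raise ValueError("n0 must be >= 0")
    span = n0 + n1
    if x.size < 2 * span + 1:
        raise ValueError(
            f"series of length {x.size} too short for offsets n0={n0}, n1={n1} "
            f"(needs at least {2 * span + 1} frames)"
        )
    smoothed = moving_average(x, n1)
    t = np.arange(x.size)
    ahead = np.minimum(t + span, x.size - 1)
    behind = np.maximum(t - span, 0)
    return smoothed[ahead] - smoothed[behind]


def find_extremum(md: np.ndarray, polarity: Polarity) -> ExtremumEvent | None:
    """Global maximum or minimum of an MD series; ``None`` if MD is all zero.

    Ties break toward the earlier frame (``argmax``/``argmin`` convention).
    """
    md = np.asarray(md, dtype=float)
    if md.size == 0 or np.all(md == 0.0):
        return None
    if polarity == "max":
        idx = int(np.argmax(md))
    elif polarity == "min":
        idx = int(np.argmin(md))
    else:
        raise ValueError(f"polarity must be 'max' or 'min', got {polarity!r}")
    return ExtremumEvent(polarity=polarity, frame=idx, value=float(md[idx]))


def _cross_outward(md: np.ndarray, start: int, level: float, step: int, rising: bool) -> float:
    """Frame position (real) of the nearest half-level crossing from ``start``.

    Walks in direction ``step``; ``rising`` says whether the curve sits
    above the level at the extremum (maximum) or below it (minimum is
    handled by the caller via negation). Clamps to the series end when
    the curve never crosses.
    """
    n = md.size
    t = start
    while True:
        nxt = t + step
        if nxt < 0 or nxt >= n:
            logger.warning(
                "half-width crossing ran off the series end at frame %d; clamping", t
            )
            return float(t)
        if (md[nxt] < level) if rising else (md[nxt] > level):
            # linear interpolation between t and nxt
            y0, y1 = md[t], md[nxt]
            if y1 == y0:
                return float(nxt)
            frac = (level - y0) / (y1 - y0)
            return float(t) + step * float(frac)
        t = nxt


def half_width(md: np.ndarray, event: ExtremumEvent) -> ExtremumEvent:
    """Full width at half extremum of the event's MD curve.

    The half level is ``event.value / 2``; the nearest crossing on each
    side of the extremum frame is found by linear interpolation between
    frames. A side that never crosses before the series end is clamped
    there (with a warning).
    """
    md = np.asarray(md, dtype=float)
    sign = 1.0 if event.polarity == "max" else -1.0
    curve = sign * md  # extremum is now a positive maximum
    level = sign * event.value / 2.0
    f1 = _cross_outward(curve, event.frame, level, step=-1, rising=True)
    f2 = _cross_outward(curve, event.frame, level, step=+1, rising=True)
    return event.with_width(f1, f2)


@dataclasses.dataclass(frozen=True)
class VideoAnalysis:
    """Per-feature dominant events of one video plus the MD series."""

    events: dict[str, ExtremumEvent | None]
    md: dict[str, np.ndarray]
    n_frames: int

    def widths(self) -> dict[str, float]:
        return {
            f: (e.v_hw if e is not None else 0.0) for f, e in self.events.items()
        }


def analyze_video(features, config: RunConfig | None = None) -> VideoAnalysis:
    """Run smoothing, modified difference, and half-width per feature.

    ``features`` is a feature table (DataFrame with ``d``, ``a``, ``r``
    columns, as produced by :func:`fallwatch.features.extract_feature_series`)
    or a mapping of feature name to 1-D array. Polarities follow
    :data:`FEATURE_POLARITY`; for the area both are tried and the
    larger-magnitude extremum kept (maximum wins an exact tie).
    """
    if config is None:
        config = RunConfig()
    series = {f: np.asarray(features[f], dtype=float) for f in FEATURES}
    n_frames = len(next(iter(series.values())))
    events: dict[str, ExtremumEvent | None] = {}
    mds: dict[str, np.ndarray] = {}
    for feat in FEATURES:
        x = series[feat]
        if np.any(~np.isfinite(x)):
            # long invalid gaps are excluded by filling with the series median,
            # which contributes no transition of its own
            med = float(np.nanmedian(x))
            x = np.where(np.isfinite(x), x, med)
        md = modified_difference(x, config.md_offset, config.md_half_window)
        mds[feat] = md
        rule = FEATURE_POLARITY[feat]
        if rule == "both":
            cand = [find_extremum(md, "max"), find_extremum(md, "min")]
            cand = [c for c in cand if c is not None]
            event = max(cand, key=lambda e: (abs(e.value), e.polarity == "max")) if cand else None
        else:
            event = find_extremum(md, rule)  # type: ignore[arg-type]
        events[feat] = half_width(md, event) if event is not None else None
    return VideoAnalysis(events=events, md=mds, n_frames=n_frames)


def learn_period_thresholds(
    widths_by_video: Mapping[str, Mapping[str, float]],
    labels: Mapping[str, str],
) -> PeriodThresholds:
    """Per-feature decision thresholds from labelled video widths.

    ``widths_by_video`` maps video id to its per-feature ``v_hw``;
    ``labels`` maps video id to ``"l1"`` (fall video) or ``"l2"``
    (normal). ``alpha1`` is the minimum fall width, ``alpha2`` the
    maximum normal width, and ``pd`` their midpoint, independently per
    feature. Both classes must be present.
    """
    fall_ids = [v for v, c in labels.items() if c == "l1"]
    normal_ids = [v for v, c in labels.items() if c == "l2"]
    if not fall_ids or not normal_ids:
        raise ValueError("need at least one l1 (fall) and one l2 (normal) video")
    alpha1, alpha2, pd = {}, {}, {}
    for feat in FEATURES:
        a1 = min(float(widths_by_video[v][feat]) for v in fall_ids)
        a2 = max(float(widths_by_video[v][feat]) for v in normal_ids)
        alpha1[feat] = a1
        alpha2[feat] = a2
        pd[feat] = (a1 + a2) / 2.0
        if a2 > a1:
            logger.warning(
                "feature %s: normal widths overlap fall widths (alpha2=%.2f > alpha1=%.2f)",
                feat, a2, a1,
            )
    return PeriodThresholds(alpha1=alpha1, alpha2=alpha2, pd=pd)


def classify_width(v_hw: float, pd: float) -> str:
    """``l1`` (fall video) iff the event width reaches the threshold."""
    return "l1" if v_hw >= pd else "l2"


def classify_video(
    widths: Mapping[str, float],
    thresholds: PeriodThresholds,
    features: Iterable[str] = FEATURES,
) -> str:
    """Video class by majority vote of the per-feature width rules."""
    votes = [classify_width(widths[f], thresholds.pd[f]) for f in features]
    return "l1" if votes.count("l1") * 2 > len(votes) else "l2"
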