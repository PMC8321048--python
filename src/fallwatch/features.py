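"""Per-frame posture features of a binary silhouette.

A standing person's silhouette is tall and narrow; a lying person's is
short and wide. Three scalars capture this per frame:

* ``d`` — vertical distance between the silhouette centroid and the
  *virtual grounding point* (VGP), the point where the vertical line
  through the centroid meets the bottom of the silhouette's bounding
  box. Large while upright, near zero when lying.
* ``a`` — silhouette area (foreground pixel count).
* ``r`` — bounding-box aspect ratio width/height; below 1 upright,
  above 1 lying.

Coordinates are raster: ``x`` is the column, ``y`` the row, and ``y``
grows downward, so the grounding point is the *largest* foreground row.
Centroids are kept sub-pixel (real-valued).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Centroid",
    "GroundingPoint",
    "FrameFeatures",
    "EmptyMaskError",
    "centroid",
    "virtual_grounding_point",
    "frame_features",
    "extract_feature_series",
    "FEATURE_COLUMNS",
]

#: Column layout of a per-frame feature table.
FEATURE_COLUMNS = ["frame", "x_c", "y_c", "x_vgp", "y_vgp", "d", "a", "r", "valid"]


class EmptyMaskError(ValueError):
    """Raised when a silhouette feature is requested for an empty mask."""


@dataclasses.dataclass(frozen=True)
class Centroid:
    x_c: float
    y_c: float


@dataclasses.dataclass(frozen=True)
class GroundingPoint:
    x_vgp: float
    y_vgp: float


@dataclasses.dataclass(frozen=True)
class FrameFeatures:
    """Posture features of one frame; ``valid`` is False for empty masks."""

    x_c: float = np.nan
    y_c: float = np.nan
    x_vgp: float = np.nan
    y_vgp: float = np.nan
    d: float = np.nan
    a: float = np.nan
    r: float = np.nan
    w: float = np.nan
    h: float = np.nan
    valid: bool = True


def _foreground(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyMaskError("empty silhouette mask")
    return rows, cols


def centroid(mask: np.ndarray) -> Centroid:
    """Mean foreground coordinate ``(x_c, y_c)`` of a binary mask."""
    rows, cols = _foreground(mask)
    return Centroid(x_c=float(cols.mean()), y_c=float(rows.mean()))


def virtual_grounding_point(mask: np.ndarray) -> GroundingPoint:
    """Point on the centroid's vertical line at the silhouette's ground side.

    ``x_vgp`` equals the centroid column; ``y_vgp`` is the bottom-most
    foreground row, i.e. where the center line meets the ground side of
    the bounding box.
    """
    rows, cols = _foreground(mask)
    return GroundingPoint(x_vgp=float(cols.mean()), y_vgp=float(rows.max()))


def frame_features(mask: np.ndarray) -> FrameFeatures:
    """All posture features of one mask; invalid result for an empty mask."""
    try:
        rows, cols = _foreground(mask)
    except EmptyMaskError:
        return FrameFeatures(valid=False)
    x_c = float(cols.mean())
    y_c = float(rows.mean())
    y_vgp = float(rows.max())
    w = float(cols.max() - cols.min() + 1)
    h = float(rows.max() - rows.min() + 1)
    return FrameFeatures(
        x_c=x_c,
        y_c=y_c,
        x_vgp=x_c,
        y_vgp=y_vgp,
        d=abs(y_vgp - y_c),
        a=float(rows.size),
        r=w / h,
        w=w,
        h=h,
        valid=True,
    )


def extract_feature_series(
    masks: Sequence[np.ndarray] | np.ndarray,
    interpolation_max_gap: int = 12,
) -> pd.DataFrame:
    """Per-frame feature table for a mask sequence.

    Empty-mask frames are filled by linear interpolation when the gap is
    at most ``interpolation_max_gap`` frames; leading/trailing gaps of any
    length are filled from the nearest valid frame. Frames inside longer
    interior gaps keep ``valid == 0`` and NaN features.

    Returns a :data:`FEATURE_COLUMNS` DataFrame, one row per frame.
    """
    if len(masks) == 0:
        raise ValueError("empty mask sequence")
    feats = [frame_features(m) for m in masks]
    if not any(f.valid for f in feats):
        raise ValueError("all frames have empty masks; nothing to extract")

    df = pd.DataFrame(
        {
            "frame": np.arange(len(feats)),
            "x_c": [f.x_c for f in feats],
            "y_c": [f.y_c for f in feats],
            "x_vgp": [f.x_vgp for f in feats],
            "y_vgp": [f.y_vgp for f in feats],
            "d": [f.d for f in feats],
            "a": [f.a for f in feats],
            "r": [f.r for f in feats],
            "valid": [int(f.valid) for f in feats],
        }
    )

    valid = df["valid"].to_numpy(dtype=bool)
    fillable = _fillable_frames(valid, interpolation_max_gap)
    value_cols = ["x_c", "y_c", "x_vgp", "y_vgp", "d", "a", "r"]
    if fillable.any():
        interp = df[value_cols].interpolate(
            method="linear", limit_direction="both", limit_area=None
        )
        df.loc[fillable, value_cols] = interp.loc[fillable, value_cols]
        df.loc[fillable, "valid"] = 1
    return df


def _fillable_frames(valid: np.ndarray, max_gap: int) -> np.ndarray:
    """Invalid frames eligible for filling: edge gaps, or interior gaps <= max_gap."""
    fillable = np.zeros_like(valid)
    n = valid.size
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        edge_gap = i == 0 or j == n
        if edge_gap or (j - i) <= max_gap:
            fillable[i:j] = True
        i = j
    return fillable
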