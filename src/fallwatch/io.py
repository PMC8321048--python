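"""Readers and writers for the pipeline's file formats.

* masks / frames — PNG sequences in a directory, zero-padded numeric
  filenames (``000000.png`` ...), read back in filename order. Mask PNGs
  binarize on read (any nonzero value becomes 1). Video containers are
  not supported (no ffmpeg backend); extract frames to images first.
* feature tables — CSV, one row per frame, columns ``frame, x_c, y_c,
  x_vgp, y_vgp, d, a, r, valid``; invalid frames keep empty feature
  cells and ``valid == 0``.
* labels — two-column CSV ``frame,state`` with states ``S1``/``S2``,
  frame indices contiguous from 0.
* model — JSON holding the transition matrix, emission matrix, initial
  probabilities, learned period thresholds, and the symbol-encoding
  version tag.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS
from .hmm import HMMModel, state_ints_to_labels, state_labels_to_int
from .temporal import FEATURES, PeriodThresholds

__all__ = [
    "read_mask_sequence",
    "write_mask_sequence",
    "read_frame_sequence",
    "write_frame_sequence",
    "read_feature_table",
    "write_feature_table",
    "read_labels",
    "write_labels",
    "read_model",
    "write_model",
]

SYMBOL_ENCODING_VERSION = "tree-daR-v1"
_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


def _image_files(path: Path) -> list[Path]:
    if not path.exists():
        raise FileNotFoundError(path)
    if not path.is_dir():
        raise ValueError(
            f"{path} is not a directory; video containers are not supported, "
            "extract frames to an image sequence first"
        )
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    if not files:
        raise ValueError(f"no image files found in {path}")
    return files


def _read_stack(path: Path, name: str) -> tuple[np.ndarray, list[Path]]:
    files = _image_files(path)
    arrays = []
    shape = None
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim == 3:  # collapse RGB(A) to luminance
            img = img[..., :3].mean(axis=2)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"mixed resolutions in {name} sequence: {f.name} is "
                f"{img.shape}, expected {shape}"
            )
        arrays.append(img)
    return np.stack(arrays), files


def read_mask_sequence(path: str | Path) -> np.ndarray:
    """Binary mask stack ``(T, H, W)`` from a directory of images."""
    stack, _ = _read_stack(Path(path), "mask")
    return (stack != 0).astype(np.uint8)


def write_mask_sequence(masks: np.ndarray, path: str | Path) -> None:
    """Write masks as 8-bit PNGs ``000000.png`` ... (foreground = 255)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, mask in enumerate(np.asarray(masks)):
        iio.imwrite(path / f"{i:06d}.png", (mask.astype(np.uint8) * 255))


def read_frame_sequence(path: str | Path) -> np.ndarray:
    """Grayscale frame stack ``(T, H, W)`` from a directory of images."""
    stack, _ = _read_stack(Path(path), "frame")
    return stack.astype(np.uint8)


def write_frame_sequence(frames: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(np.asarray(frames)):
        iio.imwrite(path / f"{i:06d}.png", frame.astype(np.uint8))


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Feature CSV, one row per frame; invalid frames get empty cells."""
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    out = table[FEATURE_COLUMNS].copy()
    value_cols = [c for c in FEATURE_COLUMNS if c not in ("frame", "valid")]
    invalid = out["valid"] == 0
    out.loc[invalid, value_cols] = np.nan
    out.to_csv(path, index=False, float_format="%.6f", na_rep="")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    df["frame"] = df["frame"].astype(int)
    df["valid"] = df["valid"].astype(int)
    return df


def write_labels(states: np.ndarray, path: str | Path) -> None:
    """Per-frame state CSV ``frame,state`` with S1/S2 labels."""
    df = pd.DataFrame(
        {"frame": np.arange(len(states)), "state": state_ints_to_labels(states)}
    )
    df.to_csv(path, index=False)


def read_labels(path: str | Path) -> np.ndarray:
    """Integer state sequence from a label CSV; indices must run 0..T-1."""
    df = pd.read_csv(path)
    for col in ("frame", "state"):
        if col not in df.columns:
            raise ValueError(f"label file {path} missing column {col!r}")
    frames = df["frame"].to_numpy(dtype=int)
    if not np.array_equal(frames, np.arange(len(frames))):
        raise ValueError(f"label file {path} frame indices must be contiguous from 0")
    return state_labels_to_int(df["state"])


def write_model(
    model: HMMModel,
    path: str | Path,
    thresholds: PeriodThresholds | None = None,
) -> None:
    """JSON model file: A, B, pi, optional thresholds, encoding version."""
    doc = {
        "states": ["S1", "S2"],
        "symbols": [f"o{k}" for k in range(1, 9)],
        "symbol_encoding": SYMBOL_ENCODING_VERSION,
        "transitions": model.transitions.tolist(),
        "emissions": model.emissions.tolist(),
        "initial": model.initial.tolist(),
    }
    if thresholds is not None:
        doc["thresholds"] = {
            "alpha1": {f: thresholds.alpha1[f] for f in FEATURES},
            "alpha2": {f: thresholds.alpha2[f] for f in FEATURES},
            "pd": {f: thresholds.pd[f] for f in FEATURES},
        }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_model(path: str | Path) -> tuple[HMMModel, PeriodThresholds | None]:
    doc = json.loads(Path(path).read_text())
    if doc.get("symbol_encoding") != SYMBOL_ENCODING_VERSION:
        raise ValueError(
            f"model file uses symbol encoding {doc.get('symbol_encoding')!r}, "
            f"expected {SYMBOL_ENCODING_VERSION!r}"
        )
    model = HMMModel(
        transitions=np.array(doc["transitions"]),
        emissions=np.array(doc["emissions"]),
        initial=np.array(doc["initial"]),
    )
    thresholds = None
    if "thresholds" in doc:
        t = doc["thresholds"]
        thresholds = PeriodThresholds(
            alpha1=dict(t["alpha1"]), alpha2=dict(t["alpha2"]), pd=dict(t["pd"])
        )
    return model, thresholds
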