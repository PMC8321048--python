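"""Run configuration for the fall-monitoring pipeline.

All method constants live here rather than in the code: the smoothing
half-window ``ma_window_half`` (51 frames at 25 fps, about two seconds),
the modified-difference offsets ``md_offset``/``md_half_window``, the
graph-cut seed refresh interval, the HMM initial state distribution, and
the invalid-frame interpolation limit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclasses.dataclass
class RunConfig:
    """Pipeline parameters.

    Parameters
    ----------
    fps
        Video frame rate in frames per second.
    ma_window_half
        Half-window ``N`` of the centered moving average; the full window
        is ``2N + 1`` frames.
    md_offset, md_half_window
        Offsets ``N0`` and ``N1`` of the modified difference: the smoothed
        series is compared ``N0 + N1`` frames ahead and behind each frame.
    reseed_interval
        How often (in frames) the graph-cut seeds are refreshed from the
        background-model foreground mask.
    initial_probs
        HMM initial state distribution ``(P(abnormal), P(normal))``.
    interpolation_max_gap
        Longest run of silhouette-less frames whose features are filled by
        linear interpolation; longer gaps stay invalid.
    pseudocount
        Additive smoothing for emission estimation; 0 keeps exact zeros.
    """

    fps: float = 25.0
    ma_window_half: int = 51
    md_offset: int = 0
    md_half_window: int = 51
    reseed_interval: int = 100
    initial_probs: tuple[float, float] = (0.8, 0.2)
    interpolation_max_gap: int = 12
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.ma_window_half < 0:
            raise ValueError("ma_window_half must be >= 0")
        if self.md_half_window < 1:
            raise ValueError("md_half_window (N1) must be >= 1")
        if self.md_offset < 0:
            raise ValueError("md_offset (N0) must be >= 0")
        if self.reseed_interval < 1:
            raise ValueError("reseed_interval must be >= 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        pi = tuple(float(p) for p in self.initial_probs)
        if len(pi) != 2 or min(pi) < 0 or abs(sum(pi) - 1.0) > 1e-9:
            raise ValueError("initial_probs must be two nonnegative values summing to 1")
        self.initial_probs = pi


def load_config(path: str | Path) -> RunConfig:
    """Read a :class:`RunConfig` from a JSON or YAML document."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "initial_probs" in data:
        data["initial_probs"] = tuple(data["initial_probs"])
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config as JSON (``.json``) or YAML (anything else)."""
    path = Path(path)
    data = dataclasses.asdict(config)
    data["initial_probs"] = list(data["initial_probs"])
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
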