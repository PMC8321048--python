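"""Synthetic labelled inputs: scripted silhouette scenes and HMM samples.

Two generators feed the test pyramid:

* :func:`generate_scene` renders a single actor as a filled ellipse in a
  320x240, 25 fps scene, following a script of timed actions (walking,
  standing, sitting, lying, the slow transitions between them, and
  sideways/forward/backward falls). The ellipse's half-axes morph
  linearly between posture keyframes — upright is roughly three times as
  tall as wide, lying the reverse — so the silhouette features behave the
  way real fall footage does: the centroid-to-ground distance ``d``
  collapses in a fall, the aspect ratio ``r`` flips past 1, and the area
  pulses up (forward fall, toward the camera) or down (sideways/backward)
  depending on direction. Ground truth marks fall-action frames abnormal
  (``S1``), everything else normal (``S2``).

* :func:`sample_hmm` draws state/symbol sequences from a known model,
  the recovery oracle for the supervised estimators.

All randomness flows from a single seed. Walking paces between the frame
margins (direction reflects); a person geometry that cannot fit the
frame raises an error.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .hmm import HMMModel, N_SYMBOLS

__all__ = [
    "Action",
    "ActionScript",
    "SceneConfig",
    "Scene",
    "ACTIONS",
    "FALL_ACTIONS",
    "generate_scene",
    "sample_hmm",
    "random_fall_script",
    "random_normal_script",
]

#: Posture keyframes as (half_width, half_height) fractions of person size.
_POSTURES = {
    "upright": (0.5, 0.5),    # of (width, height)
    "sit": (0.65, 0.62),
    "lie": (1.0, 1.0),        # axes swapped below
}

FALL_ACTIONS = ("fall_sideways", "fall_forward", "fall_backward")

#: action -> (start posture, end posture, walks?, gait sway?, area-scale target)
#: Walking and standing share the gait sway (height bob + width swing) so
#: their silhouette statistics have equal means; only walking translates.
#: The area-scale target models apparent size after a fall: falling toward
#: the camera (forward) leaves a persistently larger silhouette, sideways
#: or backward a foreshortened one; the scale ramps during the fall and
#: persists until a recovery transition ramps it back to 1. ``None``
#: keeps the prevailing scale.
ACTIONS = {
    "walk": ("upright", "upright", True, True, None),
    "stand": ("upright", "upright", False, True, None),
    "sit": ("sit", "sit", False, False, None),
    "lie": ("lie", "lie", False, False, None),
    "sit_to_lie": ("sit", "lie", False, False, None),
    "lie_to_sit": ("lie", "sit", False, False, 1.0),
    "sit_to_stand": ("sit", "upright", False, False, 1.0),
    "walk_to_sit": ("upright", "sit", False, False, None),
    "fall_sideways": ("upright", "lie", False, False, 0.75),
    "fall_forward": ("upright", "lie", False, False, 1.35),
    "fall_backward": ("upright", "lie", False, False, 0.7),
}

_MAX_FALL_SECONDS = 1.5


@dataclasses.dataclass(frozen=True)
class Action:
    """One scripted segment: an action name and its duration in seconds."""

    name: str
    duration: float

    def __post_init__(self) -> None:
        if self.name not in ACTIONS:
            raise ValueError(f"unknown action {self.name!r}; choose from {sorted(ACTIONS)}")
        if self.duration <= 0:
            raise ValueError("action duration must be positive")
        if self.name in FALL_ACTIONS and self.duration > _MAX_FALL_SECONDS:
            raise ValueError(f"falls last at most {_MAX_FALL_SECONDS} s")


ActionScript = Sequence[Action]


@dataclasses.dataclass
class SceneConfig:
    """Scene geometry, timing, rendering noise, and the master seed."""

    width: int = 320
    height: int = 240
    fps: float = 25.0
    person_height: int = 90
    person_width: int = 30
    floor_row: int = 230
    walk_speed: float = 40.0       # px/s
    bob_amplitude: float = 0.04    # fractional height modulation of the gait
    swing_amplitude: float = 0.12  # fractional width modulation (leg swing / sway)
    bob_freq: float = 2.0          # Hz, gait frequency
    noise_sigma: float = 0.0       # 8-bit gray levels, grayscale rendering only
    start_x: float | None = None   # column of the person center; default: left margin
    seed: int = 0


@dataclasses.dataclass
class Scene:
    """A generated scene: masks, optional gray frames, and ground truth."""

    masks: np.ndarray                  # (T, H, W) uint8 in {0, 1}
    frames: np.ndarray | None          # (T, H, W) uint8 or None
    states: np.ndarray                 # (T,) ints, 0 = S1 abnormal, 1 = S2 normal
    fall_intervals: list[tuple[int, int]]  # inclusive frame ranges of fall actions

    @property
    def n_frames(self) -> int:
        return int(self.states.size)


def _axes(posture: str, cfg: SceneConfig) -> tuple[float, float]:
    """Ellipse half-axes (ax, ay) in pixels for a posture keyframe."""
    hw = cfg.person_width / 2.0
    hh = cfg.person_height / 2.0
    if posture == "upright":
        return hw, hh
    if posture == "sit":
        fx, fy = _POSTURES["sit"]
        return hw * fx * 2.0, hh * fy
    if posture == "lie":
        return hh, hw  # axes swapped: as long lying down as tall standing
    raise ValueError(posture)


def _ellipse_mask(h: int, w: int, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    """Filled ellipse drawn only inside its bounding box for speed."""
    mask = np.zeros((h, w), dtype=np.uint8)
    r0 = max(int(np.floor(cy - ay)), 0)
    r1 = min(int(np.ceil(cy + ay)), h - 1)
    c0 = max(int(np.floor(cx - ax)), 0)
    c1 = min(int(np.ceil(cx + ax)), w - 1)
    if r1 < r0 or c1 < c0:
        return mask
    yy = np.arange(r0, r1 + 1)[:, None]
    xx = np.arange(c0, c1 + 1)[None, :]
    inside = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside.astype(np.uint8)
    return mask


def generate_scene(
    script: ActionScript,
    config: SceneConfig | None = None,
    render_gray: bool = False,
) -> Scene:
    """Render a scripted scene into masks, truth labels, and fall intervals.

    Each action contributes ``round(duration * fps)`` frames. Posture
    morphs linearly from the action's start to its end keyframe; falls
    additionally ramp a persistent area scale whose target depends on
    the fall direction (forward falls leave a larger silhouette toward
    the camera, sideways/backward falls a foreshortened one; recovery
    transitions ramp it back). Walking translates the actor
    horizontally, reflecting at the frame margins, with a periodic gait
    sway (height bob and leg-swing width modulation) shared by standing.

    With ``render_gray`` the scene is also rasterized as 8-bit frames:
    a smooth textured background, a striped body texture that moves with
    the actor, and additive Gaussian noise of ``config.noise_sigma``.
    """
    if not script:
        raise ValueError("empty action script")
    cfg = config if config is not None else SceneConfig()
    rng = np.random.default_rng(cfg.seed)

    margin = max(_axes("lie", cfg)[0], _axes("upright", cfg)[0]) + 2
    if 2 * margin >= cfg.width or cfg.person_height >= cfg.floor_row:
        raise ValueError("person does not fit the frame with this geometry")

    n_frames_per_action = [int(round(a.duration * cfg.fps)) for a in script]
    total = int(sum(n_frames_per_action))
    masks = np.zeros((total, cfg.height, cfg.width), dtype=np.uint8)
    states = np.ones(total, dtype=int)  # default S2 normal
    fall_intervals: list[tuple[int, int]] = []

    if render_gray:
        frames = np.empty((total, cfg.height, cfg.width), dtype=np.uint8)
        yy = np.arange(cfg.height)[:, None]
        xx = np.arange(cfg.width)[None, :]
        phase_y, phase_x = rng.uniform(0, 2 * np.pi, size=2)
        background = (
            185.0
            + 20.0 * np.sin(2 * np.pi * yy / 97.0 + phase_y)
            + 15.0 * np.sin(2 * np.pi * xx / 131.0 + phase_x)
        )
    else:
        frames = None

    cx = float(cfg.start_x) if cfg.start_x is not None else margin
    direction = 1.0
    t_global = 0
    area_scale = 1.0
    for action, n in zip(script, n_frames_per_action):
        start_p, end_p, walks, sways, scale_target = ACTIONS[action.name]
        ax0, ay0 = _axes(start_p, cfg)
        ax1, ay1 = _axes(end_p, cfg)
        is_fall = action.name in FALL_ACTIONS
        if is_fall and n > 0:
            fall_intervals.append((t_global, t_global + n - 1))
            states[t_global : t_global + n] = 0  # S1
        scale_from = area_scale
        scale_to = area_scale if scale_target is None else float(scale_target)
        for k in range(n):
            u = k / max(n - 1, 1)  # 0..1 progress within the action
            ax = ax0 + (ax1 - ax0) * u
            ay = ay0 + (ay1 - ay0) * u
            s = scale_from + (scale_to - scale_from) * u
            if s != 1.0:
                ax *= np.sqrt(s)
                ay *= np.sqrt(s)
            if sways:
                phase = 2 * np.pi * cfg.bob_freq * t_global / cfg.fps
                ay *= 1.0 + cfg.bob_amplitude * np.sin(phase)
                ax *= 1.0 + cfg.swing_amplitude * np.sin(2 * phase)
            if walks:
                cx += direction * cfg.walk_speed / cfg.fps
                if cx > cfg.width - margin:
                    cx = cfg.width - margin
                    direction = -1.0
                elif cx < margin:
                    cx = margin
                    direction = 1.0
            cy = cfg.floor_row - ay
            if cx - ax < -1 or cx + ax > cfg.width or cy - ay < -1 or cy + ay > cfg.floor_row + 1:
                raise ValueError(
                    f"person leaves the frame at frame {t_global} "
                    f"(center x={cx:.1f}, half-axes {ax:.1f}x{ay:.1f})"
                )
            mask = _ellipse_mask(cfg.height, cfg.width, cx, cy, ax, ay)
            if not mask.any():
                raise ValueError(f"degenerate (empty) silhouette at frame {t_global}")
            masks[t_global] = mask
            if frames is not None:
                img = background.copy()
                body = mask.astype(bool)
                rows = np.nonzero(body)[0]
                top = rows.min()
                stripe = 95.0 + 45.0 * np.sin(2 * np.pi * (yy - top) / 9.0)
                img[body] = np.broadcast_to(stripe, img.shape)[body]
                if cfg.noise_sigma > 0:
                    img += rng.normal(0.0, cfg.noise_sigma, size=img.shape)
                frames[t_global] = np.clip(img, 0, 255).astype(np.uint8)
            t_global += 1
        area_scale = scale_to

    return Scene(masks=masks, frames=frames, states=states, fall_intervals=fall_intervals)


def sample_hmm(
    model: HMMModel, length: int, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a (states, symbols) pair of length ``length`` from a model."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = np.empty(length, dtype=int)
    symbols = np.empty(length, dtype=int)
    states[0] = rng.choice(2, p=model.initial / model.initial.sum())
    for t in range(1, length):
        row = model.transitions[states[t - 1]]
        states[t] = rng.choice(2, p=row / row.sum())
    for j in range(2):
        idx = np.nonzero(states == j)[0]
        if idx.size:
            row = model.emissions[j]
            symbols[idx] = rng.choice(N_SYMBOLS, size=idx.size, p=row / row.sum())
    return states, symbols


def random_fall_script(
    rng: np.random.Generator, total_seconds: float = 100.0
) -> list[Action]:
    """Walk, fall in a random direction (0.6-1.2 s), then lie still.

    The walking and lying spans split the remaining time 45/55 with a
    little jitter, keeping every script close to ``total_seconds`` long.
    """
    fall = Action(str(rng.choice(FALL_ACTIONS)), float(rng.uniform(0.6, 1.2)))
    rest = total_seconds - fall.duration
    walk_frac = float(rng.uniform(0.40, 0.55))
    return [
        Action("walk", rest * walk_frac),
        fall,
        Action("lie", rest * (1.0 - walk_frac)),
    ]


def random_normal_script(
    rng: np.random.Generator, total_seconds: float = 100.0
) -> list[Action]:
    """Ambulatory daily activity: alternating walking and standing spans."""
    script: list[Action] = []
    remaining = total_seconds
    toggle = bool(rng.integers(2))
    while remaining > 1.0:
        span = float(min(rng.uniform(8.0, 25.0), remaining))
        script.append(Action("walk" if toggle else "stand", span))
        toggle = not toggle
        remaining -= span
    if not script:
        script.append(Action("walk", total_seconds))
    return script
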