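"""End-to-end synthetic evaluation study.

Generates a labelled corpus of scripted scenes (fall scenes: walk, then
a 0.6–1.2 s fall in a random direction, then lying; normal scenes:
ambulatory walk/stand activity), splits it into training and held-out
halves, learns the period-detection thresholds and the two-state HMM on
the training half, and scores the held-out half at two levels:

* video level — the l1/l2 width-threshold classification;
* frame level — Viterbi decoding against ground-truth states,
  including the Jaccard overlap of decoded abnormal frames with the
  true fall frames.

Emission training uses a tiny pseudocount (1e-6) so a symbol unseen in
training cannot make a held-out sequence impossible; this does not
change any counted probability at the reported precision.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import RunConfig
from .features import extract_feature_series
from .hmm import S1, evaluate, symbolize, train_model, viterbi
from .synthgen import SceneConfig, generate_scene, random_fall_script, random_normal_script
from .temporal import analyze_video, classify_video, learn_period_thresholds

__all__ = ["SceneRecord", "StudyResult", "run_synthetic_study"]

STUDY_PSEUDOCOUNT = 1e-6


@dataclasses.dataclass
class SceneRecord:
    """One analyzed scene: its truth labels and temporal analysis."""

    scene_id: str
    is_fall: bool
    states: np.ndarray
    analysis: object  # temporal.VideoAnalysis

    @property
    def n_frames(self) -> int:
        return int(self.states.size)


@dataclasses.dataclass
class StudyResult:
    video_accuracy: float          # % held-out videos classified l1/l2 correctly
    frame_accuracy: float          # % held-out frames decoded correctly (pooled)
    frame_accuracy_min: float      # worst single held-out scene
    mean_jaccard: float            # decoded-S1 vs true-S1 overlap, fall scenes
    min_jaccard: float
    metrics: dict[str, float]      # pooled precision/recall/accuracy/specificity/npv
    thresholds: object             # temporal.PeriodThresholds
    model: object                  # hmm.HMMModel
    n_train: int
    n_test: int


def _make_scene(rng: np.random.Generator, is_fall: bool, seconds: float,
                scene_seed: int) -> SceneRecord:
    script = (random_fall_script(rng, seconds) if is_fall
              else random_normal_script(rng, seconds))
    scene = generate_scene(script, SceneConfig(seed=scene_seed))
    table = extract_feature_series(scene.masks)
    analysis = analyze_video(table)
    return SceneRecord(
        scene_id=f"{'fall' if is_fall else 'normal'}-{scene_seed}",
        is_fall=is_fall,
        states=scene.states,
        analysis=analysis,
    )


def run_synthetic_study(
    seed: int = 0,
    n_fall: int = 10,
    n_normal: int = 10,
    scene_seconds: float = 100.0,
    config: RunConfig | None = None,
) -> StudyResult:
    """Train on half the scenes, score the other half.

    The split is stratified: half the fall scenes and half the normal
    scenes train, the rest are held out. All randomness (scripts, scene
    seeds) derives from ``seed``.
    """
    if config is None:
        config = RunConfig(pseudocount=STUDY_PSEUDOCOUNT)
    rng = np.random.default_rng(seed)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n_fall + n_normal)
    records = [
        _make_scene(rng, is_fall=i < n_fall, seconds=scene_seconds,
                    scene_seed=int(scene_seeds[i]))
        for i in range(n_fall + n_normal)
    ]
    falls = [r for r in records if r.is_fall]
    normals = [r for r in records if not r.is_fall]
    train = falls[: n_fall // 2] + normals[: n_normal // 2]
    test = falls[n_fall // 2 :] + normals[n_normal // 2 :]

    thresholds = learn_period_thresholds(
        {r.scene_id: r.analysis.widths() for r in train},
        {r.scene_id: ("l1" if r.is_fall else "l2") for r in train},
    )
    train_states = np.concatenate([r.states for r in train])
    train_symbols = np.concatenate(
        [symbolize(r.analysis.events, thresholds, r.n_frames).symbols for r in train]
    )
    model = train_model(train_states, train_symbols, initial=config.initial_probs,
                        pseudocount=config.pseudocount)

    video_hits = 0
    preds, truths = [], []
    per_scene_acc = []
    jaccards = []
    for r in test:
        label = classify_video(r.analysis.widths(), thresholds)
        if (label == "l1") == r.is_fall:
            video_hits += 1
        symbols = symbolize(r.analysis.events, thresholds, r.n_frames)
        path = viterbi(symbols, model)
        preds.append(path)
        truths.append(r.states)
        per_scene_acc.append(100.0 * float(np.mean(path == r.states)))
        if r.is_fall:
            pred_s1 = path == S1
            true_s1 = r.states == S1
            union = np.logical_or(pred_s1, true_s1).sum()
            jaccards.append(
                float(np.logical_and(pred_s1, true_s1).sum() / union) if union else 1.0
            )
    _, metrics = evaluate(np.concatenate(preds), np.concatenate(truths))
    return StudyResult(
        video_accuracy=100.0 * video_hits / len(test),
        frame_accuracy=metrics["accuracy"],
        frame_accuracy_min=min(per_scene_acc),
        mean_jaccard=float(np.mean(jaccards)) if jaccards else float("nan"),
        min_jaccard=float(np.min(jaccards)) if jaccards else float("nan"),
        metrics=metrics,
        thresholds=thresholds,
        model=model,
        n_train=len(train),
        n_test=len(test),
    )
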