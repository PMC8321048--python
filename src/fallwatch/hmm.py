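"""Two-state discrete-emission HMM over fall-detection symbols.

Hidden states are ``S1`` (abnormal: falling) and ``S2`` (normal: every
other daily action). Each frame emits one of eight symbols ``o1..o8``,
the leaves of a three-level binary tree over the per-feature period
detections: a frame's flag for feature ``X`` is set when the frame lies
inside that feature's detected event interval *and* the event width
reaches the feature threshold ``PD(X)``. With flags ``(flag_d, flag_a,
flag_r)``,

    o-index = 1 + 4 * (1 - flag_d) + 2 * (1 - flag_a) + (1 - flag_r)

so all flags set gives ``o1`` (every feature says "fall event here") and
no flags gives ``o8`` (nothing detected).

The model is trained by supervised counting: transition probabilities
from the co-occurrence matrix of consecutive ground-truth state pairs,
emissions from per-state symbol frequencies (optionally with a
pseudocount). Decoding is Viterbi in log space; evaluation is the
frame-level confusion over abnormal/normal with precision, recall,
accuracy, specificity, and negative predictive value as percentages.

States are encoded as integers 0 (``S1``) and 1 (``S2``) throughout;
symbols as integers 0..7 for ``o1..o8``.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np

from .temporal import FEATURES, ExtremumEvent, PeriodThresholds

__all__ = [
    "S1",
    "S2",
    "N_SYMBOLS",
    "HMMModel",
    "SymbolSequence",
    "OutcomeCounts",
    "symbolize",
    "count_cooccurrences",
    "transition_matrix",
    "emission_matrix",
    "train_model",
    "viterbi",
    "evaluate",
    "state_labels_to_int",
    "state_ints_to_labels",
]

logger = logging.getLogger(__name__)

S1, S2 = 0, 1  # abnormal, normal
N_SYMBOLS = 8

STATE_NAMES = ("S1", "S2")
SYMBOL_NAMES = tuple(f"o{k}" for k in range(1, N_SYMBOLS + 1))


@dataclasses.dataclass
class HMMModel:
    """``lambda = (A, B, pi)``: 2x2 transitions, 2x8 emissions, initial probs."""

    transitions: np.ndarray
    emissions: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transitions.shape != (2, 2):
            raise ValueError("transitions must be 2x2")
        if self.emissions.shape != (2, N_SYMBOLS):
            raise ValueError(f"emissions must be 2x{N_SYMBOLS}")
        if self.initial.shape != (2,):
            raise ValueError("initial must have length 2")
        for name, arr in [("transitions", self.transitions),
                          ("emissions", self.emissions),
                          ("initial", self.initial[None, :])]:
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValueError(f"{name} entries must be probabilities")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-4):
                raise ValueError(f"{name} rows must sum to 1")


@dataclasses.dataclass(frozen=True)
class SymbolSequence:
    """Per-frame observation symbols (0-based) with their feature flags."""

    symbols: np.ndarray  # (T,) ints in 0..7
    flags: np.ndarray    # (T, 3) ints in {0,1}, column order d, a, r

    def __len__(self) -> int:
        return int(self.symbols.size)

    def names(self) -> list[str]:
        return [SYMBOL_NAMES[s] for s in self.symbols]


def symbolize(
    events: Mapping[str, ExtremumEvent | None],
    thresholds: PeriodThresholds,
    n_frames: int,
) -> SymbolSequence:
    """Per-frame symbols from the detected event intervals.

    For each feature, frames in ``[floor(f1), ceil(f2)]`` are flagged when
    the event's ``v_hw`` reaches that feature's threshold ``PD``; a missing
    event flags nothing. Flags map to symbols via the tree encoding in the
    module docstring.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    flags = np.zeros((n_frames, len(FEATURES)), dtype=int)
    for i, feat in enumerate(FEATURES):
        event = events.get(feat)
        if event is None or not np.isfinite(event.v_hw):
            continue
        if event.v_hw >= thresholds.pd[feat]:
            lo = max(int(np.floor(event.f1)), 0)
            hi = min(int(np.ceil(event.f2)), n_frames - 1)
            flags[lo : hi + 1, i] = 1
    fd, fa, fr = flags[:, 0], flags[:, 1], flags[:, 2]
    symbols = 4 * (1 - fd) + 2 * (1 - fa) + (1 - fr)  # 0-based: o1 -> 0
    return SymbolSequence(symbols=symbols, flags=flags)


def count_cooccurrences(states: np.ndarray) -> np.ndarray:
    """2x2 counts of consecutive state pairs ``(t, t+1)``.

    ``C[i, j]`` counts transitions from state ``i`` to state ``j``.
    """
    s = np.asarray(states, dtype=int)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("need a 1-D state sequence of length >= 2")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("states must be 0 (S1) or 1 (S2)")
    counts = np.zeros((2, 2), dtype=np.int64)
    np.add.at(counts, (s[:-1], s[1:]), 1)
    return counts


def transition_matrix(cooccurrence: np.ndarray) -> np.ndarray:
    """Row-normalized transition matrix ``a_ij = C_ij / C_i``.

    A state never left in the data (zero row) gets a uniform row, with a
    warning.
    """
    c = np.asarray(cooccurrence, dtype=float)
    if c.shape != (2, 2) or np.any(c < 0):
        raise ValueError("cooccurrence must be a nonnegative 2x2 matrix")
    rows = c.sum(axis=1)
    a = np.empty((2, 2))
    for i in range(2):
        if rows[i] == 0:
            logger.warning("state %s never observed as a pair origin; uniform row", STATE_NAMES[i])
            a[i] = 0.5
        else:
            a[i] = c[i] / rows[i]
    return a


def emission_matrix(
    states: np.ndarray,
    symbols: np.ndarray | SymbolSequence,
    pseudocount: float = 0.0,
) -> np.ndarray:
    """Per-state symbol frequencies ``b_j(k)`` with optional smoothing.

    ``b_j(k) = (count of symbol k in state j + pseudocount) /
    (count of state j + 8 * pseudocount)``. The default pseudocount of 0
    keeps structural zeros exact. A state absent from the data gets a
    uniform row, with a warning.
    """
    if isinstance(symbols, SymbolSequence):
        symbols = symbols.symbols
    s = np.asarray(states, dtype=int)
    o = np.asarray(symbols, dtype=int)
    if s.shape != o.shape:
        raise ValueError(f"states ({s.shape}) and symbols ({o.shape}) differ in length")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if np.any((o < 0) | (o >= N_SYMBOLS)):
        raise ValueError(f"symbols must lie in 0..{N_SYMBOLS - 1}")
    b = np.empty((2, N_SYMBOLS))
    for j in range(2):
        counts = np.bincount(o[s == j], minlength=N_SYMBOLS).astype(float)
        total = counts.sum()
        if total == 0 and pseudocount == 0:
            logger.warning("state %s absent from training data; uniform row", STATE_NAMES[j])
            b[j] = 1.0 / N_SYMBOLS
        else:
            b[j] = (counts + pseudocount) / (total + N_SYMBOLS * pseudocount)
    return b


def train_model(
    states: np.ndarray,
    symbols: np.ndarray | SymbolSequence,
    initial: tuple[float, float] = (0.8, 0.2),
    pseudocount: float = 0.0,
) -> HMMModel:
    """Supervised model fit: counted transitions + counted emissions."""
    a = transition_matrix(count_cooccurrences(states))
    b = emission_matrix(states, symbols, pseudocount=pseudocount)
    return HMMModel(transitions=a, emissions=b, initial=np.asarray(initial, dtype=float))


def viterbi(symbols: np.ndarray | SymbolSequence, model: HMMModel) -> np.ndarray:
    """Most probable state path for a symbol sequence, in log space.

    Zero probabilities become ``-inf`` (no silent smoothing); exact ties
    break toward the lower state index, i.e. toward ``S1``. A frame whose
    symbol has zero emission probability in *both* states makes every
    path impossible and raises an error naming the frame.
    """
    if isinstance(symbols, SymbolSequence):
        symbols = symbols.symbols
    o = np.asarray(symbols, dtype=int)
    if o.size == 0:
        raise ValueError("empty symbol sequence")
    with np.errstate(divide="ignore"):
        log_a = np.log(model.transitions)
        log_b = np.log(model.emissions)
        log_pi = np.log(model.initial)

    t_len = o.size
    score = log_pi + log_b[:, o[0]]
    if np.all(np.isneginf(score)):
        raise ValueError(f"symbol o{o[0] + 1} at frame 0 has zero probability in both states")
    back = np.zeros((t_len, 2), dtype=np.int8)
    for t in range(1, t_len):
        # cand[i, j]: ending in j having come from i
        cand = score[:, None] + log_a
        back[t] = np.argmax(cand, axis=0)  # ties -> lower index = S1
        score = cand[back[t], [0, 1]] + log_b[:, o[t]]
        if np.all(np.isneginf(score)):
            raise ValueError(
                f"symbol o{o[t] + 1} at frame {t} has zero emission probability in both states"
            )
    path = np.empty(t_len, dtype=int)
    path[-1] = int(np.argmax(score))
    for t in range(t_len - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


@dataclasses.dataclass(frozen=True)
class OutcomeCounts:
    """Frame-level confusion: abnormal is the positive class.

    ``as1`` detected abnormal, ``as2`` missed abnormal, ``ns1`` correct
    normal, ``ns2`` false abnormal.
    """

    as1: int
    as2: int
    ns1: int
    ns2: int

    @property
    def total(self) -> int:
        return self.as1 + self.as2 + self.ns1 + self.ns2


def _pct(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting NaN", name)
        return float("nan")
    return 100.0 * num / den


def evaluate(
    predicted: np.ndarray,
    truth: np.ndarray,
    guard_frames: int = 0,
) -> tuple[OutcomeCounts, dict[str, float]]:
    """Frame-level metrics of a decoded state path against ground truth.

    Metrics (percentages): precision ``As1/(As1+Ns2)``, recall
    ``As1/(As1+As2)``, accuracy ``(As1+Ns1)/total``, specificity
    ``Ns1/(Ns1+Ns2)``, NPV ``Ns1/(Ns1+As2)``. Undefined ratios are NaN
    with a warning.

    ``guard_frames > 0`` enables the low-risk exclusion rule: false
    abnormal frames within that many frames of a true abnormal interval
    are dropped from the counts (a near-miss alarm adjacent to a real
    fall is not penalized). Off by default.
    """
    p = np.asarray(predicted, dtype=int)
    t = np.asarray(truth, dtype=int)
    if p.size == 0:
        raise ValueError("empty state sequences")
    if p.shape != t.shape:
        raise ValueError("predicted and truth lengths differ")

    keep = np.ones(p.size, dtype=bool)
    if guard_frames > 0:
        near = np.zeros(p.size, dtype=bool)
        abn = np.nonzero(t == S1)[0]
        for idx in abn:
            near[max(idx - guard_frames, 0) : idx + guard_frames + 1] = True
        keep &= ~((p == S1) & (t == S2) & near)

    p, t = p[keep], t[keep]
    as1 = int(np.sum((t == S1) & (p == S1)))
    as2 = int(np.sum((t == S1) & (p == S2)))
    ns1 = int(np.sum((t == S2) & (p == S2)))
    ns2 = int(np.sum((t == S2) & (p == S1)))
    counts = OutcomeCounts(as1=as1, as2=as2, ns1=ns1, ns2=ns2)
    metrics = {
        "precision": _pct(as1, as1 + ns2, "precision"),
        "recall": _pct(as1, as1 + as2, "recall"),
        "accuracy": _pct(as1 + ns1, counts.total, "accuracy"),
        "specificity": _pct(ns1, ns1 + ns2, "specificity"),
        "npv": _pct(ns1, ns1 + as2, "npv"),
    }
    return counts, metrics


def state_labels_to_int(labels) -> np.ndarray:
    """Map ``S1``/``S2`` label strings to the 0/1 integer encoding."""
    lookup = {"S1": S1, "S2": S2}
    try:
        return np.array([lookup[str(x)] for x in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown state label {exc.args[0]!r}; expected S1 or S2") from None


def state_ints_to_labels(states: np.ndarray) -> list[str]:
    return [STATE_NAMES[s] for s in np.asarray(states, dtype=int)]
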