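"""Moving-person silhouette extraction.

Three stages per frame:

1. a per-pixel online Mixture-of-Gaussians background model: each pixel
   keeps ``K`` Gaussian components (weight, mean, variance). A frame
   value matching a component (within ``match_threshold`` standard
   deviations) adapts it; an unmatched value replaces the least
   plausible component. Components are ranked by weight/sigma and the
   top-ranked ones holding ``background_ratio`` of the weight form the
   background; pixels not matching any background component are raw
   foreground.
2. graph-cut refinement: a binary labeling over the 4-connected pixel
   grid minimizing unary intensity-likelihood terms (with hard
   constraints at eroded seed cores) plus contrast-weighted pairwise
   terms ``lambda_c * exp(-dI^2 / (2 beta))``, solved exactly by
   max-flow/min-cut. Seeds come from the model's foreground mask,
   refreshed every ``reseed_interval`` frames and reused in between.
3. morphological cleanup and reduction to the single largest 8-connected
   component (single-actor assumption).

The cold-start convention: the first frame initializes the background
model and reports an all-background mask.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

__all__ = [
    "MoGParams",
    "BackgroundModel",
    "GraphCutParams",
    "refine_mask",
    "labeling_energy",
    "largest_component",
    "morphological_cleanup",
    "SilhouetteExtractor",
]

logger = logging.getLogger(__name__)

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclasses.dataclass
class MoGParams:
    """Mixture-of-Gaussians background model parameters."""

    n_components: int = 3
    learning_rate: float = 0.05
    match_threshold: float = 2.5   # standard deviations
    background_ratio: float = 0.7  # weight fraction deemed background
    initial_variance: float = 225.0
    min_variance: float = 4.0
    new_component_weight: float = 0.05


class BackgroundModel:
    """Online per-pixel MoG; call :meth:`update` once per frame in order."""

    def __init__(self, shape: tuple[int, int], params: MoGParams | None = None):
        self.params = params if params is not None else MoGParams()
        k = self.params.n_components
        self.shape = tuple(shape)
        self.weights = np.zeros((k,) + self.shape)
        self.means = np.zeros((k,) + self.shape)
        self.variances = np.full((k,) + self.shape, self.params.initial_variance)
        self._initialized = False

    def update(self, frame: np.ndarray) -> np.ndarray:
        """Adapt the model to one frame and return the raw foreground mask."""
        frame = np.asarray(frame, dtype=float)
        if frame.shape != self.shape:
            raise ValueError(f"frame shape {frame.shape} does not match model {self.shape}")
        p = self.params
        if not self._initialized:
            self.weights[0] = 1.0
            self.means[0] = frame
            self._initialized = True
            return np.zeros(self.shape, dtype=np.uint8)

        diff = frame[None] - self.means
        matched = diff**2 <= (p.match_threshold**2) * self.variances
        fitness = self.weights / np.sqrt(self.variances)
        fit_masked = np.where(matched, fitness, -np.inf)
        best = np.argmax(fit_masked, axis=0)          # (H, W)
        has_match = matched.any(axis=0)

        k = p.n_components
        one_hot = (np.arange(k)[:, None, None] == best[None]) & has_match[None]
        alpha = p.learning_rate
        self.weights = (1 - alpha) * self.weights + alpha * one_hot
        # adapt only the matched best component
        rho = alpha
        upd_diff = np.take_along_axis(diff, best[None], axis=0)[0]
        upd_var = np.take_along_axis(self.variances, best[None], axis=0)[0]
        new_mean = np.take_along_axis(self.means, best[None], axis=0)[0] + rho * upd_diff
        new_var = np.maximum(upd_var + rho * (upd_diff**2 - upd_var), p.min_variance)
        for arr, new in ((self.means, new_mean), (self.variances, new_var)):
            cur = np.take_along_axis(arr, best[None], axis=0)[0]
            np.put_along_axis(
                arr, best[None], np.where(has_match, new, cur)[None], axis=0
            )
        # replace the weakest component where nothing matched
        weakest = np.argmin(fitness, axis=0)
        replace = ~has_match
        if replace.any():
            sel = weakest[None]
            cur_m = np.take_along_axis(self.means, sel, axis=0)[0]
            cur_v = np.take_along_axis(self.variances, sel, axis=0)[0]
            cur_w = np.take_along_axis(self.weights, sel, axis=0)[0]
            np.put_along_axis(
                self.means, sel, np.where(replace, frame, cur_m)[None], axis=0
            )
            np.put_along_axis(
                self.variances, sel,
                np.where(replace, p.initial_variance, cur_v)[None], axis=0,
            )
            np.put_along_axis(
                self.weights, sel,
                np.where(replace, p.new_component_weight, cur_w)[None], axis=0,
            )
        self.weights /= self.weights.sum(axis=0, keepdims=True)

        # background = top-ranked components holding background_ratio of weight
        order = np.argsort(-fitness, axis=0)
        w_sorted = np.take_along_axis(self.weights, order, axis=0)
        cum = np.cumsum(w_sorted, axis=0)
        n_bg = np.argmax(cum >= p.background_ratio, axis=0) + 1  # per pixel
        rank_of = np.empty_like(order)
        np.put_along_axis(rank_of, order, np.arange(k)[:, None, None], axis=0)
        best_rank = np.take_along_axis(rank_of, best[None], axis=0)[0]
        matches_background = has_match & (best_rank < n_bg)
        return (~matches_background).astype(np.uint8)


@dataclasses.dataclass
class GraphCutParams:
    """Energy coefficients for the binary refinement cut."""

    lambda_c: float = 8.0       # pairwise contrast weight
    hard_weight: float = 1.0e4  # unary cost pinning seed cores
    erosion_radius: int = 2     # seed-core erosion (frames of certainty)
    max_unary: float = 50.0     # cap on -log likelihood terms
    scale: float = 100.0        # float -> integer capacity scale


def _seed_cores(seed_mask: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """High-confidence fg/bg cores: erosions of the seed mask and its complement."""
    seed = seed_mask.astype(bool)
    structure = np.ones((2 * radius + 1,) * 2, dtype=bool)
    fg_core = ndimage.binary_erosion(seed, structure=structure)
    bg_core = ndimage.binary_erosion(~seed, structure=structure)
    if not fg_core.any():
        fg_core = seed
    if not bg_core.any():
        bg_core = ~seed
    return fg_core, bg_core


def fit_intensity_models(
    frame: np.ndarray, seed_mask: np.ndarray, erosion_radius: int = 2
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Gaussian ``(mu, var)`` of the fg and bg seed-core intensities."""
    fg_core, bg_core = _seed_cores(np.asarray(seed_mask), erosion_radius)
    frame = np.asarray(frame, dtype=float)
    out = []
    for core in (fg_core, bg_core):
        vals = frame[core]
        out.append((float(vals.mean()), max(float(vals.var()), 1.0)))
    return out[0], out[1]


def _nll(frame: np.ndarray, model: tuple[float, float], cap: float) -> np.ndarray:
    mu, var = model
    nll = 0.5 * np.log(2 * np.pi * var) + (frame - mu) ** 2 / (2 * var)
    return np.minimum(nll, cap)


def _unary_terms(
    frame: np.ndarray,
    seed_mask: np.ndarray,
    params: GraphCutParams,
    models=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Costs (cost_fg, cost_bg) per pixel: likelihood terms + hard seed pins.

    ``models`` are the fg/bg Gaussian fits; by default they are fit to
    this frame's seed cores (correct for a fresh seed).
    """
    fg_core, bg_core = _seed_cores(seed_mask, params.erosion_radius)
    if models is None:
        models = fit_intensity_models(frame, seed_mask, params.erosion_radius)
    cost_fg = _nll(frame, models[0], params.max_unary)
    cost_bg = _nll(frame, models[1], params.max_unary)
    cost_fg = np.where(fg_core, 0.0, cost_fg)
    cost_bg = np.where(fg_core, params.hard_weight, cost_bg)
    cost_bg = np.where(bg_core, 0.0, cost_bg)
    cost_fg = np.where(bg_core, params.hard_weight, cost_fg)
    return cost_fg, cost_bg


def _pairwise_weights(frame: np.ndarray, lambda_c: float):
    """Contrast weights for vertical and horizontal 4-neighbor edges."""
    dv = np.diff(frame, axis=0) ** 2
    dh = np.diff(frame, axis=1) ** 2
    beta = max((dv.sum() + dh.sum()) / (dv.size + dh.size), 1e-6)
    return lambda_c * np.exp(-dv / (2 * beta)), lambda_c * np.exp(-dh / (2 * beta))


def labeling_energy(
    frame: np.ndarray,
    seed_mask: np.ndarray,
    labels: np.ndarray,
    params: GraphCutParams | None = None,
) -> float:
    """Unary + pairwise energy of a binary labeling under the cut's terms."""
    params = params if params is not None else GraphCutParams()
    frame = np.asarray(frame, dtype=float)
    lab = np.asarray(labels).astype(bool)
    cost_fg, cost_bg = _unary_terms(frame, seed_mask, params)
    w_v, w_h = _pairwise_weights(frame, params.lambda_c)
    energy = float(np.where(lab, cost_fg, cost_bg).sum())
    energy += float(w_v[lab[:-1, :] != lab[1:, :]].sum())
    energy += float(w_h[lab[:, :-1] != lab[:, 1:]].sum())
    return energy


def refine_mask(
    frame: np.ndarray,
    seed_mask: np.ndarray,
    params: GraphCutParams | None = None,
    current_mask: np.ndarray | None = None,
    models=None,
) -> np.ndarray:
    """Exact min-cut refinement of a seed foreground mask.

    Pixels in the eroded seed core (foreground and background) are
    pinned by hard unary terms; all others trade intensity likelihood
    against the contrast-weighted smoothness term. An empty seed mask or
    a degenerate one (all pixels one label after erosion) is returned
    unchanged with a warning.

    ``models`` are fg/bg intensity Gaussians, normally fit at seed
    capture time (see :func:`fit_intensity_models`); fit to this frame's
    seed cores when omitted. ``current_mask``, when given, is the
    background model's foreground mask for *this* frame: hard pins then
    apply only where the stored seed and the current mask agree, so a
    seed refreshed many frames ago cannot pin a region the person has
    since left — disagreeing pixels fall back to the likelihood terms.
    """
    params = params if params is not None else GraphCutParams()
    frame = np.asarray(frame, dtype=float)
    seed = np.asarray(seed_mask).astype(bool)
    if frame.shape != seed.shape:
        raise ValueError("frame and seed mask shapes differ")
    if not seed.any() or seed.all():
        logger.warning("degenerate seed mask (all one label); returning seeds unchanged")
        return seed.astype(np.uint8)

    h, w = frame.shape
    n = h * w
    if models is None:
        models = fit_intensity_models(frame, seed, params.erosion_radius)
    cost_fg, cost_bg = _unary_terms(frame, seed, params, models=models)
    if current_mask is not None:
        cur = np.asarray(current_mask).astype(bool)
        hard = (cost_fg >= params.hard_weight) | (cost_bg >= params.hard_weight)
        stale = hard & (cur != seed)
        if stale.any():
            cost_fg = np.where(stale, _nll(frame, models[0], params.max_unary), cost_fg)
            cost_bg = np.where(stale, _nll(frame, models[1], params.max_unary), cost_bg)
    w_v, w_h = _pairwise_weights(frame, params.lambda_c)

    scale = params.scale
    source, sink = n, n + 1
    idx = np.arange(n).reshape(h, w)

    rows_parts = []
    cols_parts = []
    caps_parts = []

    def add(r, c, cap):
        rows_parts.append(np.asarray(r).ravel())
        cols_parts.append(np.asarray(c).ravel())
        caps_parts.append(np.rint(np.asarray(cap).ravel() * scale).astype(np.int64))

    # terminal links: cut s->p paid when p is background, p->t when foreground
    add(np.full(n, source), idx, cost_bg)
    add(idx, np.full(n, sink), cost_fg)
    # symmetric neighbor links
    add(idx[:-1, :], idx[1:, :], w_v)
    add(idx[1:, :], idx[:-1, :], w_v)
    add(idx[:, :-1], idx[:, 1:], w_h)
    add(idx[:, 1:], idx[:, :-1], w_h)

    rows = np.concatenate(rows_parts)
    cols = np.concatenate(cols_parts)
    caps = np.concatenate(caps_parts)
    keep = caps > 0
    graph = sparse.csr_matrix(
        (caps[keep], (rows[keep], cols[keep])), shape=(n + 2, n + 2), dtype=np.int64
    )
    flow = maximum_flow(graph, source, sink).flow
    residual = graph - flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reachable = breadth_first_order(residual, source, return_predecessors=False)
    labels = np.zeros(n + 2, dtype=np.uint8)
    labels[reachable] = 1  # source side = foreground
    return labels[:n].reshape(h, w)


def morphological_cleanup(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Binary opening then closing with a square structuring element."""
    if radius <= 0:
        return np.asarray(mask, dtype=np.uint8)
    structure = np.ones((2 * radius + 1,) * 2, dtype=bool)
    m = np.asarray(mask).astype(bool)
    m = ndimage.binary_opening(m, structure=structure)
    m = ndimage.binary_closing(m, structure=structure)
    return m.astype(np.uint8)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected component; empty in, empty out.

    A size tie goes to the component containing the earliest pixel in
    raster (row-major) order.
    """
    m = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(m, structure=_EIGHT_CONNECTED)
    if n == 0:
        return np.zeros_like(m, dtype=np.uint8)
    sizes = np.bincount(labels.ravel())[1:]
    winners = np.nonzero(sizes == sizes.max())[0] + 1
    if winners.size > 1:
        flat = labels.ravel()
        first = min(int(np.argmax(flat == wlab)) for wlab in winners)
        keep = flat[first]
    else:
        keep = winners[0]
    return (labels == keep).astype(np.uint8)


class SilhouetteExtractor:
    """Stateful frame-by-frame pipeline: MoG -> graph cut -> cleanup -> largest blob.

    Graph-cut seeds are refreshed from the cleaned MoG mask every
    ``reseed_interval`` frames (frame 0 counts) and reused in between;
    an empty seed mask falls back to the raw MoG output for the frame.
    """

    def __init__(
        self,
        shape: tuple[int, int],
        mog_params: MoGParams | None = None,
        cut_params: GraphCutParams | None = None,
        reseed_interval: int = 100,
        cleanup_radius: int = 1,
        use_graph_cut: bool = True,
    ):
        self.model = BackgroundModel(shape, mog_params)
        self.cut_params = cut_params if cut_params is not None else GraphCutParams()
        self.reseed_interval = int(reseed_interval)
        self.cleanup_radius = int(cleanup_radius)
        self.use_graph_cut = use_graph_cut
        self._frame_no = 0
        self._seed_mask: np.ndarray | None = None
        self._seed_models = None

    def process(self, frame: np.ndarray) -> np.ndarray:
        """Silhouette mask for the next frame of the sequence."""
        frame_f = np.asarray(frame, dtype=float)
        raw = self.model.update(frame_f)
        if self._frame_no % self.reseed_interval == 0 or self._seed_mask is None:
            cleaned = morphological_cleanup(raw, self.cleanup_radius)
            if cleaned.any():
                self._seed_mask = cleaned
                self._seed_models = fit_intensity_models(
                    frame_f, cleaned, self.cut_params.erosion_radius
                )
        self._frame_no += 1
        if not self.use_graph_cut:
            refined = raw
        elif self._seed_mask is None or not self._seed_mask.any():
            refined = raw
        else:
            refined = refine_mask(
                frame_f,
                self._seed_mask,
                self.cut_params,
                current_mask=raw,
                models=self._seed_models,
            )
        refined = morphological_cleanup(refined, self.cleanup_radius)
        return largest_component(refined)
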