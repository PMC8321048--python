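# Methods

## The detection model

`fallwatch` treats a fall as an abrupt, sustained change in the shape
of a single person's silhouette. Three per-frame scalars carry the
signal, all computed on the largest connected component of the binary
silhouette in raster coordinates (x = column, y = row, y grows
downward):

* point distance `d = |y_VGP − y_c|`, the vertical distance between the
  silhouette centroid and the virtual grounding point (the point where
  the centroid's vertical line meets the bottom of the bounding box).
  Large while upright (roughly half the body height), near zero lying.
* area `a`, the foreground pixel count — a proxy for apparent body size,
  which grows when a person falls toward the camera and shrinks when
  they fall sideways or away (foreshortening).
* aspect ratio `r = w/h` of the tight bounding box — below 1 upright,
  above 1 lying.

A note on the grounding-point geometry: read literally, "the crossing
of the vertical line through x_c and the horizontal line through y_c"
is the centroid itself, which would make `d ≡ 0`. The implemented
convention — `VGP = (x_c, bottom-most foreground row)` — is the point
where the vertical center line meets the *ground side* of the object,
which is what the name suggests and what makes `d` a posture feature
(large standing, small lying). Centroids are kept sub-pixel; nothing is
rounded before `d` is formed.

### Change-period detection

Each feature series is smoothed with a centered moving average of
half-window `N` (window `2N + 1`); boundary windows are truncated to
the available frames and renormalized by the actual count, which keeps
the series length, reproduces constants exactly, and introduces no
phantom edge ramps. The *modified difference*

    MD(t) = S(t + N0 + N1) − S(t − N0 − N1),

with `S` the series smoothed at half-window `N1` and indices clamped to
the series ends, is a smoothed symmetric derivative: a step of height
`c` in the feature produces a triangular `MD` pulse of peak `≈ c` and
base `≈ 2(N0+N1)` frames. Defaults are `N = N1 = 51` and `N0 = 0` at
25 fps (about two seconds of smoothing); they are configuration values,
never hard-coded, and scale with the frame rate.

The dominant extremum of `MD` is taken per feature — the global
minimum for `d` (distance collapses in a fall), the global maximum for
`r` (ratio flips past 1), and for `a` both polarities are evaluated and
the larger magnitude kept, because the area's direction depends on the
fall direction; an exact tie goes to the maximum, and equal extreme
values go to the earliest frame. The event is then measured at half
level: walking outward from the extremum frame, the nearest crossings
of `MD` with half the extremum value (linear interpolation between
frames) give real-valued bounds `f1, f2` and the width
`v_hw = |f1 − f2|`; a side that never crosses before the series end is
clamped there with a warning.

Widths classify whole videos: `alpha1` = the smallest width among
fall-labelled training videos, `alpha2` = the largest among normal
ones, and the midpoint `PD = (alpha1 + alpha2)/2` is the per-feature
decision threshold (`v_hw ≥ PD` ⇒ fall video). The package classifies a
video by majority vote of the three per-feature rules, which buffers
the decision against a single feature's marginal width.

### The two-state HMM

Frames emit one of eight symbols: with `flag_X = 1` when the frame lies
inside feature X's event interval `[⌊f1⌋, ⌈f2⌉]` *and* that event's
width reaches `PD(X)`,

    o-index = 1 + 4(1 − flag_d) + 2(1 − flag_a) + (1 − flag_r),

so `o1` means all three features flag the frame and `o8` means none
does. This left-to-right leaf ordering makes the trained emission
matrix concentrate abnormal mass at `o1`/`o3` (fall detected on `d` and
`r`, with/without `a`) and normal mass at `o8`, matching the worked
example the estimators are tested against.

Training is supervised counting, not expectation–maximization:
transitions are the row-normalized co-occurrence counts of consecutive
ground-truth state pairs; emissions are per-state symbol frequencies.
The default pseudocount is 0, so structural zeros stay exact; a state
never observed gets a uniform row with a warning. The initial
distribution defaults to `π = (0.8, 0.2)`. Decoding is Viterbi in log
space with `log 0 = −∞` — zero probabilities are never smoothed
silently; ties break toward the abnormal state (lower index), and a
symbol with zero emission probability in both states raises an error
naming the frame rather than producing an arbitrary path.

Evaluation counts the four frame-level outcomes with abnormal as the
positive class and reports precision, recall, accuracy (correct frames
over all frames), specificity and NPV as percentages; undefined ratios
are NaN with a warning. An optional guard window drops false-abnormal
frames within a configurable distance of a true fall (a near-miss alarm
adjacent to a real fall arguably costs nothing in a care setting); it
is off by default and unused in all reported numbers.

## Silhouette extraction

The background model is the standard per-pixel online
Mixture-of-Gaussians: K = 3 components per pixel (weight, mean,
variance), matched at 2.5 standard deviations, learning rate 0.05,
unmatched values replacing the least plausible component, and the
top-ranked components holding 70% of the weight forming the background.
The first frame initializes the model and reports an all-background
mask (cold-start convention). Graph-cut refinement minimizes a binary
energy — hard unary pins at the eroded cores of the seed mask, Gaussian
intensity likelihoods (capped at 50 nats) elsewhere, pairwise weight
`λ_c·exp(−ΔI²/2β)` with `β` the mean squared neighbor difference and
`λ_c = 8` — solved exactly by max-flow/min-cut on integer-scaled
capacities (scale 100; the optimality guarantee therefore holds up to
one capacity quantum per term, which the energy regression test allows
for). Seeds refresh from the model's cleaned foreground mask every
`reseed_interval` frames (default 100) and are reused in between; the
fitted fg/bg intensity Gaussians are stored at seed time, and hard pins
are dropped wherever the stored seed disagrees with the current model
output, so a stale seed cannot pin a region the person has left.
Morphological opening/closing (3×3) precedes largest-8-connected-
component selection; a component-size tie keeps the component whose
first pixel comes earliest in raster order.

Frames with an empty silhouette get invalid features; gaps of at most
`interpolation_max_gap` frames (default 12, half a second) are filled
by linear interpolation, edge gaps from the nearest valid frame, and
longer interior gaps are excluded downstream (the analysis fills them
with the series median, which contributes no transition of its own).

## The synthetic scene generator

The generator emulates the kind of footage the method targets: a single
actor in a fixed-camera 320×240, 25 fps indoor scene, scripted as timed
actions (walk, stand, sit, lie, the slow transitions, and
sideways/forward/backward falls of at most 1.5 s). The actor is a
filled ellipse anchored to a floor row whose half-axes morph linearly
between posture keyframes — upright about 3× taller than wide (90×30 px
default), lying the reverse, sitting intermediate. Ground truth marks
fall-action frames S1; everything else, including lying after a fall,
is S2.

Two dynamics choices matter and are deliberate:

* **Gait sway.** Real walking silhouettes oscillate strongly (leg
  swing, vertical bob). Walking therefore modulates the body height by
  ±4% and the width by ±12% at a 2 Hz gait frequency, and standing
  keeps the same sway so that walk and stand segments have identical
  feature means. Without this the normal scenes' feature series would
  be nearly constant, and the modified difference would be dominated by
  rasterization-bias envelope bumps as wide as a fall pulse — an
  artifact of over-clean rendering, not a property of real footage.
* **Persistent area scale.** A fall ramps an apparent-size factor to a
  direction-dependent target (forward 1.35, sideways 0.75, backward
  0.7) that persists while the person lies on the ground and is only
  ramped back by a recovery transition. This reproduces the sustained
  area step of real falls (a transient pulse would leave the area's
  difference signal with equal positive and negative lobes and make its
  polarity meaningless).

Grayscale rendering adds a smooth textured background, a striped body
texture that moves with the actor, and additive Gaussian noise; all
randomness flows from a single seed and identical seeds give
bit-identical scenes.

What the generator does **not** emulate: occlusions, shadows,
illumination changes, multiple people, camera motion, or photoreal
appearance. Passing tests therefore demonstrate the correctness of the
statistical machinery under controlled geometry, not robustness to
those nuisances.

The evaluation study (`fallwatch.pipeline.run_synthetic_study`) uses 10
fall scenes (walk, a 0.6–1.2 s fall in a random direction, lying) and
10 normal scenes (alternating walking and standing spans), each about
100 s — the scale at which per-frame metrics are meaningful given the
detector's ~4 s temporal resolution. Slow sit/lie transitions are not
in the default normal mix: under two-second smoothing, any large
posture transition produces a difference pulse whose half-level width
is close to the smoothing span regardless of the transition's speed, so
the width criterion cannot reliably separate a slow sit from a fall.
This is a limitation of the width-threshold classifier itself (its
per-video accuracy on real footage is likewise imperfect), and the
study conditions state it rather than hide it. Training uses a
pseudocount of 1e-6 so a symbol unseen in training cannot make a
held-out sequence impossible; at the reported precision this changes no
counted probability.

## Temporal resolution and the interval-overlap ceiling

With `N0 = 0, N1 = 51`, the detected event interval `[f1, f2]` of a
genuine fall has width ≈ `2·N1 + 1 ≈ 103` frames: the half-level width
of the difference pulse is set by the smoothing span, not by the
event's true duration. A fall lasting at most 1.5 s (≤ 37 frames at
25 fps) is therefore localized — the extremum sits inside the true fall
— but its extent is overestimated by the smoothing span. Consequences:

* decoded abnormal intervals overlap the true fall frames with a
  Jaccard index of at most ≈ 37/103 ≈ 0.36 (measured ≈ 0.22–0.27), an
  architectural ceiling of the method's published smoothing constants;
* frame-level precision is low (≈ 22–26% in the study) even when every
  true fall frame is recovered, because the ~100-frame alarm interval
  surrounds a ≤ 37-frame event; recall, NPV (both 100% in the study)
  and specificity/accuracy (≈ 98–99% on 100 s scenes) are the
  informative metrics at this resolution.

Shrinking `N1` would sharpen the intervals but weaken the width-based
video classifier that depends on the same constant; the package keeps
the published values as defaults and exposes both in the configuration.

## Numerical choices

* Moving-average boundaries: truncated, renormalized windows.
* Difference boundaries: clamped indices; series shorter than
  `2(N0+N1)+1` are rejected.
* Half-level crossings: nearest crossing on each side of the extremum,
  linear interpolation, clamped at the series ends with a warning.
* Emission/transition zero rows: uniform with a warning (never silent).
* Mask IO binarizes on read (any nonzero → 1); feature CSVs round-trip
  to 1e-6; model JSON stores A, B, π, thresholds and a symbol-encoding
  version tag that is checked on load.
* Video containers are not read directly; frames are image sequences
  (PNG/JPEG). Frame indexing is 0-based everywhere, including label
  files.
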