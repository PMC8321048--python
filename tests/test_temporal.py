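"""Moving average, modified difference, half-width, and the width classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fallwatch import synthgen, temporal
from fallwatch.config import RunConfig
from fallwatch.features import extract_feature_series


def ma_reference(x, n):
    """Windowed mean by direct enumeration (truncated, renormalized)."""
    out = []
    for t in range(len(x)):
        lo, hi = max(t - n, 0), min(t + n, len(x) - 1)
        out.append(sum(x[lo : hi + 1]) / (hi - lo + 1))
    return np.array(out)


def md_reference(x, n0, n1):
    """Modified difference by direct enumeration with clamped indices."""
    s = ma_reference(x, n1)
    span = n0 + n1
    return np.array(
        [s[min(t + span, len(x) - 1)] - s[max(t - span, 0)] for t in range(len(x))]
    )


finite_series = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=7, max_size=40
).map(np.array)


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        assert temporal.moving_average(np.full(30, 7.0), 5) == pytest.approx(np.full(30, 7.0))

    def test_small_example(self):
        out = temporal.moving_average(np.array([1.0, 2, 3, 4, 5]), 1)
        assert out[2] == pytest.approx(3.0)  # (2+3+4)/3
        assert out == pytest.approx([1.5, 2, 3, 4, 4.5])

    def test_linear_ramp_interior_is_ramp(self):
        x = 2.5 * np.arange(50)
        out = temporal.moving_average(x, 4)
        assert out[4:-4] == pytest.approx(x[4:-4])

    def test_zero_window_is_identity(self):
        x = np.array([3.0, 1.0, 4.0])
        assert temporal.moving_average(x, 0) == pytest.approx(x)

    @settings(deadline=None, max_examples=60)
    @given(x=finite_series, n=st.integers(0, 6))
    def test_matches_enumeration(self, x, n):
        assert temporal.moving_average(x, n) == pytest.approx(ma_reference(x, n))

    @settings(deadline=None, max_examples=30)
    @given(
        x=finite_series, n=st.integers(0, 4),
        a=st.floats(-3, 3, allow_nan=False), b=st.floats(-3, 3, allow_nan=False),
    )
    def test_linearity(self, x, n, a, b):
        y = np.cos(np.arange(x.size))
        lhs = temporal.moving_average(a * x + b * y, n)
        rhs = a * temporal.moving_average(x, n) + b * temporal.moving_average(y, n)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            temporal.moving_average(np.array([]), 2)


class TestModifiedDifference:
    def test_constant_is_zero(self):
        assert temporal.modified_difference(np.full(20, 4.2), 0, 3) == pytest.approx(0.0)

    def test_unit_ramp_interior(self):
        md = temporal.modified_difference(np.arange(30, dtype=float), 0, 1)
        assert md[2:-2] == pytest.approx(2.0)  # (t+1) - (t-1)

    def test_step_max_equals_height(self):
        t0, c = 40, 6.5
        x = np.where(np.arange(100) >= t0, c, 0.0)
        md = temporal.modified_difference(x, 0, 5)
        ref = md_reference(x, 0, 5)
        assert md == pytest.approx(ref)
        assert md.max() == pytest.approx(ref.max())
        assert abs(int(np.argmax(md)) - t0) <= 1
        assert md.max() == pytest.approx(c * (1 - 1 / 11))  # one shared sample at t0

    @settings(deadline=None, max_examples=60)
    @given(x=finite_series, n0=st.integers(0, 2), n1=st.integers(1, 3))
    def test_matches_enumeration(self, x, n0, n1):
        if x.size < 2 * (n0 + n1) + 1:
            x = np.resize(x, 2 * (n0 + n1) + 1)
        assert temporal.modified_difference(x, n0, n1) == pytest.approx(
            md_reference(x, n0, n1)
        )

    @settings(deadline=None, max_examples=40)
    @given(x=finite_series, n1=st.integers(1, 3))
    def test_time_reversal_antisymmetry(self, x, n1):
        if x.size < 2 * n1 + 1:
            x = np.resize(x, 2 * n1 + 1)
        fwd = temporal.modified_difference(x, 0, n1)
        rev = temporal.modified_difference(x[::-1], 0, n1)
        assert fwd == pytest.approx(-rev[::-1], abs=1e-9)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError, match="too short"):
            temporal.modified_difference(np.arange(4, dtype=float), 0, 2)


TRIANGLE = np.array([0, 1, 2, 3, 4, 5, 4, 3, 2, 1, 0], dtype=float)


class TestExtremaAndHalfWidth:
    def test_unique_maximum(self):
        e = temporal.find_extremum(TRIANGLE, "max")
        assert (e.frame, e.value) == (5, 5.0)

    def test_all_zero_gives_none(self):
        assert temporal.find_extremum(np.zeros(10), "max") is None

    def test_tie_breaks_to_earlier_frame(self):
        md = np.array([0.0, 3.0, 1.0, 3.0, 0.0])
        assert temporal.find_extremum(md, "max").frame == 1

    def test_triangle_fwhm(self):
        e = temporal.half_width(TRIANGLE, temporal.find_extremum(TRIANGLE, "max"))
        assert (e.f1, e.f2, e.v_hw) == pytest.approx((2.5, 7.5, 5.0))

    @pytest.mark.parametrize("width", [3, 7, 15])
    def test_rectangular_pulse_width(self, width):
        md = np.zeros(60)
        md[20 : 20 + width] = 4.0
        e = temporal.half_width(md, temporal.find_extremum(md, "max"))
        assert abs(e.v_hw - width) <= 1.0

    def test_minimum_polarity_symmetric_arms(self):
        md = -TRIANGLE
        e = temporal.half_width(md, temporal.find_extremum(md, "min"))
        assert e.frame - e.f1 == pytest.approx(e.f2 - e.frame)
        assert e.v_hw == pytest.approx(5.0)

    @settings(deadline=None, max_examples=40)
    @given(scale=st.floats(0.01, 50, allow_nan=False))
    def test_width_invariant_under_positive_scaling(self, scale):
        e1 = temporal.half_width(TRIANGLE, temporal.find_extremum(TRIANGLE, "max"))
        scaled = scale * TRIANGLE
        e2 = temporal.half_width(scaled, temporal.find_extremum(scaled, "max"))
        assert e2.v_hw == pytest.approx(e1.v_hw)

    def test_monotone_flank_clamps_to_series_end(self):
        md = np.arange(10, dtype=float)  # max at the last frame
        e = temporal.half_width(md, temporal.find_extremum(md, "max"))
        assert e.f2 == pytest.approx(9.0)


class TestPeriodThresholds:
    WIDTHS = {
        "v1": {"d": 30.0, "a": 30.0, "r": 30.0},
        "v2": {"d": 35.0, "a": 35.0, "r": 35.0},
        "v3": {"d": 18.0, "a": 18.0, "r": 18.0},
        "v4": {"d": 20.0, "a": 20.0, "r": 20.0},
    }
    LABELS = {"v1": "l1", "v2": "l1", "v3": "l2", "v4": "l2"}

    def test_midpoint_thresholds(self):
        th = temporal.learn_period_thresholds(self.WIDTHS, self.LABELS)
        assert th.alpha1["d"] == 30.0
        assert th.alpha2["d"] == 20.0
        assert th.pd["d"] == 25.0

    def test_classification_rule(self):
        assert temporal.classify_width(26.0, 25.0) == "l1"
        assert temporal.classify_width(25.0, 25.0) == "l1"  # >= is a fall
        assert temporal.classify_width(24.0, 25.0) == "l2"

    def test_missing_class_raises(self):
        with pytest.raises(ValueError, match="l1"):
            temporal.learn_period_thresholds(
                {"v3": self.WIDTHS["v3"]}, {"v3": "l2"}
            )

    def test_separated_widths_give_perfect_leave_one_out(self):
        rng = np.random.default_rng(5)
        falls = 30 + 10 * rng.random(8)    # widths strictly above normals
        normals = 5 + 10 * rng.random(8)
        videos = {f"f{i}": {"d": w, "a": w, "r": w} for i, w in enumerate(falls)}
        videos |= {f"n{i}": {"d": w, "a": w, "r": w} for i, w in enumerate(normals)}
        labels = {v: ("l1" if v.startswith("f") else "l2") for v in videos}
        hits = 0
        for held in videos:
            th = temporal.learn_period_thresholds(
                {v: w for v, w in videos.items() if v != held},
                {v: c for v, c in labels.items() if v != held},
            )
            hits += temporal.classify_video(videos[held], th) == labels[held]
        assert hits == len(videos)


@pytest.fixture(scope="module")
def fall_scene_analysis():
    scene = synthgen.generate_scene(
        [synthgen.Action("walk", 10.0), synthgen.Action("fall_sideways", 0.8),
         synthgen.Action("lie", 10.0)],
        synthgen.SceneConfig(seed=11),
    )
    table = extract_feature_series(scene.masks)
    return scene, temporal.analyze_video(table, RunConfig())


class TestAnalyzeVideo:
    def test_fall_polarities(self, fall_scene_analysis):
        scene, analysis = fall_scene_analysis
        assert analysis.events["d"].polarity == "min"
        assert analysis.events["r"].polarity == "max"
        lo, hi = scene.fall_intervals[0]
        # the extremum localizes the transition to within the smoothing span
        for feat in ("d", "r"):
            assert lo - 55 <= analysis.events[feat].frame <= hi + 55

    def test_forward_fall_area_maximum(self):
        scene = synthgen.generate_scene(
            [synthgen.Action("walk", 8.0), synthgen.Action("fall_forward", 0.8),
             synthgen.Action("lie", 8.0)],
            synthgen.SceneConfig(seed=12),
        )
        analysis = temporal.analyze_video(extract_feature_series(scene.masks), RunConfig())
        assert analysis.events["a"].polarity == "max"

    def test_sideways_fall_area_minimum(self, fall_scene_analysis):
        _, analysis = fall_scene_analysis
        assert analysis.events["a"].polarity == "min"
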