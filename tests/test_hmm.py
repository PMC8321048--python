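"""Two-state HMM: symbolization, counting estimators, Viterbi, evaluation."""

import numpy as np
import pytest

from fallwatch import hmm
from fallwatch.synthgen import sample_hmm
from fallwatch.temporal import ExtremumEvent, PeriodThresholds

# worked model printed for the "single monitored person" example sequence
A_PRINTED = np.array([[0.07229, 0.92771], [0.07229, 0.92771]])
B_PRINTED = np.array(
    [
        [0.75, 0, 0.25, 0, 0, 0, 0, 0],
        [0.020672, 0.062016, 0.015504, 0, 0, 0.069767, 0.054264, 0.777778],
    ]
)
PI = np.array([0.8, 0.2])


def thresholds(pd_d=10.0, pd_a=10.0, pd_r=10.0):
    return PeriodThresholds(
        alpha1={"d": 0, "a": 0, "r": 0},
        alpha2={"d": 0, "a": 0, "r": 0},
        pd={"d": pd_d, "a": pd_a, "r": pd_r},
    )


def event(f1, f2):
    e = ExtremumEvent(polarity="max", frame=int((f1 + f2) / 2), value=1.0)
    return e.with_width(f1, f2)


class TestSymbolize:
    def test_no_events_all_o8(self):
        seq = hmm.symbolize({"d": None, "a": None, "r": None}, thresholds(), 6)
        assert (seq.symbols == 7).all()  # o8

    def test_all_flags_give_o1(self):
        ev = {"d": event(2, 20), "a": event(2, 20), "r": event(2, 20)}
        seq = hmm.symbolize(ev, thresholds(), 30)
        assert seq.symbols[5] == 0  # o1
        assert seq.symbols[25] == 7

    def test_d_and_r_without_a_give_o3(self):
        ev = {"d": event(2, 20), "a": None, "r": event(2, 20)}
        seq = hmm.symbolize(ev, thresholds(), 30)
        assert seq.symbols[10] == 2  # o3

    def test_narrow_event_below_threshold_flags_nothing(self):
        ev = {"d": event(2, 6), "a": None, "r": None}  # v_hw = 4 < PD = 10
        seq = hmm.symbolize(ev, thresholds(), 30)
        assert (seq.symbols == 7).all()

    def test_interval_bounds_rounded_outward(self):
        ev = {"d": event(2.6, 20.2), "a": None, "r": None}
        seq = hmm.symbolize(ev, thresholds(), 30)
        flagged = np.nonzero(seq.flags[:, 0])[0]
        assert flagged[0] == 2 and flagged[-1] == 21

    def test_bad_frame_count_raises(self):
        with pytest.raises(ValueError):
            hmm.symbolize({"d": None, "a": None, "r": None}, thresholds(), 0)


class TestCountingEstimators:
    @pytest.mark.parametrize(
        "states, expected",
        [
            ([0, 0, 1], [[1, 1], [0, 0]]),
            ([0, 1, 0, 1, 0], [[0, 2], [2, 0]]),
            ([1] * 6, [[0, 0], [0, 5]]),
        ],
    )
    def test_cooccurrence_pairs(self, states, expected):
        assert hmm.count_cooccurrences(np.array(states)).tolist() == expected

    def test_cooccurrence_needs_two_frames(self):
        with pytest.raises(ValueError):
            hmm.count_cooccurrences(np.array([0]))

    def test_transition_matrix_from_printed_counts(self):
        a = hmm.transition_matrix(np.array([[900, 11550], [11550, 148225]]))
        assert np.round(a, 5).tolist() == A_PRINTED.tolist()

    def test_transition_matrix_identity_and_uniform(self):
        assert hmm.transition_matrix(np.array([[5, 0], [0, 7]])).tolist() == [[1, 0], [0, 1]]
        assert hmm.transition_matrix(np.ones((2, 2))).tolist() == [[0.5, 0.5], [0.5, 0.5]]

    def test_emission_printed_first_row(self):
        b = hmm.emission_matrix(np.zeros(4, dtype=int), np.array([0, 0, 2, 0]))
        assert b[0].tolist() == [0.75, 0, 0.25, 0, 0, 0, 0, 0]

    def test_emission_single_symbol(self):
        b = hmm.emission_matrix(np.ones(5, dtype=int), np.full(5, 7))
        assert b[1, 7] == 1.0

    def test_emission_rows_sum_to_one_with_pseudocount(self):
        rng = np.random.default_rng(0)
        for pc in (0.0, 0.5, 3.0):
            s = rng.integers(0, 2, 200)
            o = rng.integers(0, 8, 200)
            b = hmm.emission_matrix(s, o, pseudocount=pc)
            assert b.sum(axis=1) == pytest.approx([1.0, 1.0])

    def test_emission_uniform_symbols_law_of_large_numbers(self):
        rng = np.random.default_rng(1)
        o = rng.integers(0, 8, 8000)
        b = hmm.emission_matrix(np.zeros(8000, dtype=int), o)
        assert b[0] == pytest.approx(np.full(8, 1 / 8), abs=0.02)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            hmm.emission_matrix(np.zeros(4, dtype=int), np.zeros(5, dtype=int))

    def test_transition_recovery_within_three_standard_errors(self):
        model = hmm.HMMModel(A_PRINTED, B_PRINTED, PI)
        states, _ = sample_hmm(model, 10_000, seed=123)
        a_hat = hmm.transition_matrix(hmm.count_cooccurrences(states))
        row_n = np.bincount(states[:-1], minlength=2)
        for i in range(2):
            for j in range(2):
                se = np.sqrt(A_PRINTED[i, j] * (1 - A_PRINTED[i, j]) / row_n[i])
                assert abs(a_hat[i, j] - A_PRINTED[i, j]) <= 3 * se


def brute_force_viterbi(symbols, model):
    """Exhaustive argmax over all 2^T paths; ties to the lexicographically first."""
    from itertools import product

    best, best_p = None, -1.0
    for path in product((0, 1), repeat=len(symbols)):
        p = model.initial[path[0]] * model.emissions[path[0], symbols[0]]
        for t in range(1, len(symbols)):
            p *= model.transitions[path[t - 1], path[t]] * model.emissions[path[t], symbols[t]]
        if p > best_p:
            best, best_p = path, p
    return np.array(best), best_p


class TestViterbi:
    def test_deterministic_emissions_force_path(self):
        b = np.zeros((2, 8))
        b[0, 0] = b[1, 1] = 1.0
        model = hmm.HMMModel(np.eye(2) * 0.99 + 0.005, b, [0.5, 0.5])
        o = np.array([0, 0, 1, 1, 0])
        assert hmm.viterbi(o, model).tolist() == [0, 0, 1, 1, 0]

    def test_zero_abnormal_emission_for_o8_forces_normal(self):
        model = hmm.HMMModel(A_PRINTED, B_PRINTED, PI)
        path = hmm.viterbi(np.full(50, 7), model)
        assert (path == 1).all()

    def test_impossible_symbol_names_frame(self):
        b = np.zeros((2, 8))
        b[0, 0] = b[1, 0] = 1.0  # only o1 can ever be emitted
        model = hmm.HMMModel(np.full((2, 2), 0.5), b, [0.5, 0.5])
        with pytest.raises(ValueError, match="frame 3"):
            hmm.viterbi(np.array([0, 0, 0, 5]), model)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            a = rng.dirichlet(np.ones(2), size=2)
            b = rng.dirichlet(np.ones(8) * rng.uniform(0.2, 2), size=2)
            pi = rng.dirichlet(np.ones(2))
            model = hmm.HMMModel(a, b, pi)
            t_len = int(rng.integers(1, 13))
            o = rng.integers(0, 8, t_len)
            path = hmm.viterbi(o, model)
            ref, ref_p = brute_force_viterbi(o, model)
            p = model.initial[path[0]] * model.emissions[path[0], o[0]]
            for t in range(1, t_len):
                p *= model.transitions[path[t - 1], path[t]] * model.emissions[path[t], o[t]]
            assert p == pytest.approx(ref_p, rel=1e-9)

    def test_agrees_with_hmmlearn_decoder(self):
        pytest.importorskip("hmmlearn")
        from hmmlearn.hmm import CategoricalHMM

        model = hmm.HMMModel(A_PRINTED, B_PRINTED, PI)
        _, symbols = sample_hmm(model, 300, seed=7)
        ref = CategoricalHMM(n_components=2)
        ref.startprob_ = PI.copy()
        ref.transmat_ = A_PRINTED.copy()
        ref.emissionprob_ = B_PRINTED.copy()
        expected = ref.predict(symbols.reshape(-1, 1))
        assert hmm.viterbi(symbols, model).tolist() == expected.tolist()


class TestEvaluate:
    def test_confusion_arithmetic(self):
        truth = np.array([0] * 10 + [1] * 90)
        pred = truth.copy()
        pred[9] = 1  # one missed fall frame
        counts, m = hmm.evaluate(pred, truth)
        assert (counts.as1, counts.as2, counts.ns1, counts.ns2) == (9, 1, 90, 0)
        assert m["precision"] == pytest.approx(100.0)
        assert m["recall"] == pytest.approx(90.0)
        assert m["accuracy"] == pytest.approx(99.0)
        assert m["specificity"] == pytest.approx(100.0)
        assert m["npv"] == pytest.approx(100 * 90 / 91)

    def test_perfect_agreement(self):
        x = np.array([0, 1, 1, 0, 1])
        _, m = hmm.evaluate(x, x)
        assert all(v == pytest.approx(100.0) for v in m.values())

    def test_degenerate_all_normal(self):
        x = np.ones(10, dtype=int)
        _, m = hmm.evaluate(x, x)
        assert np.isnan(m["recall"])
        assert m["specificity"] == pytest.approx(100.0)

    def test_guard_window_excludes_adjacent_false_alarms(self):
        truth = np.ones(30, dtype=int)
        truth[10:13] = 0
        pred = np.ones(30, dtype=int)
        pred[8:15] = 0  # alarm spills 2 frames each side of the true fall
        strict_counts, strict = hmm.evaluate(pred, truth)
        lenient_counts, lenient = hmm.evaluate(pred, truth, guard_frames=2)
        assert strict_counts.ns2 == 4 and strict["precision"] < 100
        assert lenient_counts.ns2 == 0 and lenient["precision"] == pytest.approx(100.0)

    def test_length_mismatch_and_empty_raise(self):
        with pytest.raises(ValueError):
            hmm.evaluate(np.array([0]), np.array([0, 1]))
        with pytest.raises(ValueError):
            hmm.evaluate(np.array([]), np.array([]))
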