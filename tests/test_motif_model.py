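import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corescan import (
    MotifModelError,
    Pwm,
    background_from_gc,
    motif_score_quantile,
    pwm_from_consensus,
    read_pwm,
    score_window,
    to_scoring_matrix,
    write_pwm,
)

UNIFORM = background_from_gc(0.5)


class TestBackground:
    @pytest.mark.parametrize(
        "gc,expected",
        [
            (0.5, {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}),
            (0.6, {"A": 0.2, "C": 0.3, "G": 0.3, "T": 0.2}),
        ],
    )
    def test_formulas(self, gc, expected):
        bg = background_from_gc(gc)
        for nt, p in expected.items():
            assert bg.p[nt] == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("gc", [0.0, 1.0, -0.1, 1.5, float("nan")])
    def test_degenerate_gc_rejected(self, gc):
        with pytest.raises(MotifModelError):
            background_from_gc(gc)

    @given(gc=st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=50, derandomize=True)
    def test_gc_split_in_half(self, gc):
        bg = background_from_gc(gc)
        assert bg.p["G"] == bg.p["C"] == gc / 2
        assert bg.p["A"] == bg.p["T"] == (1 - gc) / 2
        assert sum(bg.p.values()) == pytest.approx(1.0, abs=1e-12)


class TestPwmValidation:
    def test_column_not_summing_to_one(self):
        probs = np.full((4, 3), 0.25)
        probs[0, 1] = 0.2  # column 2 sums to 0.95
        with pytest.raises(MotifModelError, match="column 2"):
            Pwm(name="bad", probs=probs)

    def test_negative_probability(self):
        probs = np.array([[1.2], [-0.2], [0.0], [0.0]])
        with pytest.raises(MotifModelError, match="negative"):
            Pwm(name="bad", probs=probs)

    def test_anchor_offset_bounds(self):
        probs = np.full((4, 2), 0.25)
        with pytest.raises(MotifModelError, match="anchor_offset"):
            Pwm(name="bad", probs=probs, anchor_offset=2)

    def test_consensus_is_columnwise_argmax(self):
        pwm = pwm_from_consensus("x", "TCAGTY")
        assert pwm.consensus == "TCAGTC"  # Y profile favours C on the A<C<G<T tie rule


class TestScoringMatrix:
    def test_log2_ratios_single_column(self):
        pwm = Pwm(name="c1", probs=np.array([[0.5], [0.25], [0.125], [0.125]]))
        sm = to_scoring_matrix(pwm, UNIFORM, pseudocount=0.0)
        np.testing.assert_allclose(sm.scores[:, 0], [1.0, 0.0, -1.0, -1.0], atol=1e-12)
        assert sm.max_score == pytest.approx(1.0)

    def test_uniform_column_scores_zero(self):
        pwm = Pwm(name="u", probs=np.full((4, 3), 0.25))
        sm = to_scoring_matrix(pwm, UNIFORM, pseudocount=0.0)
        np.testing.assert_allclose(sm.scores, 0.0, atol=1e-12)

    def test_two_column_hand_table_gc04(self, two_col_pwm):
        # independent recomputation: log2 of each probability over the
        # GC=0.4 background (A/T: 0.3, C/G: 0.2), cell by cell
        bg = background_from_gc(0.4)
        sm = to_scoring_matrix(two_col_pwm, bg, pseudocount=0.0)
        expected = [
            [math.log2(0.5 / 0.3), math.log2(0.1 / 0.3)],
            [math.log2(0.25 / 0.2), math.log2(0.2 / 0.2)],
            [math.log2(0.125 / 0.2), math.log2(0.3 / 0.2)],
            [math.log2(0.125 / 0.3), math.log2(0.4 / 0.3)],
        ]
        np.testing.assert_allclose(sm.scores, expected, atol=1e-12)

    def test_uniform_background_identity(self, two_col_pwm):
        # at GC 0.5 every background probability is 1/4, so the scoring
        # matrix collapses to log2(4 P) cell-wise
        sm = to_scoring_matrix(two_col_pwm, UNIFORM, pseudocount=0.0)
        np.testing.assert_allclose(sm.scores, np.log2(4.0 * two_col_pwm.probs), atol=1e-12)

    def test_zero_probability_needs_pseudocount(self):
        pwm = Pwm(name="z", probs=np.array([[1.0], [0.0], [0.0], [0.0]]))
        with pytest.raises(MotifModelError, match="pseudocount"):
            to_scoring_matrix(pwm, UNIFORM, pseudocount=0.0)
        sm = to_scoring_matrix(pwm, UNIFORM, pseudocount=1e-3)
        assert np.isfinite(sm.scores).all()

    def test_gc_monotonicity(self, two_col_pwm):
        # raising GC inflates the G/C background, deflating G/C scores, and
        # symmetrically inflates A/T scores
        gcs = [0.2, 0.35, 0.5, 0.65, 0.8]
        mats = [to_scoring_matrix(two_col_pwm, background_from_gc(g)) for g in gcs]
        for lo, hi in zip(mats, mats[1:]):
            assert np.all(hi.scores[[1, 2], :] < lo.scores[[1, 2], :])  # C, G
            assert np.all(hi.scores[[0, 3], :] > lo.scores[[0, 3], :])  # A, T

    def test_cutoff_above_max_warns(self):
        pwm = pwm_from_consensus("w", "ACGT", cutoff=100.0)
        with pytest.warns(UserWarning, match="never be reported"):
            to_scoring_matrix(pwm, UNIFORM)


class TestScoreWindow:
    def test_consensus_scores_max(self, default_library):
        for el in default_library:
            sm = to_scoring_matrix(el.pwm, UNIFORM)
            assert score_window(sm, sm.consensus) == pytest.approx(sm.max_score, abs=1e-9)

    def test_manual_cell_lookup(self, two_col_pwm):
        sm = to_scoring_matrix(two_col_pwm, background_from_gc(0.4), pseudocount=0.0)
        assert score_window(sm, "AC") == pytest.approx(
            sm.scores[0, 0] + sm.scores[1, 1], abs=1e-12
        )

    def test_all_n_window_scores_column_minima(self, two_col_pwm):
        sm = to_scoring_matrix(two_col_pwm, UNIFORM)
        assert score_window(sm, "NN") == pytest.approx(sm.column_min.sum(), abs=1e-12)

    def test_consensus_dominates_all_windows(self):
        # exhaustive over all 256 windows of a 4-column matrix
        rng = np.random.default_rng(11)
        probs = rng.dirichlet(np.ones(4), size=4).T
        sm = to_scoring_matrix(Pwm(name="r4", probs=probs), UNIFORM)
        best = score_window(sm, sm.consensus)
        for i in range(256):
            w = "".join("ACGT"[(i >> (2 * j)) & 3] for j in range(4))
            assert score_window(sm, w) <= best + 1e-12

    @pytest.mark.parametrize("window,err", [("A", "length"), ("AX", "invalid character")])
    def test_invalid_windows(self, two_col_pwm, window, err):
        sm = to_scoring_matrix(two_col_pwm, UNIFORM)
        with pytest.raises(MotifModelError, match=err):
            score_window(sm, window)


class TestPwmFileRoundTrip:
    def test_round_trip_bit_exact(self, tmp_path, default_library):
        for el in default_library:
            p1 = tmp_path / f"{el.name}.pwm"
            p2 = tmp_path / f"{el.name}.again.pwm"
            write_pwm(el.pwm, p1, extra_meta={"category": el.category})
            pwm2, meta = read_pwm(p1)
            write_pwm(pwm2, p2, extra_meta=meta)
            assert p1.read_text() == p2.read_text()
            assert pwm2.anchor_offset == el.pwm.anchor_offset
            assert pwm2.cutoff == el.pwm.cutoff
            np.testing.assert_allclose(pwm2.probs, el.pwm.probs, atol=5e-7)

    def test_malformed_header_named(self, tmp_path):
        bad = tmp_path / "bad.pwm"
        bad.write_text("A\t0.25\n")
        with pytest.raises(MotifModelError, match="header"):
            read_pwm(bad)


class TestMotifScoreQuantile:
    def test_matches_monte_carlo(self):
        pwm = pwm_from_consensus("q", "TCAGTY")
        rng = np.random.default_rng(5)
        sm = to_scoring_matrix(pwm, UNIFORM)
        draws = []
        for _ in range(20000):
            idx = [rng.choice(4, p=pwm.probs[:, j]) for j in range(pwm.length)]
            draws.append(sum(sm.scores[i, j] for j, i in enumerate(idx)))
        for q in (0.05, 0.5):
            exact = motif_score_quantile(pwm, UNIFORM, q=q)
            mc = float(np.quantile(draws, q))
            assert exact == pytest.approx(mc, abs=0.3)
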