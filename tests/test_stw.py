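import numpy as np
import pytest
from hypothesis import given, strategies as st

from engfeat.features_td import l2_normalize
from engfeat.preprocess import WindowSet
from engfeat.stw import (STWConfig, STWState, derivative_streams, dtw_distance,
                         run_stw_framework, stw_feature_count, stw_raw_vector,
                         stw_step)


def dtw_brute_force(s, t, squared=False):
    """Exhaustive minimum over all monotone warping paths (independent of
    the dynamic-programming implementation; depth-first with exact pruning)."""
    n, m = len(s), len(t)
    best = [float("inf")]

    def cost(i, j):
        d = s[i] - t[j]
        return d * d if squared else abs(d)

    def walk(i, j, acc):
        acc += cost(i, j)
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


short_seq = st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=6)


class TestDTW:
    def test_identity_alignment_costs_zero(self, rng):
        x = rng.standard_normal(20)
        assert dtw_distance(x, x) == 0.0

    def test_forced_arithmetic_examples(self):
        assert dtw_distance([0.0, 0.0], [1.0, 1.0]) == pytest.approx(2.0)
        assert dtw_distance([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]) == pytest.approx(2.0)

    def test_squared_cost_option(self):
        cfg = STWConfig(dtw_cost="squared")
        assert dtw_distance([0.0], [2.0], cfg) == pytest.approx(4.0)

    def test_matches_brute_force_on_seeded_suite(self, rng):
        # >= 200 random short pairs against exhaustive path enumeration
        for _ in range(220):
            n, m = rng.integers(1, 7, size=2)
            s = rng.standard_normal(n)
            t = rng.standard_normal(m)
            assert dtw_distance(s, t) == pytest.approx(dtw_brute_force(s, t),
                                                       rel=1e-12, abs=1e-12)

    @given(short_seq, short_seq)
    def test_symmetric_and_nonnegative(self, s, t):
        d1 = dtw_distance(s, t)
        assert d1 >= 0.0
        assert d1 == pytest.approx(dtw_distance(t, s), rel=1e-12, abs=1e-12)

    def test_band_constrained_cost_dominates_unconstrained(self, rng):
        s, t = rng.standard_normal(30), rng.standard_normal(30)
        full = dtw_distance(s, t)
        banded = dtw_distance(s, t, STWConfig(dtw_band=3))
        wide = dtw_distance(s, t, STWConfig(dtw_band=60))
        assert banded >= full - 1e-12
        assert wide == pytest.approx(full, rel=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])


class TestDerivativeStreams:
    def test_linear_ramp(self):
        d0, d1, d2 = derivative_streams(np.arange(5.0))
        assert np.all(d1 == 1.0) and np.all(d2 == 0.0)

    def test_constant(self):
        _, d1, d2 = derivative_streams(np.full(4, 3.0))
        assert np.all(d1 == 0.0) and np.all(d2 == 0.0)

    def test_forced_arithmetic(self):
        d0, d1, d2 = derivative_streams([1.0, 4.0, 9.0])
        np.testing.assert_array_equal(d1, [3.0, 5.0])
        np.testing.assert_array_equal(d2, [2.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            derivative_streams([1.0, 2.0])


class TestFeatureCount:
    @pytest.mark.parametrize("nc,expected", [(16, 360), (2, 3), (3, 9)])
    def test_count_formula(self, nc, expected):
        assert stw_feature_count(nc) == expected

    def test_formula_for_all_channel_counts(self):
        for nc in range(2, 17):
            assert stw_feature_count(nc) == nc * (nc - 1) // 2 * 3

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            stw_feature_count(1)


class TestRawVector:
    def test_identical_channels_give_all_zeros(self):
        block = np.tile(np.sin(np.arange(10.0)), (4, 1))
        np.testing.assert_allclose(stw_raw_vector(block), 0.0)

    def test_16_channels_give_360_features(self, rng):
        assert stw_raw_vector(rng.standard_normal((16, 5))).shape == (360,)

    def test_two_channel_entries_match_dtw_oracle(self):
        block = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        raw = stw_raw_vector(block)
        # pairs-major, derivative-minor: [d0, d1, d2] of the single pair
        assert raw[0] == pytest.approx(dtw_brute_force([0, 0, 0], [1, 1, 1]))
        assert raw[1] == pytest.approx(0.0)  # first differences both zero
        assert raw[2] == pytest.approx(0.0)


class TestStep:
    def test_first_iteration_switch_semantics(self, rng):
        raw = np.abs(rng.standard_normal(6))
        cfg = STWConfig(beta=1.0)
        out, state = stw_step(raw, STWState.initial(6), cfg)
        L = np.log1p(raw + cfg.eps)
        # cell' = L; fused = L; out = normalize(L + beta L) + normalize(log1p(L))
        expected = l2_normalize(L + cfg.beta * L) + l2_normalize(np.log1p(np.abs(L)))
        np.testing.assert_allclose(out, expected, rtol=1e-12)
        np.testing.assert_allclose(state.cell, L)
        assert state.t == 1 and state.prev_out is not None

    def test_cell_state_accumulates_linearly(self, rng):
        raw = np.abs(rng.standard_normal(4))
        cfg = STWConfig()
        state = STWState.initial(4)
        for t in range(5):
            _, state = stw_step(raw, state, cfg)
        np.testing.assert_allclose(state.cell, 5 * np.log1p(raw + cfg.eps), rtol=1e-12)

    def test_cell_state_is_nondecreasing(self, rng):
        cfg = STWConfig()
        state = STWState.initial(8)
        prev_cell = state.cell.copy()
        for _ in range(6):
            _, state = stw_step(np.abs(rng.standard_normal(8)), state, cfg)
            assert np.all(state.cell >= prev_cell - 1e-15)
            prev_cell = state.cell.copy()

    def test_length_mismatch_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            stw_step(np.ones(3), STWState.initial(4))
        with pytest.raises(ValueError):
            stw_step(np.array([1.0, np.nan]), STWState.initial(2))

    def test_beta_range_enforced(self):
        with pytest.raises(ValueError, match="beta"):
            STWConfig(beta=2.0)
        assert STWConfig(beta=2.0, enforce_beta_range=False).beta == 2.0


def _window_set(blocks_by_event):
    ws = WindowSet()
    for e, blocks in enumerate(blocks_by_event):
        for i, b in enumerate(blocks):
            ws.windows.append(b)
            ws.labels.append(e)
            ws.source.append((e, i))
    return ws


class TestFramework:
    def test_output_has_360_columns_for_16_channels(self, rng):
        ws = _window_set([[rng.standard_normal((16, 5))]])
        fm = run_stw_framework(ws)
        assert fm.n_features == 360

    def test_two_runs_are_bit_identical(self, rng):
        ws = _window_set([[rng.standard_normal((4, 12)) for _ in range(3)]])
        a = run_stw_framework(ws)
        b = run_stw_framework(ws)
        np.testing.assert_array_equal(a.values, b.values)

    def test_state_resets_between_events(self, rng):
        b1, b2 = rng.standard_normal((2, 3, 12))
        joined = run_stw_framework(_window_set([[b1, b2]]))
        split = run_stw_framework(_window_set([[b1], [b2]]))
        np.testing.assert_array_equal(joined.values[0], split.values[0])
        assert not np.allclose(joined.values[1], split.values[1])

    def test_classes_with_distinct_gains_are_separated(self, rng):
        # two spatial gain patterns; between-class STW rows should sit
        # further apart than within-class rows
        gains = {0: np.array([1.0, 2.0, 4.0]), 1: np.array([4.0, 2.0, 1.0])}
        events = []
        labels = []
        for e in range(8):
            cls = e % 2
            base = rng.standard_normal(20)
            blocks = [gains[cls][:, None] * (base + 0.05 * rng.standard_normal(20))
                      for _ in range(2)]
            events.append(blocks)
            labels.append(cls)
        ws = WindowSet()
        for e, blocks in enumerate(events):
            for i, b in enumerate(blocks):
                ws.windows.append(b)
                ws.labels.append(labels[e])
                ws.source.append((e, i))
        fm = run_stw_framework(ws)
        X, y = fm.values, np.array(fm.labels)
        from scipy.spatial.distance import cdist

        d = cdist(X, X)
        same = d[(y[:, None] == y[None, :]) & ~np.eye(len(y), dtype=bool)]
        diff = d[y[:, None] != y[None, :]]
        assert diff.mean() > same.mean()
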