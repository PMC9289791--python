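import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from engfeat.features_td import (TDDConfig, channel_difference_streams, mav,
                                 nonlinear_version, run_mav_framework,
                                 run_mav_wl_framework, run_tdd_framework,
                                 run_tsd_framework, tdd_descriptors,
                                 tdd_similarity, tsd_extra_descriptors,
                                 tsd_similarity, wavelength, window_fusion)
from engfeat.preprocess import WindowSet

EPS = 1e-8

finite_vec = st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=1, max_size=12)


def tdd_reference(x, lam=0.1, eps=EPS):
    """Plain-arithmetic re-derivation of f1..f6 (independent of numpy)."""
    N = len(x)
    d1 = [x[i + 1] - x[i] for i in range(N - 1)]
    d2 = [d1[i + 1] - d1[i] for i in range(N - 2)]
    m0 = math.sqrt(sum(v * v for v in x)) ** lam / lam
    m2 = math.sqrt(sum(v * v for v in d1) / N) ** lam / lam
    m4 = math.sqrt(sum(v * v for v in d2) / N) ** lam / lam
    g = lambda a: math.log(max(abs(a), eps))
    s = m0 / math.sqrt(max(abs(m0 - m2), eps) * max(abs(m0 - m4), eps))
    irf = math.sqrt(m2 * m2 / max(abs(m0 * m4), eps))
    wlr = sum(abs(v) for v in d1) / max(sum(abs(v) for v in d2), eps)
    return [g(m0), g(m0 - m2), g(m0 - m4), g(s), g(irf), g(wlr)]


class TestScalars:
    @pytest.mark.parametrize("x,expected", [
        ([0, 0, 0, 0], 0.0),
        ([1, -1, 1, -1], 1.0),
        ([3, -4, 0, 5], 3.0),
    ])
    def test_mav_forced_arithmetic(self, x, expected):
        assert mav(x) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("x,expected", [
        ([5, 5, 5, 5], 0.0),
        ([0, 1, 0, 1], 3.0),
        (list(range(10)), 9.0),
    ])
    def test_wavelength_forced_arithmetic(self, x, expected):
        assert wavelength(x) == pytest.approx(expected, abs=1e-9)

    @given(finite_vec, st.floats(-10, 10))
    def test_mav_positively_homogeneous(self, x, c):
        assert mav(np.multiply(c, x)) == pytest.approx(abs(c) * mav(x), rel=1e-9, abs=1e-9)

    def test_empty_and_short_windows_rejected(self):
        with pytest.raises(ValueError):
            mav([])
        with pytest.raises(ValueError):
            wavelength([1.0])


class TestTDDDescriptors:
    def test_zero_order_moment_example(self):
        # sum of squares 3^2+4^2 = 25 -> m̄0 = 5, m0 = 5^0.1/0.1, f1 = log m0
        f = tdd_descriptors([3.0, 4.0, 0.0])
        assert f[0] == pytest.approx(math.log(5 ** 0.1 / 0.1), abs=1e-9)
        assert f[0] == pytest.approx(2.46358, abs=1e-4)

    def test_constant_window_collapses_f2_to_f1(self):
        f = tdd_descriptors([2.0, 2.0, 2.0, 2.0])
        assert f[1] == pytest.approx(f[0], abs=1e-9)

    def test_matches_independent_arithmetic(self, rng):
        for _ in range(25):
            x = rng.standard_normal(16).tolist()
            np.testing.assert_allclose(tdd_descriptors(x), tdd_reference(x),
                                       rtol=1e-9, atol=1e-9)

    def test_sign_vector_is_finite(self, rng):
        x = rng.choice([-1.0, 1.0], size=16)
        assert np.all(np.isfinite(tdd_descriptors(x)))

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            tdd_descriptors([1.0, 2.0])


class TestNonlinearVersion:
    def test_zero_input_unit_eps_maps_to_zero(self):
        np.testing.assert_allclose(nonlinear_version(np.zeros(4), eps=1.0), 0.0)

    def test_analytic_point(self):
        # x = e^(1/2): log(x^2) = 1 -> squared = 1
        out = nonlinear_version([math.exp(0.5)], eps=1e-300)
        assert out[0] == pytest.approx(1.0, rel=1e-9)

    @given(finite_vec)
    def test_output_nonnegative(self, x):
        assert np.all(nonlinear_version(np.array(x)) >= 0)


class TestSimilarities:
    def test_tdd_identity_and_zero_cases(self):
        a = np.array([1.0, -2.0, 3.0])
        np.testing.assert_allclose(tdd_similarity(a, a), -1.0)
        np.testing.assert_allclose(tdd_similarity(a, np.zeros(3)), 0.0)

    def test_tdd_forced_arithmetic(self):
        assert tdd_similarity([1.0], [2.0])[0] == pytest.approx(-0.8, abs=1e-9)

    def test_tsd_forced_arithmetic(self):
        np.testing.assert_allclose(tsd_similarity([1.0, 1.0], [1.0, 1.0]), [0.25, 0.25])
        np.testing.assert_allclose(tsd_similarity([1.0, 2.0], [3.0, 4.0]),
                                   [0.1, 4.0 / 15.0], rtol=1e-9)
        np.testing.assert_allclose(tsd_similarity([1.0, 2.0], [0.0, 0.0]), 0.0)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=8),
           st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=8))
    def test_bounds(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        assert np.all(np.abs(tdd_similarity(a, b)) <= 1.0 + 1e-12)
        assert np.all(np.abs(tsd_similarity(a, b)) <= 0.5 + 1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tdd_similarity([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            tsd_similarity([1.0], [1.0, 2.0])


class TestTSDExtras:
    def test_constant_window_has_zero_cov(self):
        f7, f8 = tsd_extra_descriptors([3.0, 3.0, 3.0, 3.0])
        assert f7 == pytest.approx(math.log(EPS), abs=1e-9)

    def test_tkeo_single_interior_sample(self):
        # 2^2 - 1*3 = 1 -> f8 = log(1 + eps) ~ 0
        _, f8 = tsd_extra_descriptors([1.0, 2.0, 3.0])
        assert f8 == pytest.approx(math.log(1.0 + EPS), abs=1e-12)

    def test_cov_scale_invariant(self, rng):
        x = rng.standard_normal(32) + 5.0
        f_a = tsd_extra_descriptors(x)
        f_b = tsd_extra_descriptors(2.0 * x)
        assert f_a[0] == pytest.approx(f_b[0], abs=1e-9)


class TestStreams:
    @pytest.mark.parametrize("nc,expected", [(2, 3), (3, 6), (16, 136)])
    def test_stream_count(self, nc, expected, rng):
        streams = channel_difference_streams(rng.standard_normal((nc, 8)))
        assert len(streams) == expected

    def test_two_channel_streams_are_c1_c2_and_difference(self):
        block = np.array([[1.0, 2.0], [0.5, 1.0]])
        s = channel_difference_streams(block)
        np.testing.assert_allclose(s[0], block[0])
        np.testing.assert_allclose(s[1], block[1])
        np.testing.assert_allclose(s[2], block[0] - block[1])

    def test_identical_channels_give_zero_difference(self):
        block = np.tile(np.arange(5.0), (2, 1))
        assert np.allclose(channel_difference_streams(block)[2], 0.0)

    def test_single_channel_warns(self):
        with pytest.warns(UserWarning, match="single channel"):
            s = channel_difference_streams(np.ones((1, 5)))
        assert len(s) == 1


class TestWindowFusion:
    def test_first_iteration_is_l2_normalisation(self):
        np.testing.assert_allclose(window_fusion([3.0, 4.0], None), [0.6, 0.8])

    def test_product_then_normalise(self):
        v = np.array([1.0, 2.0, 3.0])
        expected = (v * v) / np.linalg.norm(v * v)
        np.testing.assert_allclose(window_fusion(v, v), expected)

    def test_zero_partner_entry_is_absorbing(self):
        out = window_fusion([1.0, 2.0], [0.0, 1.0])
        assert out[0] == 0.0

    def test_all_zero_guard(self):
        np.testing.assert_array_equal(window_fusion([0.0, 0.0], None), [0.0, 0.0])


def _window_set(n_events, wins_per_event, nc, W, rng, labels=None):
    ws = WindowSet()
    for e in range(n_events):
        lab = labels[e] if labels else e % 2
        for w in range(wins_per_event):
            ws.windows.append(rng.standard_normal((nc, W)))
            ws.labels.append(lab)
            ws.source.append((e, w))
    return ws


class TestFrameworks:
    @pytest.mark.parametrize("runner,nc,expected_cols", [
        (run_mav_framework, 16, 16),
        (run_mav_wl_framework, 16, 32),
        (run_tdd_framework, 16, 96),
        (run_tdd_framework, 2, 12),
        (run_tsd_framework, 16, 1088),
        (run_tsd_framework, 2, 24),
        (run_tsd_framework, 3, 48),
    ])
    def test_column_counts(self, runner, nc, expected_cols, rng):
        ws = _window_set(1, 2, nc, 16, rng)
        fm = runner(ws)
        assert fm.n_features == expected_cols
        assert np.all(np.isfinite(fm.values))

    def test_fused_rows_unit_norm_or_zero(self, rng):
        ws = _window_set(2, 4, 3, 16, rng)
        for runner in (run_mav_framework, run_mav_wl_framework):
            fm = runner(ws)
            norms = np.linalg.norm(fm.values, axis=1)
            assert np.all((np.abs(norms - 1) < 1e-9) | (norms < 1e-12))

    def test_repeated_window_follows_iterated_fusion_map(self, rng):
        w = np.abs(rng.standard_normal((2, 8))) + 0.1
        n_rep = 60
        ws = WindowSet()
        for i in range(n_rep):
            ws.windows.append(w)
            ws.labels.append(0)
            ws.source.append((0, i))
        fm = run_mav_framework(ws)
        # independent iteration of r <- normalize(v ⊙ r) starting from v
        v = np.mean(np.abs(w), axis=1)
        r = v / np.linalg.norm(v)
        for i in range(n_rep):
            np.testing.assert_allclose(fm.values[i], r, rtol=1e-9)
            r = v * r
            r /= np.linalg.norm(r)
        # ... and the iteration approaches its fixed point
        assert np.allclose(fm.values[-1], fm.values[-2], atol=1e-6)

    def test_zero_signal_gives_zero_mav_rows(self):
        ws = WindowSet(windows=[np.zeros((2, 8))], labels=[0], source=[(0, 0)])
        fm = run_mav_framework(ws)
        np.testing.assert_array_equal(fm.values, 0.0)

    def test_constant_windows_have_zero_wl_features(self):
        ws = WindowSet(windows=[np.ones((2, 8))], labels=[0], source=[(0, 0)])
        fm = run_mav_wl_framework(ws)
        np.testing.assert_allclose(fm.values[0, 2:], 0.0)  # WL columns

    def test_tdd_lag_boundary_uses_pointwise_switch(self, rng):
        # with a fusion lag of 3 the first three windows have no partner:
        # identical windows then produce identical (switch-path) rows
        w = rng.standard_normal((2, 16))
        ws = WindowSet(windows=[w] * 5, labels=[0] * 5,
                       source=[(0, i) for i in range(5)])
        fm = run_tdd_framework(ws, TDDConfig())
        np.testing.assert_allclose(fm.values[0], fm.values[1])
        np.testing.assert_allclose(fm.values[0], fm.values[2])
        # from window 4 on, fusion with the 3rd-previous kicks in
        assert not np.allclose(fm.values[0], fm.values[3])

    def test_fusion_resets_at_event_boundaries(self, rng):
        w1, w2 = rng.standard_normal((2, 2, 16))
        one_event = WindowSet(windows=[w1, w2], labels=[0, 0],
                              source=[(0, 0), (0, 1)])
        two_events = WindowSet(windows=[w1, w2], labels=[0, 1],
                               source=[(0, 0), (1, 0)])
        fused = run_mav_framework(one_event).values[1]
        fresh = run_mav_framework(two_events).values[1]
        assert not np.allclose(fused, fresh)

    def test_prefusion_scaling_homogeneity(self, rng):
        # scaling the signal scales MAV and WL linearly before fusion;
        # after L2 normalisation the first (switch-path) row is invariant
        w = rng.standard_normal((2, 16))
        a = run_mav_wl_framework(WindowSet(windows=[w], labels=[0], source=[(0, 0)]))
        b = run_mav_wl_framework(WindowSet(windows=[2 * w], labels=[0], source=[(0, 0)]))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)
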