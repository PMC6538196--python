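"""Statistics: sign-rank, FDR, latencies, jackknife, asymmetry.

Exact-enumeration and hand-computed oracles are kept independent of the
implementation under test.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from occludecode.errors import ConfigurationError
from occludecode.inference import (
    compare_curves,
    diagonal_asymmetry,
    fdr_adjust,
    group_onset,
    jackknife_latency,
    onset_latency,
    peak_latency,
    signrank_p,
)


def brute_force_signrank(values, mu0=0.0, sided="right"):
    """Full 2^n enumeration of the signed-rank null (midranks for ties)."""
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs_pos = ranks[d > 0].sum()
    w_obs_neg = ranks[d < 0].sum()
    ge = le = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs_pos - 1e-12:
            ge += 1
        if w >= w_obs_neg - 1e-12:
            le += 1
    p_right = ge / 2 ** n
    if sided == "right":
        return p_right
    return min(1.0, 2.0 * min(p_right, le / 2 ** n))


class TestSignrank:
    def test_all_positive_n15_is_exact_minimum(self):
        values = np.arange(1.0, 16.0)
        assert signrank_p(values, mu0=0.0, sided="right") == pytest.approx(
            1.0 / 2 ** 15)

    def test_symmetric_values_not_significant(self):
        d = np.array([1, -1, 2, -2, 3, -3, 4, -4, 5, -5], dtype=float)
        assert signrank_p(d, 0.0, sided="right") > 0.5

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        values = np.round(rng.standard_normal(n), 2)
        values = values[values != 0]
        if values.size == 0:
            values = np.array([0.5])
        for sided in ("right", "two"):
            assert signrank_p(values, 0.0, sided) == pytest.approx(
                brute_force_signrank(values, 0.0, sided), abs=1e-12)

    def test_matches_scipy_exact_no_ties(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(12) + 0.5
        ours = signrank_p(x, 0.0, "two")
        ref = sps.wilcoxon(x, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_all_zero_differences_warns_p1(self):
        with pytest.warns(UserWarning):
            assert signrank_p(np.zeros(5), 0.0) == 1.0

    def test_large_n_normal_approximation_close_to_exact_tail(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(40) + 0.6
        ours = signrank_p(x, 0.0, "right")
        ref = sps.wilcoxon(x, alternative="greater",
                           method="approx", correction=True).pvalue
        assert ours == pytest.approx(ref, rel=1e-6)


class TestFdr:
    def test_hand_computed_bh_example(self):
        q = fdr_adjust(np.array([0.01, 0.02, 0.04]))
        np.testing.assert_allclose(q, [0.03, 0.03, 0.04])

    def test_constant_vector_identity(self):
        p = np.full(7, 0.2)
        np.testing.assert_allclose(fdr_adjust(p), p)

    def test_single_p(self):
        assert fdr_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_nan_rejected(self):
        with pytest.raises(ConfigurationError):
            fdr_adjust(np.array([0.1, np.nan]))

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_matches_statsmodels_and_is_monotone(self, p_list):
        p = np.array(p_list)
        q = fdr_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, ref, atol=1e-12)
        # monotone: same order as p
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        # q >= p elementwise, clipped at 1
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()

    def test_mask_shrinks_under_correction(self):
        rng = np.random.default_rng(3)
        p = rng.random(100) * 0.2
        q = fdr_adjust(p)
        alpha = 0.05
        assert set(np.nonzero(q < alpha)[0]) <= set(np.nonzero(p < alpha)[0])


class TestLatency:
    def test_onset_at_qualifying_run(self):
        t = np.arange(-100.0, 351.0)
        mask = (t >= 100) & (t < 112)  # 12 ms run
        assert onset_latency(mask, t) == 100.0

    def test_short_runs_rejected(self):
        t = np.arange(0.0, 200.0)
        mask = (t >= 50) & (t < 59)  # 9 ms only
        assert onset_latency(mask, t) is None

    def test_earliest_qualifying_run_wins(self):
        t = np.arange(0.0, 400.0)
        mask = ((t >= 80) & (t <= 95)) | ((t >= 150) & (t <= 300))
        # brute-force oracle
        expected = None
        for i in range(t.size - 9):
            if mask[i:i + 10].all():
                expected = t[i]
                break
        assert expected == 80.0
        assert onset_latency(mask, t) == expected

    def test_coarse_grid_scales_run_length(self):
        t = np.arange(0.0, 100.0, 2.0)  # 2 ms grid -> 5 samples needed
        mask = np.zeros(t.size, dtype=bool)
        mask[10:15] = True  # exactly 5 samples
        assert onset_latency(mask, t) == t[10]
        mask[14] = False
        assert onset_latency(mask, t) is None

    def test_peak_unique_max(self):
        t = np.arange(-100.0, 351.0)
        curve = np.exp(-0.5 * ((t - 139.0) / 30) ** 2)
        assert peak_latency(curve, t) == 139.0

    def test_peak_tie_break_earliest(self):
        t = np.arange(0.0, 300.0)
        curve = np.zeros(t.size)
        curve[(t == 150) | (t == 200)] = 5.0
        assert peak_latency(curve, t) == 150.0
        assert peak_latency(np.ones(t.size), t) == 0.0


class TestJackknife:
    def test_all_folds_agree(self):
        t = np.arange(0.0, 200.0)
        curve = np.where((t >= 79) & (t <= 150), 60.0, 50.0)
        curves = np.tile(curve, (5, 1))
        est = jackknife_latency(curves, t, "peak")
        assert est.peak_mean_ms == 79.0
        assert est.peak_sd_ms == 0.0
        assert est.n_folds == 5

    def test_fold_arithmetic(self):
        # folds engineered to produce peaks at 100, 102, 104
        t = np.arange(0.0, 200.0)
        curves = np.zeros((3, t.size))
        # leaving out subject i produces the mean of the others; build
        # subjects so pairwise means peak at distinct known times
        curves[0, 103] = curves[0, 105] = 10.0
        curves[1, 101] = curves[1, 105] = 10.0
        curves[2, 101] = curves[2, 103] = 10.0
        est = jackknife_latency(curves, t, "peak")
        # leave-out-0 -> mean of 1,2 peaks at 101; leave-out-1 -> 103;
        # leave-out-2 -> 105
        assert est.peak_mean_ms == pytest.approx(103.0)
        assert est.peak_sd_ms == pytest.approx(2.0)

    def test_two_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            jackknife_latency(np.zeros((2, 10)), np.arange(10.0), "peak")


class TestCompareCurves:
    def test_identical_curves_nothing_significant(self):
        rng = np.random.default_rng(1)
        a = 50 + rng.standard_normal((8, 50))
        m = compare_curves(a, a.copy())
        assert m.mask.sum() == 0

    def test_offset_window_detected_and_confined(self):
        rng = np.random.default_rng(2)
        t = np.arange(0.0, 400.0)
        a = 50 + 0.5 * rng.standard_normal((12, t.size))
        b = a.copy()
        win = (t >= 185) & (t <= 237)
        b[:, win] += 20.0
        m = compare_curves(a, b)
        sig_t = t[m.mask]
        assert sig_t.size > 0
        assert sig_t.min() >= 185 and sig_t.max() <= 237

    def test_mismatched_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            compare_curves(np.zeros((3, 10)), np.zeros((4, 10)))


class TestDiagonalAsymmetry:
    def test_single_cell_above(self):
        mask = np.zeros((300, 300), dtype=bool)
        mask[100, 200] = True  # trained at 100, tested at 200 -> above
        fa, fb = diagonal_asymmetry(mask)
        assert fa == 1.0 and fb == 0.0

    def test_symmetric_mask_equal_fractions(self):
        rng = np.random.default_rng(4)
        m = rng.random((40, 40)) < 0.2
        m = m | m.T
        fa, fb = diagonal_asymmetry(m)
        assert fa == pytest.approx(fb)

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(5)
        m = rng.random((25, 25)) < 0.3
        fa, fb = diagonal_asymmetry(m)
        above = below = total = 0
        for i in range(25):
            for j in range(25):
                if m[i, j]:
                    total += 1
                    if j > i:
                        above += 1
                    elif j < i:
                        below += 1
        assert fa == pytest.approx(above / total)
        assert fb == pytest.approx(below / total)

    def test_empty_mask_warns_none(self):
        with pytest.warns(UserWarning):
            fa, fb = diagonal_asymmetry(np.zeros((5, 5), dtype=bool))
        assert fa is None and fb is None

    def test_non_square_rejected(self):
        with pytest.raises(ConfigurationError):
            diagonal_asymmetry(np.zeros((3, 4), dtype=bool))


class TestGroupOnset:
    def test_onset_not_before_signal_with_flat_null(self):
        rng = np.random.default_rng(6)
        t = np.arange(-100.0, 300.0)
        curves = 50 + rng.standard_normal((15, t.size))
        curves[:, t >= 100] += 8.0
        onset, sig = group_onset(curves, t)
        assert onset is not None
        assert 95.0 <= onset <= 110.0
        # onset <= peak wherever both exist
        assert onset <= peak_latency(curves.mean(axis=0), t)
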