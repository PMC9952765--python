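"""Savitzky-Golay smoothing, three-criterion peak finding, quantification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csimotion import (
    MotionSegment,
    PeakCriteria,
    compute_spectrum,
    find_motion_peaks,
    quantify_motion,
    savgol_smooth,
)


def peak_oracle(x, sep, min_height, min_prominence):
    """Exhaustive reference implementation of the three-criterion finder:
    enumerate local maxima, filter by height and topographic prominence,
    then greedily keep the highest (earlier index on ties)."""
    n = x.size
    cands = [i for i in range(1, n - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]]
    kept = []
    for p in cands:
        if x[p] < min_height:
            continue
        left = x[:p][::-1]
        higher = np.nonzero(left > x[p])[0]
        lbase = left[: higher[0] + 1].min() if higher.size else left.min() if left.size else x[p]
        right = x[p + 1 :]
        higher = np.nonzero(right > x[p])[0]
        rbase = min(x[p], right[: higher[0] + 1].min()) if higher.size else min(x[p], right.min()) if right.size else x[p]
        if x[p] - max(lbase, rbase) >= min_prominence:
            kept.append(p)
    accepted = []
    for p in sorted(kept, key=lambda i: (-x[i], i)):
        if all(abs(p - q) >= sep for q in accepted):
            accepted.append(p)
    return sorted(accepted)


class TestSavgol:
    def test_reproduces_cubic_exactly(self):
        t = np.linspace(-1, 1, 500)
        x = 0.3 * t**3 - t**2 + 2 * t - 0.5
        np.testing.assert_allclose(savgol_smooth(x, 3, 101), x, atol=1e-8)

    def test_constant_preserved(self):
        np.testing.assert_allclose(savgol_smooth(np.full(300, 4.2), 3, 101), 4.2)

    def test_central_value_matches_least_squares_fit(self, rng):
        # normal-equations oracle: cubic fit over the 101-point window,
        # evaluated at the window centre
        x = rng.normal(size=400)
        out = savgol_smooth(x, order=3, window=101)
        for n0 in (60, 200, 339):
            win = x[n0 - 50 : n0 + 51]
            i = np.arange(-50, 51, dtype=float)
            V = np.vander(i, 4, increasing=True)
            coef = np.linalg.solve(V.T @ V, V.T @ win)
            assert out[n0] == pytest.approx(coef[0], rel=1e-8, abs=1e-10)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="smaller window"):
            savgol_smooth(np.ones(50), 3, 101)


class TestPeakCriteria:
    @pytest.mark.parametrize(
        "f_max, expected", [(10.0, 100), (6.0, 166), (5.0, 200)]
    )
    def test_min_separation_from_motion_band(self, f_max, expected):
        assert PeakCriteria(f_max=f_max, fs=1000.0).min_separation == expected

    def test_height_and_prominence_fractions(self):
        crit = PeakCriteria(f_max=6.0, fs=1000.0)
        Q = np.array([0.0, 10.0, 0.0])
        assert crit.min_height(Q) == pytest.approx(2.0)
        assert crit.min_prominence(Q) == pytest.approx(3.0)

    def test_invalid_factors_rejected(self):
        with pytest.raises(ValueError):
            PeakCriteria(f_max=6.0, fs=1000.0, height_factor=1.5)


class TestFindPeaks:
    def test_constant_series_has_no_peaks(self):
        crit = PeakCriteria(f_max=6.0, fs=1000.0)
        assert find_motion_peaks(np.full(500, 1.0), crit).size == 0

    def test_nonpositive_series_warns_and_returns_none(self, caplog):
        crit = PeakCriteria(f_max=6.0, fs=1000.0)
        with caplog.at_level("WARNING"):
            peaks = find_motion_peaks(-np.abs(np.sin(np.linspace(0, 30, 500))) - 1, crit)
        assert peaks.size == 0

    def test_clean_sinusoid_counts_cycles(self):
        fs = 1000.0
        t = np.arange(10000) / fs
        x = np.sin(2 * np.pi * 5 * t)
        peaks = find_motion_peaks(x, PeakCriteria(f_max=6.0, fs=fs))
        assert peaks.size == 50
        assert np.all(np.diff(peaks) >= 166)

    def test_separation_enforced_greedily_keeping_higher(self):
        x = np.zeros(500)
        x[100] = 1.0
        x[150] = 0.8  # within 166 of the higher peak: dropped
        x[350] = 0.9
        crit = PeakCriteria(f_max=6.0, fs=1000.0)
        np.testing.assert_array_equal(find_motion_peaks(x, crit), [100, 350])

    def test_monotone_in_min_separation(self, rng):
        x = np.abs(rng.normal(size=1500)) + 0.1
        counts = [
            find_motion_peaks(x, PeakCriteria(f_max=f, fs=1000.0)).size
            for f in (100.0, 20.0, 6.0, 2.0)
        ]  # decreasing f_max = increasing separation
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(50, 2000))
    def test_agrees_with_exhaustive_oracle(self, seed, n):
        r = np.random.default_rng(seed)
        x = r.normal(size=n).cumsum()  # correlated series with rich maxima
        x -= x.min()
        crit = PeakCriteria(f_max=50.0, fs=1000.0)
        expected = peak_oracle(
            x, crit.min_separation, crit.min_height(x), crit.min_prominence(x)
        )
        np.testing.assert_array_equal(find_motion_peaks(x, crit), expected)


class TestQuantify:
    def test_few_peaks_have_undefined_rate(self):
        seg = MotionSegment(0, 1000, 1000.0)
        assert quantify_motion(np.array([]), seg, 1000.0).mean_frequency == 0.0
        assert quantify_motion(np.array([5]), seg, 1000.0).mean_frequency == 0.0

    def test_fencepost_frequency(self):
        # 50 peaks spaced 200 ms: spans 9.8 s, (50-1)/9.8 = 5 Hz
        peaks = np.arange(0, 10000, 200)
        seg = MotionSegment(0, 10000, 1000.0)
        quant = quantify_motion(peaks, seg, 1000.0)
        assert quant.count == 50
        assert quant.mean_frequency == pytest.approx(5.0)

    def test_duration_from_segment(self):
        seg = MotionSegment(5000, 15000, 1000.0)
        quant = quantify_motion(np.array([6000, 7000]), seg, 1000.0)
        assert quant.duration == pytest.approx(10.0)

    def test_ruler_mode_reports_no_duration(self):
        seg = MotionSegment(0, 1000, 1000.0)
        quant = quantify_motion(np.array([100, 400]), seg, 1000.0, report_duration=False)
        assert np.isnan(quant.duration)


class TestSpectrum:
    def test_pure_tone_peaks_at_its_frequency(self):
        fs = 1000.0
        t = np.arange(20000) / fs
        freqs, mags = compute_spectrum(np.sin(2 * np.pi * 4 * t), fs)
        assert freqs[np.argmax(mags)] == pytest.approx(4.0, abs=fs / t.size)

    def test_zero_series_zero_spectrum(self):
        _, mags = compute_spectrum(np.zeros(100), 1000.0)
        assert np.all(mags == 0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_spectrum(np.ones(1), 1000.0)
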