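"""Synthetic CSI generator: motion waveforms, channel model, artifacts."""

import numpy as np
import pytest

from csimotion import (
    InvalidConfigError,
    MotionProfile,
    SceneConfig,
    detect_packet_loss,
    extract_amplitude,
    generate_displacement,
    generate_reference_trace,
    inject_packet_loss,
    inject_slow_response,
    quantify_reference,
    reflection_path_gradient,
    synthesize_csi,
)


class TestDisplacement:
    def test_zero_amplitude_is_null_motion(self):
        prof = MotionProfile.preset("tremor", displacement_amplitude=0.0)
        x, gt = generate_displacement(prof, fs=1000, duration=20, seed=0)
        assert np.all(x == 0)
        assert gt.true_count == 0

    def test_fixed_frequency_cycle_count_via_zero_crossings(self):
        prof = MotionProfile.preset("tremor", frequency_spec=5.0)
        x, gt = generate_displacement(prof, fs=1000, duration=20, seed=0)
        assert gt.true_count == 50
        # independent oracle: upward zero crossings of the active stretch
        active = x[5000:15000]
        up = np.sum((active[:-1] <= 0) & (active[1:] > 0))
        assert up == 50
        assert gt.true_mean_frequency == pytest.approx(5.0, rel=1e-6)

    def test_waveform_zero_outside_active_window(self):
        prof = MotionProfile.preset("tremor")
        x, _ = generate_displacement(prof, fs=1000, duration=20, seed=3)
        assert np.all(x[:5000] == 0)
        assert np.all(x[15000:] == 0)

    def test_tremor_cycle_frequencies_within_range(self):
        prof = MotionProfile.preset("tremor")  # 3-6 Hz range
        for seed in range(5):
            _, gt = generate_displacement(prof, fs=1000, duration=20, seed=seed)
            freqs = np.array(gt.cycle_frequencies)
            assert freqs.size == gt.true_count
            assert np.all((freqs >= 3.0) & (freqs <= 6.0))

    def test_frequency_above_nyquist_rejected(self):
        prof = MotionProfile.preset("tremor", frequency_spec=120.0)
        with pytest.raises(InvalidConfigError):
            generate_displacement(prof, fs=200, duration=20, seed=0)

    def test_ground_truth_is_consistent(self):
        prof = MotionProfile.preset("tremor")
        _, gt = generate_displacement(prof, fs=1000, duration=20, seed=11)
        assert gt.true_count == len(gt.cycle_times)
        assert gt.true_duration == prof.active_duration


class TestChannel:
    def test_static_scene_has_constant_amplitude(self):
        prof = MotionProfile.preset("tremor", displacement_amplitude=0.0)
        rec = synthesize_csi(SceneConfig(seed=2, noise_sd=0.0), prof)
        amp = extract_amplitude(rec).values
        assert np.ptp(amp, axis=0).max() < 1e-12

    def test_small_displacement_modulates_at_motion_frequency(self):
        # displacement << lambda (~6 cm): amplitude is modulated at 5 Hz
        prof = MotionProfile.preset("tremor", frequency_spec=5.0,
                                    displacement_amplitude=0.001)
        rec = synthesize_csi(SceneConfig(seed=1, noise_sd=0.0), prof)
        a = extract_amplitude(rec).values[:, 0]
        spec = np.abs(np.fft.rfft(a - a.mean()))
        freqs = np.fft.rfftfreq(a.size, 1 / rec.fs)
        assert freqs[np.argmax(spec)] == pytest.approx(5.0, abs=0.1)

    def test_tangential_motion_is_nearly_invisible(self):
        scene = SceneConfig(seed=3, noise_sd=0.0)
        g = reflection_path_gradient(scene)
        kwargs = dict(frequency_spec=5.0, displacement_amplitude=0.001)
        perp = MotionProfile.preset("tremor", direction=tuple(g), **kwargs)
        tang = MotionProfile.preset("tremor", direction=(-g[1], g[0]), **kwargs)
        var_perp = extract_amplitude(synthesize_csi(scene, perp)).values.var(axis=0)
        var_tang = extract_amplitude(synthesize_csi(scene, tang)).values.var(axis=0)
        assert var_tang.mean() <= 0.01 * var_perp.mean()

    def test_fixed_seed_reproducible_bit_for_bit(self):
        prof = MotionProfile.preset("tremor")
        a = synthesize_csi(SceneConfig(seed=7, noise_sd=0.05), prof)
        b = synthesize_csi(SceneConfig(seed=7, noise_sd=0.05), prof)
        assert np.array_equal(a.samples, b.samples)

    def test_modulation_depth_monotone_in_reflection_gain(self):
        prof = MotionProfile.preset("tremor", frequency_spec=5.0,
                                    displacement_amplitude=0.001)
        depths = []
        for gain in (0.05, 0.15, 0.3):
            scene = SceneConfig(seed=5, noise_sd=0.0, reflection_gain=gain,
                                static_path_gain=1.0 + 0.2j)
            amp = extract_amplitude(synthesize_csi(scene, prof)).values
            depths.append(amp.var(axis=0).mean())
        assert depths[0] < depths[1] < depths[2]


class TestPacketLoss:
    def test_rate_zero_is_identity(self, make_recording):
        rec = make_recording(T=100)
        out = inject_packet_loss(rec, 0.0, seed=1)
        assert np.array_equal(out.samples, rec.samples)

    def test_rate_one_repeats_first_row(self, make_recording):
        rec = make_recording(T=50)
        out = inject_packet_loss(rec, 1.0, seed=1)
        assert np.all(out.samples == out.samples[0])

    def test_loss_count_within_binomial_bounds(self, make_recording):
        T, rate = 20000, 0.1
        rec = make_recording(T=T, n_streams=1)
        out = inject_packet_loss(rec, rate, seed=42)
        repeated = int(np.sum(np.all(out.samples[1:] == out.samples[:-1], axis=1)))
        mean = rate * (T - 1)
        sd = np.sqrt((T - 1) * rate * (1 - rate))
        assert abs(repeated - mean) <= 3 * sd

    def test_round_trip_with_detector(self, make_recording):
        rec = make_recording(T=5000, n_streams=1)
        lossy = inject_packet_loss(rec, 0.08, seed=9)
        flags = detect_packet_loss(lossy, min_run=3)
        # every maximal run of >=3 identical rows must be covered by a flag
        same = np.all(lossy.samples[1:] == lossy.samples[:-1], axis=1)
        covered = np.zeros(lossy.n_times, dtype=bool)
        for s, e in flags:
            covered[s:e] = True
        i = 0
        while i < same.size:
            if same[i]:
                j = i
                while j < same.size and same[j]:
                    j += 1
                if j - i + 1 >= 3:
                    assert covered[i : j + 1].all()
                i = j
            else:
                i += 1


class TestSlowResponse:
    def _rec(self):
        prof = MotionProfile.preset("tremor", frequency_spec=5.0)
        return synthesize_csi(
            SceneConfig(seed=4, noise_sd=0.0, mode="direct"), prof
        )

    def test_zero_times_are_identity(self):
        rec = self._rec()
        out = inject_slow_response(rec, 0.0, 0.0)
        np.testing.assert_allclose(out.samples, rec.samples, rtol=1e-12)

    def test_onset_attenuated(self):
        rec = self._rec()
        out = inject_slow_response(rec, 0.5, 0.5)
        static = rec.samples[:4999].mean(axis=0)
        i = 5010  # 10 ms into the bout, ramp at 2% of full scale
        orig = np.abs(rec.samples[i] - static).mean()
        attn = np.abs(out.samples[i] - static).mean()
        assert attn < 0.1 * orig

    def test_motion_component_never_amplified(self):
        rec = self._rec()
        out = inject_slow_response(rec, 1.0, 1.0)
        static = rec.samples[:4999].mean(axis=0)
        orig = np.abs(rec.samples - static)
        attn = np.abs(out.samples - static)
        assert np.all(attn <= orig + 1e-12)

    def test_requires_ground_truth_meta(self, make_recording):
        with pytest.raises(InvalidConfigError):
            inject_slow_response(make_recording(T=10), 0.1, 0.1)


class TestReferenceTrace:
    def test_length_matches_sensor_rate(self):
        prof = MotionProfile.preset("tremor")
        trace = generate_reference_trace(prof, seed=0, duration=20.0)
        assert trace.fs == 200.0
        assert trace.values.size == 4000

    def test_null_motion_gives_noise_only(self):
        prof = MotionProfile.preset("tremor", displacement_amplitude=0.0)
        trace = generate_reference_trace(prof, seed=0, noise_sd=0.05)
        assert np.abs(trace.values).max() < 0.5  # no motion transients

    def test_peak_count_matches_ground_truth(self):
        prof = MotionProfile.preset("tremor", frequency_spec=5.0)
        trace = generate_reference_trace(prof, seed=0)
        quant = quantify_reference(trace, f_max=6.0)
        assert quant.count == 50
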