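"""PPG beat detector kernels and shared pre/post-processing."""

import dataclasses

import numpy as np
import pytest

from conftest import f1_against_truth
from pulsebench.io_formats import Waveform
from pulsebench.ppgbeats import (
    DETECTOR_NAMES,
    DetectorSpec,
    detect_beats,
    flat_segments,
    kernel_erma,
    kernel_scalogram_peaks,
    kernel_spar,
    prefilter,
    run_detector,
)
from pulsebench.synthgen import SimConfig, simulate_beat_train, synthesize_ppg


class TestPrefilter:
    def test_dc_removed(self):
        w = Waveform(np.full(500, 7.5), 25.0)
        out = prefilter(w)
        assert np.max(np.abs(out.samples)) <= 1e-6 * 7.5

    def test_passband_tone_preserved(self):
        t = np.arange(0, 60, 1 / 25)
        w = Waveform(np.sin(2 * np.pi * 1.0 * t), 25.0)
        out = prefilter(w)
        mid = out.samples[250:-250]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.05)

    def test_stopband_tone_attenuated(self):
        t = np.arange(0, 60, 1 / 30)
        w = Waveform(np.sin(2 * np.pi * 12.0 * t), 30.0)
        out = prefilter(w, high_hz=8.0)
        assert np.max(np.abs(out.samples[100:-100])) <= 0.10

    def test_passband_above_nyquist_rejected(self):
        w = Waveform(np.zeros(100), 12.0)
        with pytest.raises(ValueError, match="Nyquist"):
            prefilter(w, high_hz=8.0)


class TestFlatSegments:
    def test_recovers_injected_flat(self):
        cfg = SimConfig(duration_s=60.0, flat_spec=[(30.0, 31.0)], jitter_sd_ms=0)
        beats, _ = simulate_beat_train(cfg)
        ppg = synthesize_ppg(beats, cfg)
        segs = flat_segments(ppg)
        assert len(segs) == 1
        s, e = segs[0]
        assert s == pytest.approx(30.0, abs=1 / 25)
        assert e == pytest.approx(31.0, abs=2 / 25)

    def test_exact_threshold_not_flagged(self):
        fs = 25.0
        x = np.sin(np.arange(200))
        x[100:106] = x[100]  # 6 samples: span 0.2 s exactly
        assert flat_segments(Waveform(x, fs)) == []
        x[100:107] = x[100]  # span 0.24 s > 0.2 s
        assert len(flat_segments(Waveform(x, fs))) == 1

    def test_noisy_signal_has_none(self):
        rng = np.random.default_rng(0)
        assert flat_segments(Waveform(rng.standard_normal(1000), 25.0)) == []


class TestScalogramKernel:
    def test_hand_computed_example(self):
        peaks = kernel_scalogram_peaks(np.array([0.0, 1.0, 0.0, 1.0, 0.0]))
        assert set(peaks.tolist()) == {1, 3}

    def test_monotonic_ramp_no_peaks(self):
        assert kernel_scalogram_peaks(np.arange(50.0)).size == 0

    def test_sinusoid_one_peak_per_cycle(self):
        # phase offset keeps extrema off exact sample-pair midpoints; a
        # cycle peak within lambda samples of the window edge is outside
        # the scalogram's reach (overlapping windows recover those)
        t = np.arange(0, 5, 1 / 30)  # 5 cycles of 1 Hz in the window
        peaks = kernel_scalogram_peaks(np.sin(2 * np.pi * t + 0.3))
        assert 4 <= peaks.size <= 5
        spacing = np.diff(peaks) / 30.0
        np.testing.assert_allclose(spacing, 1.0, atol=2 / 30)

    def test_onsets_from_minima_scalogram(self):
        t = np.arange(0, 5, 1 / 30)
        peaks, onsets = kernel_scalogram_peaks(
            np.sin(2 * np.pi * t + 0.3), fs=30.0, return_onsets=True
        )
        assert 4 <= onsets.size <= 5  # troughs of the sinusoid
        assert 4 <= peaks.size <= 5
        # onsets interleave peaks
        assert np.all(np.abs(np.diff(peaks) - 30.0) <= 2)


class TestErmaKernel:
    def test_raised_sinusoid_beat_count(self):
        fs = 50.0
        t = np.arange(0, 10, 1 / fs)
        x = np.sin(2 * np.pi * 1.0 * t)  # zero-mean, as after band-pass
        beats = kernel_erma(x, fs)
        assert abs(beats.size - 10) <= 1

    def test_zero_signal_no_beats(self):
        assert kernel_erma(np.zeros(500), 25.0).size == 0

    def test_amplitude_scale_invariance(self):
        fs = 25.0
        rng = np.random.default_rng(1)
        t = np.arange(0, 30, 1 / fs)
        x = np.sin(2 * np.pi * t) + 0.1 * rng.standard_normal(t.size)
        np.testing.assert_array_equal(kernel_erma(x, fs), kernel_erma(2.0 * x, fs))


class TestSparKernel:
    def test_cycle_length_on_clean_ppg(self):
        cfg = SimConfig(duration_s=20.0, jitter_sd_ms=0, lf_amp_ms=0, hf_amp_ms=0)
        beats, _ = simulate_beat_train(cfg)
        ppg = prefilter(synthesize_ppg(beats, cfg))
        idx = kernel_spar(ppg.samples, 25.0)
        ibis = np.diff(idx) / 25.0
        assert np.median(ibis) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_window_skipped(self):
        rng = np.random.default_rng(2)
        assert kernel_spar(rng.standard_normal(500), 25.0).size == 0

    def test_30_bpm_outside_admissible_range(self):
        # 2 s cycle: autocorrelation peak falls outside the 40-200 BPM lags
        cfg = SimConfig(duration_s=20.0, mean_rr_ms=1999.0, jitter_sd_ms=0,
                        lf_amp_ms=0, hf_amp_ms=0, pulse_width_s=0.5)
        beats, _ = simulate_beat_train(cfg)
        ppg = prefilter(synthesize_ppg(beats, cfg))
        assert kernel_spar(ppg.samples, 25.0).size == 0


class TestDetectors:
    @pytest.mark.parametrize("name", DETECTOR_NAMES)
    def test_clean_signal_f1(self, clean_ppg, name):
        ppg, beats, _ = clean_ppg
        detected = run_detector(ppg, name)
        assert f1_against_truth(detected.times_s, beats) >= 0.99

    @pytest.mark.parametrize("name", ["msptd", "ampd", "erma"])
    def test_count_recovery_60bpm(self, name):
        cfg = SimConfig(duration_s=600.0, mean_rr_ms=1000.0, jitter_sd_ms=0,
                        lf_amp_ms=0, hf_amp_ms=0, seed=0)
        beats, _ = simulate_beat_train(cfg)
        detected = run_detector(synthesize_ppg(beats, cfg), name)
        assert abs(len(detected) - 600) <= 2

    def test_all_flat_signal_zero_beats(self):
        w = Waveform(np.full(1500, 3.0), 25.0)
        flat = flat_segments(w)
        out = detect_beats(prefilter(w), DetectorSpec("msptd"), flat=flat)
        assert len(out) == 0
        assert len(out.discarded_segments) == 1

    @pytest.mark.parametrize("name", DETECTOR_NAMES)
    def test_determinism(self, clean_ppg, name):
        ppg, _, _ = clean_ppg
        a = run_detector(ppg, name)
        b = run_detector(ppg, name)
        np.testing.assert_array_equal(a.times_s, b.times_s)

    @pytest.mark.parametrize("name", ["msptd", "erma", "qppgfast"])
    def test_time_shift_equivariance(self, name):
        cfg = SimConfig(duration_s=120.0, jitter_sd_ms=10, seed=8)
        beats, _ = simulate_beat_train(cfg)
        shift = 2.0
        cfg2 = dataclasses.replace(cfg, duration_s=122.0)
        ppg_a = synthesize_ppg(beats, cfg2)
        ppg_b = synthesize_ppg(beats + shift, cfg2)
        ta = run_detector(ppg_a, name).times_s
        tb = run_detector(ppg_b, name).times_s
        # compare interior beats (edges differ by construction)
        ta = ta[(ta > 5) & (ta < 110)]
        tb = tb[(tb > 5 + shift) & (tb < 110 + shift)] - shift
        assert ta.size == tb.size
        np.testing.assert_allclose(ta, tb, atol=1.01 / 25.0)

    @pytest.mark.parametrize("name", ["msptd", "ampd", "erma"])
    def test_amplitude_scale_invariance(self, clean_ppg, name):
        ppg, _, _ = clean_ppg
        scaled = Waveform(5.0 * ppg.samples, ppg.fs_hz)
        a = run_detector(ppg, name).times_s
        b = run_detector(scaled, name).times_s
        np.testing.assert_array_equal(a, b)

    def test_unknown_detector_rejected(self):
        with pytest.raises(ValueError, match="unknown detector"):
            DetectorSpec("pansharpen")

    def test_f1_noise_monotonicity_short_ladder(self):
        # 8-seed smoke version of the full noise-ladder property
        levels = [0.0, 0.5, 2.0]
        medians = {n: [] for n in ("msptd", "erma")}
        for amp in levels:
            per = {n: [] for n in medians}
            for seed in range(8):
                cfg = SimConfig(
                    duration_s=90.0, jitter_sd_ms=10, seed=seed,
                    motion_spec=[(0.0, 90.0, amp)] if amp else [],
                )
                beats, _ = simulate_beat_train(cfg)
                ppg = synthesize_ppg(beats, cfg)
                for n in per:
                    per[n].append(f1_against_truth(run_detector(ppg, n).times_s, beats))
            for n in medians:
                medians[n].append(np.median(per[n]))
        for n, vals in medians.items():
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:])), (n, vals)
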