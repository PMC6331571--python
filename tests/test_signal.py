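"""Filtering, NEO detection, noise estimation, SNR and exclusion rules."""

import numpy as np
import pytest

from probeqc.config import SimulationConfig
from probeqc.recording import RecordingSegment, simulate_recording
from probeqc.signal import (
    ExclusionRules,
    FilterSpec,
    bandpass,
    estimate_noise_sigma,
    exclude_segment,
    neo_detect,
    snr_of_segment,
    snr_series,
    snr_timecourse,
    spike_window_rms,
)
from probeqc.templates import spike_template

FS = 20000.0


def sine(freq, duration=1.0, amp=100.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_stopband_and_passband(self):
        # LFP-band tone almost removed; in-band tone almost untouched
        out_lo = bandpass(sine(100.0), FS)
        assert np.std(out_lo) < 0.05 * np.std(sine(100.0))
        out_mid = bandpass(sine(2000.0), FS)
        assert np.std(out_mid) == pytest.approx(np.std(sine(2000.0)), rel=0.10)

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass(np.zeros(4000), FS), 0.0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(4000), FS, FilterSpec(low_hz=500, high_hz=11000))
        with pytest.raises(ValueError):
            bandpass(np.zeros(4000), FS, FilterSpec(low_hz=0.0, high_hz=100))


class TestNeoDetect:
    def test_planted_spike_found_once(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 10.0, int(2.0 * FS))
        w = spike_template(0.5, FS, pp_uv=150.0)
        i0 = int(1.0 * FS)
        x[i0 : i0 + len(w)] += w
        idx = neo_detect(x, FS)
        plant = i0 + np.argmin(w)
        near = idx[np.abs(idx - plant) <= 0.25e-3 * FS]
        assert len(near) == 1

    def test_noise_false_positive_rate(self):
        """On pure sigma=10 noise the default threshold admits < 1 event/s."""
        rates = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 10.0, int(30.0 * FS))
            rates.append(len(neo_detect(x, FS)) / 30.0)
        assert np.mean(rates) < 1.0

    def test_zero_signal_no_detections(self):
        assert len(neo_detect(np.zeros(1000), FS)) == 0

    def test_nonfinite_rejected(self):
        x = np.zeros(1000)
        x[10] = np.nan
        with pytest.raises(ValueError):
            neo_detect(x, FS)

    def test_dead_time_enforced(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 5.0, int(1.0 * FS))
        w = spike_template(0.4, FS, pp_uv=300.0)
        for i0 in (2000, 2000 + 400):  # two spikes 20 ms apart
            x[i0 : i0 + len(w)] += w
        idx = neo_detect(x, FS, dead_time_ms=1.0)
        assert np.all(np.diff(idx) >= int(1e-3 * FS))


class TestNoiseSigma:
    def test_definition_on_pure_noise(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 8.0, int(30 * FS))
        assert estimate_noise_sigma(x, np.array([]), FS) == pytest.approx(8.0, rel=0.02)

    def test_mean_centering(self):
        x = np.full(20000, 123.4)
        assert estimate_noise_sigma(x, np.array([]), FS) == pytest.approx(0.0, abs=1e-9)

    def test_spike_windows_excluded(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 8.0, int(30 * FS))
        base = estimate_noise_sigma(x, np.array([]), FS)
        y = x.copy()
        i0 = len(y) // 2
        y[i0 - 5 : i0 + 5] += 5000.0  # one huge spike inside its 1 ms window
        est = estimate_noise_sigma(y, np.array([i0]), FS)
        assert est == pytest.approx(base, rel=0.01)

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_sigma(np.zeros(10), np.arange(10), FS)


class TestSnrFormula:
    def _with_windows(self, rms_values, sigma):
        """Build a signal whose 1 ms spike windows have exactly the given
        RMS values (constant amplitude within the window)."""
        half = int(round(1e-3 / 2 * FS))
        x = np.zeros(int(FS))
        idx = []
        for k, r in enumerate(rms_values):
            i0 = 2000 + k * 800
            x[i0 - half : i0 + half + 1] = r
            idx.append(i0)
        return x, np.array(idx), sigma

    def test_unity_ratio_zero_db(self):
        x, idx, s = self._with_windows([5.0, 5.0], 5.0)
        assert snr_of_segment(x, idx, s, FS) == pytest.approx(0.0, abs=1e-9)

    def test_tenfold_ratio_twenty_db(self):
        x, idx, s = self._with_windows([50.0], 5.0)
        assert snr_of_segment(x, idx, s, FS) == pytest.approx(20.0, abs=1e-9)

    def test_mixed_windows_mean_of_rms(self):
        # mean RMS of {sigma, 3 sigma} -> 20 log10(2) = 6.0206 dB
        x, idx, s = self._with_windows([5.0, 15.0], 5.0)
        assert snr_of_segment(x, idx, s, FS) == pytest.approx(6.0206, abs=1e-3)

    def test_amplitude_scale_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 10, int(FS))
        w = spike_template(0.5, FS, pp_uv=200.0)
        x[5000 : 5000 + len(w)] += w
        idx = neo_detect(x, FS)
        s = estimate_noise_sigma(x, idx, FS)
        a = snr_of_segment(x, idx, s, FS)
        b = snr_of_segment(3 * x, idx, 3 * s, FS)
        assert a == pytest.approx(b, abs=1e-9)

    def test_no_spikes_flagged_not_error(self):
        assert np.isnan(snr_of_segment(np.zeros(100), np.array([]), 1.0, FS))

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            snr_of_segment(np.ones(100), np.array([50]), 0.0, FS)


class TestExclusionRules:
    def test_artifact_rule(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 10, (2, int(30 * FS) // 10))
        x[0, 500] = 1500.0
        assert exclude_segment(x, FS) == "artifact"

    def test_delta_rule(self):
        t = np.arange(int(30 * FS)) / FS
        x = 400.0 * np.sin(2 * np.pi * 3.0 * t)[None, :]
        assert exclude_segment(x, FS) == "delta"

    def test_clean_slow_wave_retained(self, small_layout, sparse_sim):
        rec, _ = simulate_recording([], small_layout, sparse_sim, 30.0, seed=7)
        assert exclude_segment(rec.samples, rec.fs_hz) is None


class TestSnrSeries:
    def test_pipeline_recovers_analytic_snr(self, small_layout):
        """Filter + NEO + SNR recovers the constructed SNR within 0.5 dB."""
        cfg = SimulationConfig(neuron_density_per_mm3=0.0, noise_sigma_uv=8.0,
                               lfp_amp_uv=0.0)
        rec, _ = simulate_recording([], small_layout, cfg, 30.0, seed=8)
        x = rec.samples[0].astype(np.float64)
        # plant 40 identical spikes on one channel
        w = spike_template(0.5, FS, pp_uv=250.0)
        plant = np.arange(40) * int(0.7 * FS) + 4000
        for i0 in plant:
            x[i0 : i0 + len(w)] += w
        filt = bandpass(x, FS)
        idx = neo_detect(filt, FS, k=20.0)  # high threshold: detections = plants
        sigma = estimate_noise_sigma(filt, idx, FS)
        got = snr_of_segment(filt, idx, sigma, FS)
        # analytic reference: the clean filtered template in 1 ms windows
        # at the detector's own alignment, over the known noise level
        clean = bandpass(x - rec.samples[0], FS)
        offset = int(neo_detect(clean, FS)[0]) - int(plant[0])
        ref_rms = spike_window_rms(clean, plant + offset, FS)
        expected = 20 * np.log10(np.mean(ref_rms) / sigma)
        assert got == pytest.approx(expected, abs=0.5)

    def test_segmentation_and_exclusion_reasons(self, small_layout):
        cfg = SimulationConfig(
            neuron_density_per_mm3=0.0,
            noise_sigma_uv=8.0,
            artifact_schedule=((40.0, 1500.0),),
            delta_episodes=((65.0, 92.0),),
        )
        rec, _ = simulate_recording([], small_layout, cfg, 95.0, seed=9)
        series = snr_series(rec)
        assert len(series.t_start_s) == 3  # tail dropped
        assert series.reasons[1] == "artifact"
        assert series.reasons[2] == "delta"
        assert np.isnan(series.channel_mean_db[1])

    def test_mismatched_channels_rejected(self, small_layout, sparse_sim):
        rec, _ = simulate_recording([], small_layout, sparse_sim, 30.0, seed=10)
        s1 = snr_series(rec)
        rec2 = RecordingSegment(rec.samples[:4], rec.fs_hz)
        s2 = snr_series(rec2)
        with pytest.raises(ValueError, match="channel"):
            snr_timecourse({0.002: [s1, s2]})
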