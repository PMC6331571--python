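"""Synthetic-data generator: populations, recordings, images, file formats."""

import numpy as np
import pytest
from scipy import stats as sstats

from probeqc.config import SimulationConfig
from probeqc.insertion import InsertionProtocol, mean_survival
from probeqc.io import read_recording, write_recording
from probeqc.population import simulate_population
from probeqc.recording import simulate_recording
from probeqc.sections import TrackRect, distance_to_track, render_section_image
from probeqc.templates import spike_template
from probeqc.units import violation_rate


class TestTemplates:
    @pytest.mark.parametrize("ttp", [0.3, 0.45, 0.65, 0.9])
    def test_planted_trough_to_peak_exact(self, ttp):
        fs = 20000.0
        w = spike_template(ttp, fs, pp_uv=200.0)
        i_tr = int(np.argmin(w))
        i_pk = i_tr + int(np.argmax(w[i_tr:]))
        assert (i_pk - i_tr) / fs * 1000.0 == pytest.approx(ttp, abs=1000.0 / fs)
        assert w.max() - w.min() == pytest.approx(200.0, rel=1e-6)


class TestPopulation:
    def test_zero_density_empty(self, small_layout):
        cfg = SimulationConfig(neuron_density_per_mm3=0.0)
        assert simulate_population(small_layout, InsertionProtocol(0.1), cfg, 0) == []

    def test_deterministic(self, small_layout, sparse_sim):
        a = simulate_population(small_layout, InsertionProtocol(0.1), sparse_sim, 7)
        b = simulate_population(small_layout, InsertionProtocol(0.1), sparse_sim, 7)
        assert len(a) == len(b)
        for u, v in zip(a, b):
            assert u.position_um == v.position_um
            assert u.survived == v.survived
            assert u.onset_time_s == v.onset_time_s
            assert np.array_equal(u.template, v.template)

    def test_class_construction(self, small_layout, sparse_sim):
        units = simulate_population(
            small_layout, InsertionProtocol(0.002), sparse_sim, 3
        )
        for u in units:
            if u.cell_class == "narrow":
                assert u.ttp_ms < 0.6
            else:
                assert u.ttp_ms >= 0.6

    def test_speed_dependent_survival_monte_carlo(self, small_layout, sparse_sim):
        """Expected surviving count within 50 um: slow > fast over many seeds.

        The oracle is the closed-form mean of the survival curve; the
        Monte-Carlo survivor fractions must straddle it accordingly.
        """
        counts = {0.002: [], 1.0: []}
        totals = {0.002: [], 1.0: []}
        for seed in range(120):
            for speed in counts:
                units = simulate_population(
                    small_layout, InsertionProtocol(speed), sparse_sim, seed
                )
                near = [u for u in units if u.position_um[0] <= 50.0]
                counts[speed].append(sum(u.survived for u in near))
                totals[speed].append(len(near))
        frac_slow = sum(counts[0.002]) / sum(totals[0.002])
        frac_fast = sum(counts[1.0]) / sum(totals[1.0])
        assert frac_slow > frac_fast
        assert frac_slow == pytest.approx(mean_survival(0, 50, 0.002), abs=0.02)
        assert frac_fast == pytest.approx(mean_survival(0, 50, 1.0), abs=0.03)


class TestRecording:
    def test_noise_only_sigma(self, small_layout):
        cfg = SimulationConfig(
            neuron_density_per_mm3=0.0, noise_sigma_uv=10.0, lfp_amp_uv=0.0
        )
        rec, spikes = simulate_recording([], small_layout, cfg, 30.0, seed=0)
        assert spikes == {}
        sd = rec.samples.std(axis=1)
        assert np.allclose(sd, 10.0, rtol=0.02)

    def test_single_unit_reference_amplitude(self, small_layout):
        """A unit 1 um from a site shows its full template amplitude there."""
        cfg = SimulationConfig(neuron_density_per_mm3=0.0, noise_sigma_uv=0.0,
                               lfp_amp_uv=0.0)
        from probeqc.population import GroundTruthUnit

        site_depth = small_layout.site_positions[3, 1]
        unit = GroundTruthUnit(
            unit_id=0, position_um=(1.0, site_depth), cell_class="wide",
            ttp_ms=0.9, pp_ref_uv=200.0, rate_up_hz=8.0, survived=True,
            onset_time_s=0.0, template=spike_template(0.9, cfg.fs_hz, 200.0),
        )
        rec, spikes = simulate_recording([unit], small_layout, cfg, 20.0, seed=1)
        assert len(spikes[0]) > 5
        pp = rec.samples[3].max() - rec.samples[3].min()
        assert pp == pytest.approx(200.0, rel=0.02)

    def test_ground_truth_bookkeeping_and_refractory(self, short_recording):
        rec, spikes, units = short_recording
        by_id = {u.unit_id: u for u in units}
        assert sum(len(t) for t in spikes.values()) > 0
        for uid, times in spikes.items():
            assert np.array_equal(times, by_id[uid].spike_times_s)
            assert np.all(np.diff(times) > 0)
            if not by_id[uid].survived:
                assert len(times) == 0
            # absolute refractory period enforced by construction
            if len(times) > 1:
                assert violation_rate(times) == 0.0

    def test_deterministic(self, small_layout, sparse_sim):
        units_a = simulate_population(small_layout, InsertionProtocol(0.1), sparse_sim, 5)
        rec_a, _ = simulate_recording(units_a, small_layout, sparse_sim, 31.0, seed=6)
        units_b = simulate_population(small_layout, InsertionProtocol(0.1), sparse_sim, 5)
        rec_b, _ = simulate_recording(units_b, small_layout, sparse_sim, 31.0, seed=6)
        assert np.array_equal(rec_a.samples, rec_b.samples)

    def test_too_short_duration_rejected(self, small_layout, sparse_sim):
        units = simulate_population(small_layout, InsertionProtocol(0.1), sparse_sim, 5)
        with pytest.raises(ValueError):
            simulate_recording(units, small_layout, sparse_sim, 0.003, seed=0)


class TestRecordingIO:
    def test_round_trip_within_half_count(self, short_recording, tmp_path):
        rec, _, _ = short_recording
        path = write_recording(tmp_path / "rec", rec, layout_id="linear32[:8]")
        back, meta = read_recording(tmp_path / "rec")
        assert back.samples.shape == rec.samples.shape
        assert meta["layout_id"] == "linear32[:8]"
        # half a quantization step, plus float32 representation slack
        assert np.max(np.abs(back.samples - rec.samples)) <= 0.5 * meta[
            "uv_per_count"
        ] + 1e-4

    def test_gain_scales_counts(self, small_layout):
        cfg = SimulationConfig(neuron_density_per_mm3=0.0, noise_sigma_uv=20.0,
                               lfp_amp_uv=0.0)
        rec, _ = simulate_recording([], small_layout, cfg, 1.0, seed=2)
        import numpy as np

        counts1 = np.round(rec.samples / 0.195)
        counts2 = np.round(rec.samples / 0.390)
        # doubling the gain halves the integer representation
        assert np.abs(counts2 - counts1 / 2).max() <= 1.0

    def test_truncated_binary_rejected(self, short_recording, tmp_path):
        rec, _, _ = short_recording
        path = write_recording(tmp_path / "rec", rec)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError, match="metadata"):
            read_recording(tmp_path / "rec")


class TestSectionImages:
    def test_total_deficit_excludes_near_track(self):
        track = TrackRect(300.0, 300.0)
        sec = render_section_image(
            (600.0, 600.0), 2.0, track, 2000.0,
            lambda d: np.where(np.asarray(d) < 40.0, 0.0, 1.0), seed=0,
        )
        d = distance_to_track(
            sec.planted_centroids_um[:, 0], sec.planted_centroids_um[:, 1], track
        )
        assert np.all(d >= 40.0)

    def test_uniform_field_is_uniform(self):
        """No-damage control: planted positions pass a chi-squared
        uniformity test over a coarse grid for nearly all seeds."""
        n_pass = 0
        seeds = 40
        for seed in range(seeds):
            sec = render_section_image(
                (600.0, 600.0), 2.0, TrackRect(300.0, 300.0), 3000.0, None, seed
            )
            c = sec.planted_centroids_um
            hist, _, _ = np.histogram2d(c[:, 0], c[:, 1], bins=4,
                                        range=[[0, 600], [0, 600]])
            p = sstats.chisquare(hist.ravel()).pvalue
            n_pass += p > 0.01
        assert n_pass >= int(0.95 * seeds) - 1

    def test_deterministic_bytes(self):
        kw = dict(size_um=(300.0, 300.0), scale_um_per_px=2.0,
                  track=TrackRect(150.0, 150.0), density_per_mm2=1000.0,
                  deficit=None, seed=9)
        a = render_section_image(kw["size_um"], kw["scale_um_per_px"], kw["track"],
                                 kw["density_per_mm2"], kw["deficit"], kw["seed"])
        b = render_section_image(kw["size_um"], kw["scale_um_per_px"], kw["track"],
                                 kw["density_per_mm2"], kw["deficit"], kw["seed"])
        assert a.pixels.tobytes() == b.pixels.tobytes()

    def test_invalid_deficit_rejected(self):
        with pytest.raises(ValueError, match="deficit"):
            render_section_image(
                (300.0, 300.0), 2.0, TrackRect(150.0, 150.0), 500.0,
                lambda d: np.full_like(np.asarray(d, dtype=float), 1.5), seed=0,
            )

    def test_far_field_density_matches_poisson(self):
        dens = 2000.0
        counts = []
        for seed in range(30):
            sec = render_section_image(
                (500.0, 500.0), 2.0, TrackRect(250.0, 250.0), dens, None, seed
            )
            counts.append(len(sec.planted_centroids_um))
        expected = dens * 0.25
        assert np.mean(counts) == pytest.approx(expected, rel=0.05)


class TestSectionImageIO:
    def test_round_trip(self, tmp_path):
        from probeqc.sections import (
            TrackRect,
            read_section_image,
            render_section_image,
            write_section_image,
        )

        sec = render_section_image(
            (300.0, 300.0), 2.0, TrackRect(150.0, 150.0, angle_deg=20.0),
            1500.0, None, seed=3,
        )
        write_section_image(tmp_path / "sec", sec)
        back = read_section_image(tmp_path / "sec")
        assert np.array_equal(back.pixels, sec.pixels)
        assert back.scale_um_per_px == sec.scale_um_per_px
        assert back.track == sec.track
        assert np.allclose(back.planted_centroids_um, sec.planted_centroids_um)


class TestOnsetLatency:
    def test_speed_dependent_onset_medians(self, small_layout, sparse_sim):
        """Units start firing earlier after slow insertion: the median
        onset latency at 0.002 mm/s sits below the one at 1 mm/s over
        hundreds of seeded units."""
        onsets = {0.002: [], 1.0: []}
        for seed in range(30):
            for speed in onsets:
                units = simulate_population(
                    small_layout, InsertionProtocol(speed), sparse_sim, seed + 500
                )
                onsets[speed].extend(u.onset_time_s for u in units)
        assert len(onsets[0.002]) >= 100
        assert np.median(onsets[0.002]) < np.median(onsets[1.0])
        # exponential-law means sit near their configured values
        assert np.mean(onsets[0.002]) == pytest.approx(110.9, rel=0.15)
        assert np.mean(onsets[1.0]) == pytest.approx(294.4, rel=0.15)
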