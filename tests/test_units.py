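"""Single-unit metrics, isolation distance, waveform classification."""

import numpy as np
import pytest

from probeqc.templates import spike_template
from probeqc.units import (
    average_waveform,
    classify_units,
    extract_snippets,
    first_spike_latency,
    isolation_distance,
    peak_to_peak,
    trough_to_peak,
    unit_metrics_table,
    violation_rate,
    waveform_features,
)

FS = 20000.0


class TestAverageWaveform:
    def test_identity_and_symmetry(self):
        w = np.random.default_rng(0).normal(size=(1, 2, 40))
        assert np.array_equal(average_waveform(w), w[0])
        sym = np.stack([w[0], -w[0]])
        assert np.allclose(average_waveform(sym), 0.0)

    def test_clt_convergence(self):
        rng = np.random.default_rng(1)
        template = spike_template(0.6, FS, 120.0)[None, :]
        snips = template[None, :, :] + rng.normal(0, 5.0, (1000, 1, len(template[0])))
        mean = average_waveform(snips)
        assert np.all(np.abs(mean - template) < 3 * 5.0 / np.sqrt(1000) + 1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_waveform(np.empty((0, 2, 10)))


class TestPeakToPeak:
    def test_flat_zero(self):
        assert peak_to_peak(np.zeros((3, 20)))[0] == 0.0

    def test_arithmetic(self):
        w = np.zeros((1, 30))
        w[0, 10], w[0, 20] = -100.0, 80.0
        pp, best = peak_to_peak(w)
        assert pp == 180.0 and best == 0

    def test_best_channel_tie_breaks_low(self):
        w = np.zeros((3, 30))
        w[1, 5], w[2, 5] = 50.0, 50.0
        assert peak_to_peak(w)[1] == 1


class TestViolationRate:
    def test_clean_train(self):
        assert violation_rate(np.arange(100) * 0.010) == 0.0

    def test_hand_count(self):
        # 10 spikes, exactly two ISIs of 1 ms -> 20%
        t = np.concatenate([[0.0, 0.001], [0.1, 0.101], np.arange(6) * 0.05 + 1.0])
        assert violation_rate(np.sort(t)) == pytest.approx(20.0)

    def test_boundary_is_not_violation(self):
        # "within 2 ms" implemented as strict <; an ISI of exactly 2 ms passes
        t = np.array([0.0, 0.002, 0.004])
        assert violation_rate(t) == 0.0
        t = np.array([0.0, 0.0019999])
        assert violation_rate(t) == pytest.approx(50.0)

    def test_empty_flagged(self):
        assert np.isnan(violation_rate(np.array([])))


class TestFirstSpikeLatency:
    def test_arithmetic(self):
        assert first_spike_latency(np.array([12.5, 20.0]), 0.0) == 12.5
        assert first_spike_latency(np.array([5.0]), 5.0) == 0.0
        assert np.isnan(first_spike_latency(np.array([])))

    def test_translation_invariance_of_metrics(self):
        t = np.sort(np.random.default_rng(2).uniform(0, 10, 50))
        assert violation_rate(t) == violation_rate(t + 123.0)
        assert first_spike_latency(t, 0.0) == pytest.approx(
            first_spike_latency(t + 123.0, 123.0)
        )


def brute_force_isolation(features, labels, target):
    """O(N^2) oracle: explicit Mahalanobis to every outside event."""
    inside = features[labels == target]
    outside = features[labels != target]
    n_c = len(inside)
    if n_c > len(features) // 2 or n_c < features.shape[1] + 2:
        return np.nan
    if len(outside) < n_c:
        return np.nan
    mu = inside.mean(axis=0)
    cinv = np.linalg.inv(np.cov(inside, rowvar=False))
    d = np.array([float((o - mu) @ cinv @ (o - mu)) for o in outside])
    return np.sort(d)[n_c - 1]


class TestIsolationDistance:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            n_c = rng.integers(20, 120)
            n_o = rng.integers(n_c + 5, 380)
            dims = rng.integers(2, 6)
            sep = rng.uniform(1, 10)
            f = np.vstack([
                rng.normal(0, 1, (n_c, dims)),
                rng.normal(sep, 1.5, (n_o, dims)),
            ])
            labels = np.array([0] * n_c + [1] * n_o)
            got = isolation_distance(f, labels, 0)
            want = brute_force_isolation(f, labels, 0)
            assert got == pytest.approx(want, rel=1e-9)

    def test_separated_beats_overlapping(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (100, 2))
        overlap = np.vstack([a, rng.normal(0, 1, (150, 2))])
        apart = np.vstack([a, rng.normal(10, 1, (150, 2))])
        labels = np.array([0] * 100 + [1] * 150)
        assert isolation_distance(apart, labels, 0) > isolation_distance(
            overlap, labels, 0
        )

    def test_majority_cluster_undefined(self):
        rng = np.random.default_rng(5)
        f = rng.normal(size=(100, 2))
        labels = np.array([0] * 60 + [1] * 40)
        assert np.isnan(isolation_distance(f, labels, 0))


class TestTroughToPeak:
    @pytest.mark.parametrize("ttp", [0.3, 0.9])
    def test_planted_duration(self, ttp):
        w = spike_template(ttp, FS, 150.0)
        assert trough_to_peak(w, FS) == pytest.approx(ttp, abs=1000.0 / FS)

    def test_monotone_decay_unclassifiable(self):
        w = np.concatenate([[-100.0], np.linspace(-99, -1, 50)])
        assert np.isnan(trough_to_peak(w, FS))


class TestClassification:
    def test_printed_narrow_fraction(self):
        # 34 narrow of 220 classified -> 15.45%
        ttp = np.concatenate([np.full(34, 0.4), np.full(186, 0.8)])
        res = classify_units(ttp, dip_reps=50, seed=0)
        assert (res.labels == "narrow").sum() == 34
        assert res.narrow_fraction_pct == pytest.approx(15.45, abs=0.01)

    def test_threshold_boundary_is_wide(self):
        res = classify_units(np.array([0.6] * 10), dip_reps=50, seed=0)
        assert set(res.labels) == {"wide"}

    def test_unimodal_all_narrow(self):
        res = classify_units(np.full(50, 0.3), dip_reps=100, seed=1)
        assert res.narrow_fraction_pct == 100.0
        assert res.dip_p > 0.05  # degenerate unimodal sample: no dip evidence

    def test_bimodal_mixture_detected(self):
        from probeqc.stats import dip_null_distribution

        null = dip_null_distribution(200, reps=300, seed=42)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ttp = np.concatenate([
                rng.normal(0.35, 0.05, 100), rng.normal(0.9, 0.1, 100)
            ])
            res = classify_units(ttp, seed=seed, dip_reps=0,)
            from probeqc.stats import dip_test

            _, p = dip_test(ttp, null_dips=null)
            hits += p < 0.01
        assert hits >= 19  # >= 95% of seeds


class TestMetricsTable:
    def test_ground_truth_pipeline(self, short_recording):
        rec, spikes, units = short_recording
        df = unit_metrics_table(rec, spikes, t0_s=rec.t0_s)
        assert not df.empty
        iso = df[df["well_isolated"]]
        assert (iso["peak_to_peak_uv"] > 60.0).all()
        assert (iso["violation_pct"] < 2.0).all()
        # refractory enforced by the simulator: violations are exactly 0
        assert (df["violation_pct"].dropna() == 0.0).all()
        # every unit with spikes got a latency
        assert df.loc[df["n_spikes"] > 0, "first_latency_s"].notna().all()

    def test_isolation_criteria_drive_well_isolated(self, short_recording):
        rec, spikes, _ = short_recording
        df = unit_metrics_table(rec, spikes)
        bad = df[~df["well_isolated"]]
        assert (
            bad["exclusion_reason"].isin(
                ["low_amplitude", "refractory", "no_spikes", "too_few_spikes"]
            )
        ).all()
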