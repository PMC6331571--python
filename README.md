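# probeqc

Quantifying how the **insertion speed** of a rigid silicon probe affects
the quality of acute extracellular recordings — and, through histology,
the survival of neurons around the probe track.

Inserting a probe into cortex injures neurons along the path. Because
recorded spike amplitude falls off steeply with distance, the neurons
within ~50 µm of the recording sites (the *single-unit zone*) determine
how many units a penetration yields and how clean the multi-unit band
looks. `probeqc` implements the complete quantitative pipeline for
comparing insertion speeds (0.002–1 mm/s) in this setting:

* **Multi-unit SNR** — 500–5000 Hz zero-phase band-pass, spike detection
  with the smoothed nonlinear energy operator
  ψ(n) = x(n)² − x(n−1)·x(n+1) thresholded at k·mean(ψ), noise as the
  RMS of mean-centered samples outside 1 ms spike windows, and per
  30 s segment and channel

  SNR_dB = 20·log₁₀[ (1/N)·Σₙ RMS(spikeₙ) / σ̂_noise ],

  with artifact (>1 mV), delta-wave (2–4 Hz) and noise-outlier segment
  exclusion and grand-average time courses per speed.
* **Single-unit metrics** — best-channel peak-to-peak amplitude,
  refractory violation rate (< 2 ms ISIs), first-spike latency,
  isolation distance (Mahalanobis, n_c-th closest outside event), and
  trough-to-peak-based narrow/wide classification at 0.6 ms with
  Hartigan's dip test of bimodality. A unit is *well isolated* iff
  peak-to-peak > 60 µV and violation rate < 2%.
* **Peri-track neuron density** — soma detection on NeuN-like section
  images, 20 × 100 µm² binned density profiles out to 400 µm
  (normalized to the 160–400 µm region), and the SU-zone (0–50 µm) /
  control-zone (50–100 µm) density ratio.
* **Group statistics** — Kruskal–Wallis with Dunn/Bonferroni post-hoc,
  Mann–Whitney U, χ², t/ANOVA, Pearson correlation.
* **A ground-truth simulator** — neurons around a 128-site dense array
  or 32-site linear probe, with a speed-and-distance survival curve,
  speed-dependent firing-onset latencies, slow-wave-gated firing,
  distance-attenuated spike waveforms, delta episodes and artifacts —
  so every analysis stage is testable against planted truth, and whole
  virtual experiments (simulate → analyze → compare → report) run in
  minutes. See `docs/methods.md` for the models and calibrations.

## Worked example

The numbered scripts under `analysis/` tell the story end to end; each
writes its tables under `results/`. With the shipped seeds:

```text
$ python analysis/01_simulate_recordings.py
0.002 mm/s: 66 neurons simulated, 66 survived, 9069 spikes in 60 s
1 mm/s: 62 neurons simulated, 57 survived, 7274 spikes in 60 s

$ python analysis/02_snr_timecourse.py
0.002 mm/s: 2 segments (0 excluded), channel-mean SNR 11.91 dB
1 mm/s: 2 segments (0 excluded), channel-mean SNR 8.86 dB

$ python analysis/03_unit_metrics.py
0.002 mm/s: 66 units with spikes, 24 well isolated, mean peak-to-peak 139 uV, median first-spike latency 3.18 s
1 mm/s: 57 units with spikes, 13 well isolated, mean peak-to-peak 91 uV, median first-spike latency 4.40 s
pooled: 37 classified units, 18.9% narrow (putative interneurons); dip = 0.0676, p = 0.1896

$ python analysis/04_cell_density.py
control: pooled zone ratio 100.5% (per-section 102 +- 33 %, 1269 somata/section)
fast: pooled zone ratio 82.1% (per-section 84 +- 28 %, 1260 somata/section)
slow: pooled zone ratio 100.0% (per-section 102 +- 33 %, 1268 somata/section)
```

Reading this: the fast insertion kills a fraction of the neurons within
~50 µm of the shank (62 → 57 survivors here; the loss is concentrated
near the probe), which shows up as a ~3 dB lower multi-unit SNR, half
the well-isolated unit yield with smaller spikes (91 vs 139 µV), later
first spikes, and an ~18% neuron-density deficit in the SU zone of the
matching sections — while the slow insertion is indistinguishable from
the undamaged control (ratio ≈ 100%). A single penetration pair is
noisy; `analysis/05_virtual_experiment.py` runs the full two-speed
virtual experiment (8 penetrations per speed) and prints the
group-level unit summary and statistics:

```text
$ python analysis/05_virtual_experiment.py
mean segment SNR (dB):         0.002 mm/s: 10.85    1 mm/s: 10.37
units per penetration:         0.002 mm/s: 16.6     1 mm/s: 10.4
SU/control zone ratio (%):     0.002 mm/s: 93.8     1 mm/s: 76.1

group statistics:
          test              variable    groups      n  statistic        p
kruskal_wallis            unit_yield 0.002;1.0    8;8       6.42  1.1e-02
kruskal_wallis       first_latency_s 0.002;1.0 133;83      40.13  2.4e-10
kruskal_wallis    isolation_distance 0.002;1.0 133;83       4.54  3.3e-02
        t_test        zone_ratio_pct 0.002;1.0    8;8       3.13  7.4e-03
       pearson yield_vs_zone_density       all     16       0.64  8.2e-03
```

The slow insertion yields significantly more units per penetration,
units start firing earlier, clusters separate better, significantly
more neurons survive in the SU zone (93.8% vs 76.1% of the control
density), and penetrations with more surviving neurons yield more units
(r = 0.64).

The same stages are available as a CLI (`probeqc simulate`,
`probeqc analyze-snr`, `probeqc analyze-units`,
`probeqc analyze-histology`, `probeqc run`, `probeqc speed-sequence`)
over the documented on-disk formats: int16 binary + JSON recordings,
CSV spike/unit tables, TIFF + JSON section images.

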