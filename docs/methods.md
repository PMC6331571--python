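# Methods

`probeqc` quantifies the quality of acute extracellular recordings as a
function of the speed at which a rigid silicon probe was inserted into
cortex, and ships a synthetic-data generator that emulates
insertion-speed-dependent tissue damage so that every analysis stage can
be validated against planted ground truth. This note documents the
models, their parameters and the choices made where the design was
genuinely open.

## The damage model

The central object is a per-neuron survival probability after insertion,
logistic in the neuron's lateral distance $d$ (µm) from the shank
surface with a speed-dependent midpoint:

$$p(d, s) = \frac{1}{1 + e^{-(d - \mu(s))/w}},\qquad
\mu(s) = \mu_1 + \beta \log_{10}(s/1\,\mathrm{mm\,s^{-1}})$$

with defaults $\mu_1 = 8$ µm, $\beta = 14.08$ µm/decade, $w = 10$ µm.
These constants are calibrated so that the mean survival over the first
50 µm (the *single-unit zone*) is ≈ 0.99 at 0.002 mm/s and ≈ 0.77 at
1 mm/s, matching the reported SU-zone/control-zone density ratios
(98.6% vs 76.8%) for the slowest and fastest insertions. Survival is
monotone in both arguments and approaches 1 far from the shank.

Two further speed-dependent mechanisms complete the model:

* **Onset latency.** Each surviving neuron resumes firing after an
  exponentially distributed latency whose mean is
  $110.9 + 68.0\,\log_{10}(s/0.002)$ seconds — reproducing the observed
  group means at the two extreme speeds (110.9 s and 294.4 s). The two
  intermediate speeds land at 179 s and 226 s versus observed 209.5 s
  and 210.8 s; a two-parameter log-linear law cannot match all four
  reported means, and we prioritize the endpoints. In reduced-duration
  runs the latencies are scaled by `duration / 2700 s` so the latency
  structure occupies the same fraction of the recording.
* **Per-penetration damage variability.** A zero-mean Gaussian shift
  (SD 10 µm) of the survival midpoint is drawn once per penetration and
  applied to both the recording simulation and that penetration's
  histology sections. This reproduces the large insertion-to-insertion
  spread of unit yields (reported relative SDs of 31–36%) and makes the
  per-penetration yield and peri-track density share a common cause —
  which is what gives the yield-vs-density correlation its strength in
  real data (insertions differ in dimpling and vascular damage).

## The recording simulator

Neurons are placed by a homogeneous Poisson process (default
25,000/mm³) in a slab extending 100 µm laterally from the shank.
Spike amplitudes decay exponentially with distance
($\lambda = 28$ µm from a 1 µm reference), so a median-amplitude unit
falls below the 60 µV isolation criterion beyond roughly 50 µm — only
the SU-zone neurons are isolable, which is the premise of the
density-vs-yield comparison. Waveforms are biphasic raised-cosine
templates whose trough-to-peak time is exact by construction
(narrow-spiking cells drawn in 0.30–0.45 ms, wide in 0.65–1.10 ms, 15%
narrow by default).

Firing is an inhomogeneous point process gated by a shared two-state
semi-Markov up/down alternation (~1 Hz, 50% up fraction), the
anesthesia-like slow wave: units fire at their up-state rate (median
4 Hz, lognormal spread) during up states and at 5% of it during down
states, with a 2 ms absolute refractory period enforced on the
quantized spike times. The trace additionally carries a slow-wave LFP
component (smoothed up-state indicator, 150 µV), optional scheduled
delta episodes (a 2–4 Hz high-amplitude oscillation with sinusoidally
gated firing), optional >1 mV artifact transients, and white Gaussian
noise (12 µV SD). Sampling is 20 kHz; on disk, recordings are int16
channel-major binary at 0.195 µV/count with a JSON sidecar.

Amplitude (180 µV median reference peak-to-peak, lognormal σ = 0.4) and
density defaults were calibrated against the reported single-unit
tables: simulated well-isolated units have peak-to-peak means of
~110–140 µV (reported: 127–182 µV), per-penetration yields with a
slow/fast ratio near 2 (reported: 2.2–2.4), and segment SNRs of
~10–11 dB (reported time courses: ~6–9 dB).

What the generator does **not** emulate: biophysical waveform diversity
(bursting, amplitude adaptation), electrode drift, spatially correlated
noise, spike collisions/overlap at the waveform level beyond linear
summation, blood-vessel topology, or dimpling mechanics. Passing tests
therefore demonstrate that the *analysis* is correct against a
controlled ground truth, not that the simulator reproduces every
property of in vivo data.

## SNR pipeline

Wideband traces are band-pass filtered at 500–5000 Hz with a 4th-order
Butterworth (≈24 dB/octave) applied forward–backward (zero phase,
reflective padding). Spikes are detected with the nonlinear energy
operator $\psi(n) = x(n)^2 - x(n{-}1)\,x(n{+}1)$, smoothed with a
0.5 ms Bartlett window, thresholded at $k = 8$ times its mean, with a
1 ms dead time — the smoothing window, threshold multiplier and dead
time are config-exposed since the upstream description names the
method but not its constants. Noise is the RMS of mean-centered
samples outside 1 ms windows around detections, and per 30 s segment
and channel

$$\mathrm{SNR_{dB}} = 20 \log_{10}
\frac{\tfrac1N\sum_n \mathrm{RMS(spike}_n)}{\hat\sigma_{noise}}.$$

Segments are excluded when any wideband sample exceeds 1 mV
(artifact), when the 2–4 Hz fraction of 0.5–10 Hz wideband power
exceeds 0.5 (delta episodes; the quantitative criterion is an
operational stand-in for a by-inspection rule and is config-exposed),
or when the segment's noise SD exceeds 3× the median across segments
(high-frequency noise). A trailing partial segment is dropped. Channel
means are averaged across penetrations of the same speed, aligned on
segment index, to give the grand-average time course.

## Single-unit metrics

Metrics operate on spike times plus waveform snippets (2 ms pre/post
trough) and accept any sorter's output; in the virtual experiments the
simulator's exact assignments stand in for curated sorting. A unit is
*well isolated* iff its best-channel mean-waveform peak-to-peak exceeds
60 µV and under 2% of its spikes are followed by another within 2 ms
("within 2 ms" is implemented as a strict inequality; a 2.000 ms ISI is
clean). Peak-to-peak uses only the channel with the largest amplitude
(ties to the lowest index). Isolation distance is the squared
Mahalanobis distance — under the cluster's own covariance, ridge-
regularized if singular — of the $n_c$-th closest outside event; it is
undefined when the cluster holds more than half of all events or fewer
than dims + 2. The feature space is three principal components per
channel over the units' best channels (config-exposed). Trough-to-peak
time runs from the global trough to the largest subsequent interior
local maximum; waveforms without one are unclassified. Narrow-spiking
(putative interneuron) means trough-to-peak < 0.6 ms; exactly 0.6 ms
classifies wide.

## Histology

Synthetic sections place somata by a thinned Poisson process (the
thinning field is the survival curve around a 100 × 10 µm² track
rectangle) and render them as ~4.5 µm radius raised-cosine blobs on a
noisy background. Detection is deliberately simple — Gaussian smooth,
threshold, connected components, area filter — with every parameter
exposed; the default threshold sits a bit above half the soma peak so
touching somata split. Validation is against planted centroids only;
merged somata under the separation limit are a documented undercount.

Distance is measured from the nearest long edge of the track, bins are
half-open 20 µm intervals over 0–400 µm on each side (within the
100 µm track-length band), densities are normalized per side to the
mean density of the 160–400 µm bins and then averaged across sides
(normalizing before averaging; the alternative order is exposed via the
per-side table). The SU/control zone ratio pools both sides over
0–50 µm and 50–100 µm. In the virtual experiment, zone ratios are
additionally pooled across a penetration's sections *before* the ratio
is formed — the ratio of pooled densities is far better behaved than
the mean of small-count ratios.

## Statistics

Kruskal–Wallis (omnibus) with Dunn's rank-sum z post-hoc and Bonferroni
correction over all pairs (run only when the omnibus rejects at
α = 0.05); Mann–Whitney U (exact for small tie-free samples) for
two-group designs; a two-tailed Pearson χ² for cell-class proportions;
Student's t and one-way ANOVA for the density comparisons; Pearson's r
for the yield-density association. The Dunn z uses the standard tie
correction (the variant is a convention; none is named upstream).

Hartigan's dip statistic is implemented from its defining minimax
problem: the dip is the smallest band half-width admitting a unimodal
(convex-then-concave, atom allowed at the mode) cdf. We minimize over
the mode's position among the order statistics — any interior-mode
solution converts to one of this form — with two closed-form hull
deviation thresholds per mode and a junction feasibility condition
resolved by bisection. The implementation is cross-validated against a
linear-programming oracle of the same minimax problem (exact on all
generic and cluster configurations tested at numerically safe scales).
P-values are Monte-Carlo calibrated against uniform samples of the same
size (2000 replicates by default); null tables can be shared across
tests of equal sample size.

## The virtual experiment

`run_virtual_experiment` mirrors the in-vivo design: penetrations per
speed with balanced insertion-order randomization, one recording per
penetration analyzed for SNR and unit metrics, sections per penetration
quantified for density, and the group statistics over everything. The
default reduced scale (two speeds — slowest and fastest, as in the
thin-probe experiment — 8 penetrations per speed, 90 s recordings on an
8-channel subset of the linear probe, 3 sections per penetration) was
sized so that each directional effect of the damage model (SNR, yield,
zone ratio, yield-density correlation) is resolvable in a single seeded
run; `ExperimentConfig.full_scale()` restores 45-minute full-array
penetrations. All randomness derives from one master seed through
per-stage `SeedSequence` substreams; identical configurations produce
byte-identical outputs.

## Known limitations

* The dip implementation can exceed the true dip on adversarial samples
  whose internal spacing ratios reach ~10⁶ (where the LP reference is
  itself ill-conditioned); the MC calibration uses the same statistic
  on both sides, so the test stays internally consistent.
* The soma detector undercounts merging somata at high density; the
  experiment's rendering regime keeps the planted-vs-detected zone
  ratios faithful, but raw recovery is ~90%, not 100%.
* Simulated SNR levels run ~1–2 dB above the reported time courses;
  group *differences* are the quantity the pipeline is designed to
  resolve.
* The full-scale configuration (128 channels × 45 min) is memory- and
  time-hungry (tens of GB equivalents if materialized at once) and is
  provided for completeness, not used by the test suite.
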