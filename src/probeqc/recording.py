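"""Multi-channel voltage synthesis with exact spike ground truth.

Surviving units fire an inhomogeneous point process gated by a shared
~1 Hz up/down state sequence; each spike is pasted onto every recording
site, scaled by the exponential distance attenuation; Gaussian noise, a
slow-wave LFP component, scheduled 2-4 Hz delta episodes and >1 mV
artifact transients complete the trace.  The spike times returned are the
exact (sample-quantized) ground truth, with an absolute refractory period
enforced by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import SimulationConfig
from .population import GroundTruthUnit
from .probes import ProbeLayout
from .templates import TROUGH_OFFSET_MS

__all__ = ["RecordingSegment", "simulate_recording", "up_down_states"]

#: units contributing less than this peak-to-peak on a site are skipped
MIN_SITE_PP_UV = 1.0


@dataclass
class RecordingSegment:
    """A block of sampled multi-channel voltage.

    ``samples`` is a (channels x time) float array in microvolts;
    ``t0_s`` is the offset of the first sample from probe arrival at
    depth.
    """

    samples: np.ndarray
    fs_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.samples.ndim != 2:
            raise ValueError("samples must be (channels, time)")
        if self.fs_hz <= 2 * 5000:
            raise ValueError("sampling rate must exceed twice the 5 kHz band edge")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def up_down_states(duration_s: float, config: SimulationConfig, rng) -> np.ndarray:
    """Alternating up/down state boundaries as an array of change times.

    Returns ``t_bounds`` with t_bounds[0] = 0; the state on
    [t_bounds[2i], t_bounds[2i+1]) is *up*.  Durations are exponential
    with means up_state_fraction / rate and (1 - fraction) / rate, a
    two-state semi-Markov alternation averaging one cycle per
    1 / slow_wave_rate_hz seconds.
    """
    mean_up = config.up_state_fraction / config.slow_wave_rate_hz
    mean_down = (1.0 - config.up_state_fraction) / config.slow_wave_rate_hz
    bounds = [0.0]
    t = 0.0
    up = True
    while t < duration_s:
        t += rng.exponential(mean_up if up else mean_down)
        bounds.append(min(t, duration_s))
        up = not up
    return np.asarray(bounds)


def _is_up(times: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(bounds, times, side="right") - 1
    return idx % 2 == 0


def _delta_mask(times: np.ndarray, episodes) -> np.ndarray:
    m = np.zeros(len(times), dtype=bool)
    for start, end in episodes:
        m |= (times >= start) & (times < end)
    return m


def _unit_spike_samples(
    unit: GroundTruthUnit,
    duration_s: float,
    bounds: np.ndarray,
    config: SimulationConfig,
    rng,
) -> np.ndarray:
    """Sample indices of one unit's spikes (thinned, refractory-enforced)."""
    if not unit.survived or unit.onset_time_s >= duration_s:
        return np.empty(0, dtype=np.int64)
    n_cand = rng.poisson(unit.rate_up_hz * duration_s)
    t_cand = np.sort(rng.uniform(0.0, duration_s, n_cand))
    keep_p = np.where(
        _is_up(t_cand, bounds), 1.0, config.rate_down_fraction
    )
    if config.delta_episodes:
        in_delta = _delta_mask(t_cand, config.delta_episodes)
        gate = 0.5 * (1.0 + np.sin(2.0 * np.pi * config.delta_freq_hz * t_cand))
        keep_p = np.where(in_delta, gate, keep_p)
    t_spk = t_cand[(rng.random(n_cand) < keep_p) & (t_cand >= unit.onset_time_s)]
    samples = np.round(t_spk * config.fs_hz).astype(np.int64)
    # refractory: strictly more than refractory_ms between quantized spikes
    min_gap = int(np.ceil(config.refractory_ms / 1000.0 * config.fs_hz)) + 1
    kept = []
    last = -min_gap
    for s in samples:
        if s - last >= min_gap:
            kept.append(s)
            last = s
    return np.asarray(kept, dtype=np.int64)


def simulate_recording(
    units: list[GroundTruthUnit],
    layout: ProbeLayout,
    config: SimulationConfig,
    duration_s: float,
    seed,
) -> tuple[RecordingSegment, dict[int, np.ndarray]]:
    """Synthesize one penetration's voltage traces plus exact ground truth.

    Returns the recording and a mapping unit_id -> spike times (s).  The
    same times are stored on each unit's ``spike_times_s``.
    """
    template_s = max((len(u.template) for u in units), default=0) / config.fs_hz
    if duration_s <= template_s:
        raise ValueError("duration must exceed the spike template length")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng_state, rng_spk, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    fs = config.fs_hz
    n_t = int(round(duration_s * fs))
    n_ch = layout.n_channels
    x = np.zeros((n_ch, n_t), dtype=np.float32)

    bounds = up_down_states(duration_s, config, rng_state)
    trough_off = int(round(TROUGH_OFFSET_MS * fs / 1000.0))

    spike_times: dict[int, np.ndarray] = {}
    site_pos = layout.site_positions
    for unit in units:
        spk = _unit_spike_samples(unit, duration_s, bounds, config, rng_spk)
        # keep only spikes whose full template fits in the trace
        n_w = len(unit.template)
        spk = spk[(spk >= trough_off) & (spk + (n_w - trough_off) < n_t)]
        times = spk / fs
        unit.spike_times_s = times
        spike_times[unit.unit_id] = times
        if not len(spk):
            continue
        lat, dep = unit.position_um
        dist = np.hypot(lat, dep - site_pos[:, 1])
        gains = config.amplitude.gain(dist)
        active = np.flatnonzero(unit.pp_ref_uv * gains >= MIN_SITE_PP_UV)
        if not len(active):
            continue
        contrib = (
            gains[active, None] * unit.template[None, :]
        ).astype(np.float32)
        for s in spk:
            i0 = s - trough_off
            x[active, i0 : i0 + n_w] += contrib

    # slow-wave LFP: smoothed up-state indicator, mean-centered; built at
    # a low rate (its content is < 20 Hz) and interpolated up
    if config.lfp_amp_uv > 0:
        fs_lo = 200.0
        t_lo = np.arange(int(duration_s * fs_lo) + 1) / fs_lo
        up = _is_up(t_lo, bounds).astype(np.float64)
        lfp_lo = gaussian_filter1d(up, sigma=0.05 * fs_lo)
        lfp_lo = config.lfp_amp_uv * (lfp_lo - lfp_lo.mean())
        lfp = np.interp(np.arange(n_t) / fs, t_lo, lfp_lo).astype(np.float32)
        x += lfp[None, :]

    # delta episodes: high-amplitude 2-4 Hz oscillation
    for start, end in config.delta_episodes:
        i0, i1 = int(start * fs), min(int(end * fs), n_t)
        if i1 <= i0:
            continue
        tt = np.arange(i0, i1) / fs
        x[:, i0:i1] += (
            config.delta_amp_uv * np.sin(2 * np.pi * config.delta_freq_hz * tt)
        ).astype(np.float32)

    # artifacts: 2 ms biphasic transients on all channels
    for t_a, peak in config.artifact_schedule:
        i0 = int(round(t_a * fs))
        n_a = int(round(0.002 * fs))
        if i0 < 0 or i0 + n_a >= n_t:
            continue
        half = n_a // 2
        pulse = np.concatenate(
            [np.linspace(0, peak, half), np.linspace(peak, -0.3 * peak, n_a - half)]
        ).astype(np.float32)
        x[:, i0 : i0 + n_a] += pulse

    if config.noise_sigma_uv > 0:
        x += rng_noise.standard_normal((n_ch, n_t), dtype=np.float32) * np.float32(
            config.noise_sigma_uv
        )

    return RecordingSegment(x, fs, t0_s=0.0), spike_times
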