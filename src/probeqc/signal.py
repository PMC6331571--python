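"""Multi-unit band processing and segmentwise SNR.

The pipeline mirrors standard acute-recording quality assessment:

1. band-pass the wideband trace between 500 and 5000 Hz (zero-phase,
   ~24 dB/octave) to isolate multi-unit activity;
2. detect spikes with the nonlinear energy operator (NEO),
   psi(n) = x(n)^2 - x(n-1) x(n+1), smoothed and thresholded at a
   multiple of its mean, with a 1 ms dead time;
3. estimate the noise level as the RMS of mean-centered samples outside
   1-ms spike windows;
4. per consecutive 30-s segment and channel,
   SNR_dB = 20 log10( mean_n RMS(spike_n) / sigma_noise );
5. exclude segments containing >1 mV artifacts, delta-wave (2-4 Hz)
   episodes, or outlying noise levels, then average across channels and
   penetrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import RecordingSegment

__all__ = [
    "FilterSpec",
    "bandpass",
    "neo",
    "neo_detect",
    "estimate_noise_sigma",
    "spike_window_rms",
    "snr_of_segment",
    "ExclusionRules",
    "exclude_segment",
    "SNRSeries",
    "snr_series",
    "snr_timecourse",
]

SEGMENT_LENGTH_S = 30.0


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification: 500-5000 Hz, 4th order (~24 dB/octave),
    applied forward-backward for zero phase shift."""

    low_hz: float = 500.0
    high_hz: float = 5000.0
    order: int = 4

    def validate(self, fs_hz: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= fs_hz / 2:
            raise ValueError("high cutoff must be below Nyquist")


def bandpass(x: np.ndarray, fs_hz: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    spec = spec or FilterSpec()
    spec.validate(fs_hz)
    sos = sps.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs_hz, output="sos"
    )
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=-1)


def neo(x: np.ndarray) -> np.ndarray:
    """Nonlinear energy operator psi(n) = x(n)^2 - x(n-1) x(n+1).

    Same length as the input; the two edge samples are zero.
    """
    x = np.asarray(x, dtype=np.float64)
    psi = np.zeros_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    return psi


def neo_detect(
    x: np.ndarray,
    fs_hz: float,
    k: float = 8.0,
    smooth_ms: float = 0.5,
    dead_time_ms: float = 1.0,
) -> np.ndarray:
    """Spike sample indices from the smoothed, thresholded energy operator.

    The energy trace is smoothed with a Bartlett window of ``smooth_ms``,
    thresholded at ``k`` times its mean, and local maxima closer than
    ``dead_time_ms`` are suppressed.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    psi = neo(x)
    n_win = max(int(round(smooth_ms / 1000.0 * fs_hz)), 1)
    if n_win > 1:
        win = np.bartlett(n_win + 2)[1:-1]
        win /= win.sum()
        psi = np.convolve(psi, win, mode="same")
    thr = k * psi.mean()
    if thr <= 0:
        return np.empty(0, dtype=np.int64)
    dead = max(int(round(dead_time_ms / 1000.0 * fs_hz)), 1)
    peaks, _ = sps.find_peaks(psi, height=thr, distance=dead)
    return peaks.astype(np.int64)


def _spike_window_slices(idx: np.ndarray, n: int, half: int):
    for i in idx:
        yield max(int(i) - half, 0), min(int(i) + half + 1, n)


def estimate_noise_sigma(
    x: np.ndarray,
    spike_indices: np.ndarray,
    fs_hz: float,
    window_ms: float = 1.0,
) -> float:
    """Noise SD: RMS of mean-centered samples outside the spike windows."""
    x = np.asarray(x, dtype=np.float64)
    mask = np.ones(len(x), dtype=bool)
    half = int(round(window_ms / 2000.0 * fs_hz))
    for a, b in _spike_window_slices(np.asarray(spike_indices), len(x), half):
        mask[a:b] = False
    if not mask.any():
        raise ValueError("spike windows cover the entire segment")
    out = x[mask]
    return float(np.sqrt(np.mean((out - out.mean()) ** 2)))


def spike_window_rms(
    x: np.ndarray, spike_indices: np.ndarray, fs_hz: float, window_ms: float = 1.0
) -> np.ndarray:
    """RMS of the signal in a 1-ms window centered on each detection."""
    x = np.asarray(x, dtype=np.float64)
    half = int(round(window_ms / 2000.0 * fs_hz))
    return np.array(
        [
            np.sqrt(np.mean(x[a:b] ** 2))
            for a, b in _spike_window_slices(np.asarray(spike_indices), len(x), half)
        ]
    )


def snr_of_segment(
    x: np.ndarray,
    spike_indices: np.ndarray,
    sigma_noise: float,
    fs_hz: float,
    window_ms: float = 1.0,
) -> float:
    """SNR_dB = 20 log10( (1/N) sum_n RMS(spike_n) / sigma_noise ).

    Returns NaN (flagged, not an error) when no spike was detected.
    """
    if len(spike_indices) == 0:
        return float("nan")
    if not sigma_noise > 0:
        raise ValueError("sigma_noise must be positive")
    rms = spike_window_rms(x, spike_indices, fs_hz, window_ms)
    return float(20.0 * np.log10(rms.mean() / sigma_noise))


@dataclass(frozen=True)
class ExclusionRules:
    """Segment exclusion: artifacts, delta waves, outlying noise.

    * artifact: any wideband sample beyond ``artifact_uv`` (default 1 mV);
    * delta: fraction of 0.5-10 Hz spectral power lying in 2-4 Hz above
      ``delta_power_fraction`` (an operational stand-in for the
      by-inspection criterion; see the methods note);
    * noise: segment noise SD above ``noise_factor`` times the median
      across segments.
    """

    artifact_uv: float = 1000.0
    delta_band_hz: tuple = (2.0, 4.0)
    delta_ref_band_hz: tuple = (0.5, 10.0)
    delta_power_fraction: float = 0.5
    noise_factor: float = 3.0


def _delta_fraction(wideband_mean: np.ndarray, fs_hz: float, rules: ExclusionRules) -> float:
    nper = min(len(wideband_mean), int(8 * fs_hz))
    f, pxx = sps.welch(wideband_mean, fs=fs_hz, nperseg=nper)
    lo, hi = rules.delta_ref_band_hz
    ref = pxx[(f >= lo) & (f <= hi)].sum()
    if ref <= 0:
        return 0.0
    dlo, dhi = rules.delta_band_hz
    return float(pxx[(f >= dlo) & (f <= dhi)].sum() / ref)


def exclude_segment(
    wideband: np.ndarray, fs_hz: float, rules: ExclusionRules | None = None
) -> str | None:
    """Reason ('artifact' | 'delta') to drop a wideband 30-s block, or None.

    The noise-outlier rule needs cross-segment context and is applied in
    `snr_series`.
    """
    rules = rules or ExclusionRules()
    wb = np.asarray(wideband)
    if np.abs(wb).max() > rules.artifact_uv:
        return "artifact"
    mean_trace = wb.mean(axis=0) if wb.ndim == 2 else wb
    if _delta_fraction(mean_trace, fs_hz, rules) > rules.delta_power_fraction:
        return "delta"
    return None


@dataclass
class SNRSeries:
    """Per-channel, per-30-s-segment SNR with exclusion bookkeeping."""

    values_db: np.ndarray          # (n_segments, n_channels), NaN where no spikes
    t_start_s: np.ndarray          # segment start times
    excluded: np.ndarray           # bool per segment
    reasons: list                  # str | None per segment
    segment_length_s: float = SEGMENT_LENGTH_S

    @property
    def channel_mean_db(self) -> np.ndarray:
        """Per-segment mean over channels; NaN for excluded segments."""
        with np.errstate(invalid="ignore"):
            m = np.nanmean(self.values_db, axis=1)
        m[self.excluded] = np.nan
        return m

    @property
    def channel_sd_db(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            s = np.nanstd(self.values_db, axis=1)
        s[self.excluded] = np.nan
        return s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_index": np.arange(len(self.t_start_s)),
                "t_start_s": self.t_start_s,
                "channel_mean_db": self.channel_mean_db,
                "channel_sd_db": self.channel_sd_db,
                "excluded": self.excluded,
                "reason": [r if r else "" for r in self.reasons],
            }
        )


def snr_series(
    rec: RecordingSegment,
    spec: FilterSpec | None = None,
    rules: ExclusionRules | None = None,
    k: float = 8.0,
    segment_length_s: float = SEGMENT_LENGTH_S,
) -> SNRSeries:
    """Full SNR pipeline for one penetration's recording.

    The trace is filtered once, split into consecutive full-length
    segments (a short tail is dropped), spikes are detected per channel
    and segment, and exclusion rules are applied on the wideband data.
    """
    rules = rules or ExclusionRules()
    n_seg = int(rec.n_samples / (segment_length_s * rec.fs_hz))
    seg_n = int(segment_length_s * rec.fs_hz)
    if n_seg == 0:
        raise ValueError("recording shorter than one segment")
    filtered = bandpass(rec.samples, rec.fs_hz, spec)

    values = np.full((n_seg, rec.n_channels), np.nan)
    sig_med = np.full((n_seg, rec.n_channels), np.nan)
    reasons: list = [None] * n_seg
    for s in range(n_seg):
        sl = slice(s * seg_n, (s + 1) * seg_n)
        reasons[s] = exclude_segment(rec.samples[:, sl], rec.fs_hz, rules)
        for c in range(rec.n_channels):
            x = filtered[c, sl]
            idx = neo_detect(x, rec.fs_hz, k=k)
            sigma = estimate_noise_sigma(x, idx, rec.fs_hz)
            sig_med[s, c] = sigma
            if len(idx):
                values[s, c] = snr_of_segment(x, idx, sigma, rec.fs_hz)

    # noise-outlier rule: segment median sigma vs median across segments
    seg_sigma = np.nanmedian(sig_med, axis=1)
    ref = np.nanmedian(seg_sigma)
    for s in range(n_seg):
        if reasons[s] is None and ref > 0 and seg_sigma[s] > rules.noise_factor * ref:
            reasons[s] = "noise"

    excluded = np.array([r is not None for r in reasons])
    return SNRSeries(
        values_db=values,
        t_start_s=rec.t0_s + np.arange(n_seg) * segment_length_s,
        excluded=excluded,
        reasons=reasons,
        segment_length_s=segment_length_s,
    )


def snr_timecourse(series_by_speed: dict[float, list[SNRSeries]]) -> pd.DataFrame:
    """Grand-average SNR time course per insertion speed.

    Penetrations of the same speed are aligned on segment index (t0);
    the grand average is the mean of per-penetration channel means over
    non-excluded segments.
    """
    rows = []
    for speed, series_list in series_by_speed.items():
        if not series_list:
            continue
        n_ch = {s.values_db.shape[1] for s in series_list}
        if len(n_ch) != 1:
            raise ValueError("mismatched channel counts within a speed group")
        n_seg = max(len(s.t_start_s) for s in series_list)
        for seg in range(n_seg):
            vals = [
                s.channel_mean_db[seg]
                for s in series_list
                if seg < len(s.t_start_s) and not np.isnan(s.channel_mean_db[seg])
            ]
            rows.append(
                {
                    "speed_mm_s": speed,
                    "segment_index": seg,
                    "t_start_s": seg * series_list[0].segment_length_s,
                    "grand_mean_db": np.mean(vals) if vals else np.nan,
                    "sem_db": (
                        np.std(vals, ddof=1) / np.sqrt(len(vals))
                        if len(vals) > 1
                        else np.nan
                    ),
                    "n_penetrations": len(vals),
                }
            )
    return pd.DataFrame(rows)
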