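"""Synthetic spike waveform templates.

A template is a biphasic extracellular waveform: a negative trough
followed, ``ttp_ms`` later, by a smaller positive peak.  Both phases are
raised-cosine lobes whose supports do not reach the other phase's
extremum, so the planted trough-to-peak time is exact to within one
sample and the peak-to-peak amplitude is exactly the trough depth plus
the peak height.
"""

from __future__ import annotations

import numpy as np

__all__ = ["spike_template", "TEMPLATE_DURATION_MS", "TROUGH_OFFSET_MS"]

TEMPLATE_DURATION_MS = 4.0
TROUGH_OFFSET_MS = 2.0  # trough sits at the template center


def spike_template(
    ttp_ms: float,
    fs_hz: float,
    pp_uv: float = 1.0,
    peak_ratio: float = 0.35,
    duration_ms: float = TEMPLATE_DURATION_MS,
) -> np.ndarray:
    """Build a biphasic spike template sampled at ``fs_hz``.

    Parameters
    ----------
    ttp_ms : float
        Planted trough-to-peak time (ms); < 0.6 gives a narrow-spiking
        (putative interneuron) waveform, >= 0.6 a wide one.
    pp_uv : float
        Peak-to-peak amplitude (trough depth + peak height), uV.
    peak_ratio : float
        Height of the positive peak relative to the trough depth.

    Returns
    -------
    ndarray of length ``round(duration_ms * fs / 1000)`` with the trough
    exactly at sample ``round(TROUGH_OFFSET_MS * fs / 1000)``.
    """
    if ttp_ms <= 0 or pp_uv <= 0:
        raise ValueError("ttp_ms and pp_uv must be positive")
    n = int(round(duration_ms * fs_hz / 1000.0))
    i_trough = int(round(TROUGH_OFFSET_MS * fs_hz / 1000.0))
    i_peak = i_trough + int(round(ttp_ms * fs_hz / 1000.0))
    if i_peak >= n - 1:
        raise ValueError("template too short for the requested trough-to-peak time")
    t = np.arange(n) / fs_hz * 1000.0  # ms
    # lobe half-widths: never reach the other extremum
    half = min(0.25, 0.49 * ttp_ms)

    def lobe(center_ms: float, half_ms: float) -> np.ndarray:
        u = (t - center_ms) / half_ms
        out = np.where(np.abs(u) < 1.0, np.cos(0.5 * np.pi * u) ** 2, 0.0)
        return out

    a_trough = pp_uv / (1.0 + peak_ratio)
    w = -a_trough * lobe(t[i_trough], half) + peak_ratio * a_trough * lobe(
        t[i_peak], half
    )
    return w.astype(np.float64)
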