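"""On-disk formats.

Recordings are stored the way acquisition systems deliver them: a raw
int16 binary (channel-major frames) plus a JSON sidecar holding the
sampling rate, channel count, microvolts-per-count gain, time origin and
probe layout id.  Ground truth and analysis products are plain CSV;
section images are TIFF with a JSON sidecar carrying the pixel scale and
track rectangle.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import RecordingSegment

__all__ = [
    "write_recording",
    "read_recording",
    "write_spike_times",
    "read_spike_times",
    "units_to_frame",
]

DEFAULT_UV_PER_COUNT = 0.195  # typical 16-bit headstage gain


def write_recording(
    path: str | Path,
    rec: RecordingSegment,
    layout_id: str = "",
    uv_per_count: float = DEFAULT_UV_PER_COUNT,
) -> Path:
    """Write ``<path>.bin`` (int16, channel-major) + ``<path>.json``.

    Values are quantized to ``uv_per_count`` microvolt steps; the
    round-trip error is at most half a quantization step.  Raises if the
    signal exceeds the int16 range at the chosen gain.
    """
    path = Path(path)
    counts = np.round(rec.samples / uv_per_count)
    if np.abs(counts).max(initial=0) > np.iinfo(np.int16).max:
        raise ValueError("signal exceeds int16 range at this uv_per_count")
    counts.astype(np.int16).tofile(path.with_suffix(".bin"))
    meta = {
        "fs_hz": rec.fs_hz,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "uv_per_count": uv_per_count,
        "t0_s": rec.t0_s,
        "layout_id": layout_id,
        "dtype": "int16",
        "order": "channel_major",
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path.with_suffix(".bin")


def read_recording(path: str | Path) -> tuple[RecordingSegment, dict]:
    """Read a binary + JSON recording pair written by `write_recording`.

    Raises on a size mismatch between the metadata and the binary.
    """
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    raw = np.fromfile(path.with_suffix(".bin"), dtype=np.int16)
    expected = meta["n_channels"] * meta["n_samples"]
    if raw.size != expected:
        raise ValueError(
            f"binary holds {raw.size} samples, metadata promises {expected}"
        )
    samples = raw.reshape(meta["n_channels"], meta["n_samples"]).astype(
        np.float32
    ) * np.float32(meta["uv_per_count"])
    return RecordingSegment(samples, meta["fs_hz"], meta["t0_s"]), meta


def write_spike_times(path: str | Path, spike_times: dict[int, np.ndarray]) -> Path:
    """Ground-truth (or sorted) spike times as CSV: unit_id, time_s."""
    rows = [
        {"unit_id": uid, "time_s": t}
        for uid, times in sorted(spike_times.items())
        for t in np.asarray(times)
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(path, index=False)
    return Path(path)


def read_spike_times(path: str | Path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    return {
        int(uid): grp["time_s"].to_numpy()
        for uid, grp in df.groupby("unit_id", sort=True)
    }


def units_to_frame(units) -> pd.DataFrame:
    """Ground-truth unit table (position, class, survival, onset)."""
    return pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "lateral_um": [u.position_um[0] for u in units],
            "depth_um": [u.position_um[1] for u in units],
            "cell_class": [u.cell_class for u in units],
            "ttp_ms": [u.ttp_ms for u in units],
            "pp_ref_uv": [u.pp_ref_uv for u in units],
            "survived": [u.survived for u in units],
            "onset_time_s": [u.onset_time_s for u in units],
            "n_spikes": [len(u.spike_times_s) for u in units],
        }
    )
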