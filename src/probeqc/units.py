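"""Single-unit quality metrics and cell-type classification.

Operates on spike times plus waveforms, whether they come from the
simulator's ground truth or from an external sorter.  A unit is *well
isolated* when its best-channel mean waveform exceeds 60 uV peak-to-peak
and fewer than 2% of its spikes are followed by another within 2 ms.
Narrow-spiking units (trough-to-peak < 0.6 ms) are putative inhibitory
interneurons; wide-spiking ones putative principal cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import RecordingSegment
from . import stats as _stats

__all__ = [
    "extract_snippets",
    "average_waveform",
    "peak_to_peak",
    "violation_rate",
    "first_spike_latency",
    "isolation_distance",
    "waveform_features",
    "trough_to_peak",
    "classify_units",
    "ClassificationResult",
    "unit_metrics_table",
]

PP_CRITERION_UV = 60.0
VIOLATION_CRITERION_PCT = 2.0
REFRACTORY_MS = 2.0
NARROW_THRESHOLD_MS = 0.6


def extract_snippets(
    samples: np.ndarray,
    fs_hz: float,
    spike_times_s: np.ndarray,
    pre_ms: float = 2.0,
    post_ms: float = 2.0,
) -> np.ndarray:
    """Cut (spikes x channels x samples) waveform snippets around spikes.

    Spikes whose window would cross the trace edges are dropped.
    """
    samples = np.atleast_2d(samples)
    pre = int(round(pre_ms / 1000.0 * fs_hz))
    post = int(round(post_ms / 1000.0 * fs_hz))
    idx = np.round(np.asarray(spike_times_s) * fs_hz).astype(np.int64)
    idx = idx[(idx - pre >= 0) & (idx + post < samples.shape[1])]
    if len(idx) == 0:
        return np.empty((0, samples.shape[0], pre + post + 1))
    return np.stack([samples[:, i - pre : i + post + 1] for i in idx])


def average_waveform(snippets: np.ndarray) -> np.ndarray:
    """Per-channel sample mean of the spike snippets."""
    snippets = np.asarray(snippets)
    if snippets.ndim != 3 or snippets.shape[0] == 0:
        raise ValueError("need at least one (channels x samples) snippet")
    return snippets.mean(axis=0)


def peak_to_peak(mean_waveform: np.ndarray) -> tuple[float, int]:
    """Max minus min per channel; returns the best channel's value.

    The best channel is the one with the largest amplitude; ties break
    to the lowest channel index.
    """
    w = np.atleast_2d(mean_waveform)
    if w.size == 0:
        raise ValueError("empty waveform")
    pp = w.max(axis=1) - w.min(axis=1)
    best = int(np.argmax(pp))
    return float(pp[best]), best


def violation_rate(spike_times_s: np.ndarray, refractory_ms: float = REFRACTORY_MS) -> float:
    """Percentage of spikes followed by another within the refractory gap.

    Strict inequality: an inter-spike interval of exactly 2 ms is not a
    violation.  An empty train returns NaN.
    """
    t = np.sort(np.asarray(spike_times_s, dtype=float))
    if len(t) == 0:
        return float("nan")
    if len(t) == 1:
        return 0.0
    viol = np.count_nonzero(np.diff(t) < refractory_ms / 1000.0)
    return 100.0 * viol / len(t)


def first_spike_latency(spike_times_s: np.ndarray, t0_s: float = 0.0) -> float:
    """Time from probe arrival at depth to the unit's first spike."""
    t = np.asarray(spike_times_s, dtype=float)
    if len(t) == 0:
        return float("nan")
    return float(t.min() - t0_s)


def isolation_distance(
    features: np.ndarray,
    labels: np.ndarray,
    target,
    ridge: float = 1e-9,
) -> float:
    """Cluster separation: squared Mahalanobis distance of the n_c-th
    closest non-cluster event from the cluster center, using the
    cluster's own covariance.

    Undefined (NaN) when the cluster holds more than half of all events
    or fewer than dims + 2, or when fewer than n_c outside events exist.
    A singular covariance is ridge-regularized.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    in_c = labels == target
    n_c = int(in_c.sum())
    n, dims = features.shape
    if n_c < dims + 2 or n_c > n - n_c or n_c > n // 2:
        return float("nan")
    xc = features[in_c]
    xo = features[~in_c]
    mu = xc.mean(axis=0)
    cov = np.cov(xc, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        cinv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        cov = cov + ridge * np.trace(cov) / dims * np.eye(dims)
        cinv = np.linalg.inv(cov)
    d = xo - mu
    md2 = np.einsum("ij,jk,ik->i", d, cinv, d)
    md2.sort()
    return float(md2[n_c - 1])


def waveform_features(
    snippets: np.ndarray, n_components: int = 3, channels=None
) -> np.ndarray:
    """Per-channel principal-component scores, concatenated.

    ``channels`` restricts the feature space to the given channel
    indices (typically the best channels of the units under study).
    """
    snippets = np.asarray(snippets, dtype=float)
    if channels is not None:
        snippets = snippets[:, np.asarray(channels), :]
    n_spk, n_ch, n_s = snippets.shape
    feats = []
    for c in range(n_ch):
        xc = snippets[:, c, :] - snippets[:, c, :].mean(axis=0)
        k = min(n_components, n_spk, n_s)
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        feats.append(xc @ vt[:k].T)
    return np.concatenate(feats, axis=1)


def trough_to_peak(waveform: np.ndarray, fs_hz: float) -> float:
    """Time (ms) from the global trough to the subsequent local maximum.

    Returns NaN (waveform unclassifiable) when no interior local maximum
    follows the trough.
    """
    w = np.asarray(waveform, dtype=float).ravel()
    i_tr = int(np.argmin(w))
    tail = w[i_tr:]
    if len(tail) < 3:
        return float("nan")
    interior = (tail[1:-1] >= tail[:-2]) & (tail[1:-1] >= tail[2:])
    cand = np.flatnonzero(interior) + 1
    if len(cand) == 0:
        return float("nan")
    i_pk = cand[np.argmax(tail[cand])]
    return float(i_pk / fs_hz * 1000.0)


@dataclass
class ClassificationResult:
    labels: np.ndarray              # "narrow" | "wide" | "unclassified"
    narrow_fraction_pct: float      # among classified units
    dip_statistic: float
    dip_p: float


def classify_units(
    ttp_ms: np.ndarray,
    threshold_ms: float = NARROW_THRESHOLD_MS,
    dip_reps: int = 2000,
    seed=0,
) -> ClassificationResult:
    """Label units narrow/wide by trough-to-peak time and test bimodality.

    Narrow iff ttp < threshold (0.6 ms); exactly at threshold is wide.
    NaN values are left unclassified.  Bimodality of the classified
    distribution is assessed with Hartigan's dip test (Monte-Carlo
    uniform null).
    """
    ttp = np.asarray(ttp_ms, dtype=float)
    labels = np.where(ttp < threshold_ms, "narrow", "wide").astype(object)
    labels[np.isnan(ttp)] = "unclassified"
    classified = ttp[~np.isnan(ttp)]
    n_narrow = int((labels == "narrow").sum())
    frac = 100.0 * n_narrow / len(classified) if len(classified) else float("nan")
    if len(classified) >= 8:
        dip, p = _stats.dip_test(classified, reps=dip_reps, seed=seed)
    else:
        dip, p = float("nan"), float("nan")
    return ClassificationResult(np.asarray(labels), frac, dip, p)


def unit_metrics_table(
    rec: RecordingSegment,
    spike_times: dict[int, np.ndarray],
    t0_s: float = 0.0,
    min_spikes: int = 10,
    feature_channels: int = 4,
    isolation_min_units: int = 2,
) -> pd.DataFrame:
    """Compute the full per-unit metric table for one penetration.

    Columns mirror the on-disk unit-table contract: unit_id, n_spikes,
    peak_to_peak_uv, best_channel, violation_pct, first_latency_s,
    isolation_distance, ttp_ms, cell_class, well_isolated,
    exclusion_reason.
    """
    rows = []
    snips: dict[int, np.ndarray] = {}
    for uid, times in sorted(spike_times.items()):
        times = np.asarray(times)
        row = {"unit_id": uid, "n_spikes": len(times)}
        if len(times) == 0:
            row.update(
                peak_to_peak_uv=np.nan,
                best_channel=-1,
                violation_pct=np.nan,
                first_latency_s=np.nan,
                ttp_ms=np.nan,
                exclusion_reason="no_spikes",
            )
            rows.append(row)
            continue
        sn = extract_snippets(rec.samples, rec.fs_hz, times)
        if len(sn) < max(min_spikes, 1):
            row.update(
                peak_to_peak_uv=np.nan,
                best_channel=-1,
                violation_pct=violation_rate(times),
                first_latency_s=first_spike_latency(times, t0_s),
                ttp_ms=np.nan,
                exclusion_reason="too_few_spikes",
            )
            rows.append(row)
            continue
        snips[uid] = sn
        mean_wf = average_waveform(sn)
        pp, best = peak_to_peak(mean_wf)
        viol = violation_rate(times)
        row.update(
            peak_to_peak_uv=pp,
            best_channel=best,
            violation_pct=viol,
            first_latency_s=first_spike_latency(times, t0_s),
            ttp_ms=trough_to_peak(mean_wf[best], rec.fs_hz),
            exclusion_reason=(
                None
                if pp > PP_CRITERION_UV and viol < VIOLATION_CRITERION_PCT
                else ("low_amplitude" if pp <= PP_CRITERION_UV else "refractory")
            ),
        )
        rows.append(row)

    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["well_isolated"] = df["exclusion_reason"].isna()
    df["cell_class"] = np.where(
        df["ttp_ms"].isna(),
        "unclassified",
        np.where(df["ttp_ms"] < NARROW_THRESHOLD_MS, "narrow", "wide"),
    )

    # isolation distance in a shared per-channel-PC feature space
    df["isolation_distance"] = np.nan
    if len(snips) >= isolation_min_units:
        uids = list(snips)
        best_by_uid = df.set_index("unit_id")["best_channel"]
        chans = sorted(
            {int(best_by_uid[u]) for u in uids if best_by_uid[u] >= 0}
        )[:feature_channels]
        if chans:
            feats = waveform_features(
                np.concatenate([snips[u] for u in uids]), channels=chans
            )
            labels = np.concatenate(
                [np.full(len(snips[u]), u) for u in uids]
            )
            iso = {u: isolation_distance(feats, labels, u) for u in uids}
            df["isolation_distance"] = df["unit_id"].map(iso)
    return df
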