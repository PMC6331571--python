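"""Soma detection and peri-track neuron-density quantification.

Two quantifications of neuron loss around the probe track, both computed
from soma centroids (detected or planted):

* a binned profile — counts in 20 x 100 um^2 bins on each long side of
  the track out to 400 um, normalized to the mean density of the
  160-400 um bins;
* the single-unit / control zone ratio — density in the 0-50 um band
  over density in the 50-100 um band, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops

from .sections import SectionImage, TrackRect, track_frame_coords

__all__ = [
    "detect_somata",
    "DensityProfile",
    "binned_density_profile",
    "ZoneDensity",
    "zone_density_ratio",
]

BIN_WIDTH_UM = 20.0
BIN_LENGTH_UM = 100.0
N_BINS_PER_SIDE = 20
NORM_RANGE_UM = (160.0, 400.0)
SU_ZONE_UM = (0.0, 50.0)
CONTROL_ZONE_UM = (50.0, 100.0)


def detect_somata(
    section: SectionImage,
    min_area_um2: float = 20.0,
    max_area_um2: float = 400.0,
    threshold: float | None = None,
    smooth_um: float = 2.0,
) -> np.ndarray:
    """Detect soma centroids: threshold -> connected components -> size filter.

    Returns an (n, 2) array of (x_um, y_um) centroids.  The intensity
    threshold defaults to Otsu's; areas outside the configured range (in
    square micrometers) are discarded.
    """
    scale = section.scale_um_per_px
    if not scale > 0:
        raise ValueError("image lacks a positive um/pixel calibration")
    img = section.pixels.astype(float)
    if smooth_um > 0:
        img = gaussian(img, sigma=smooth_um / scale, preserve_range=True)
    if threshold is None:
        threshold = threshold_otsu(img)
    mask = img > threshold
    if not mask.any() or mask.all():
        return np.empty((0, 2))
    lab = label(mask)
    px_area = scale * scale
    cents = [
        (p.centroid[1] * scale, p.centroid[0] * scale)
        for p in regionprops(lab)
        if min_area_um2 <= p.area * px_area <= max_area_um2
    ]
    return np.asarray(cents, dtype=float).reshape(-1, 2)


def _side_distance(centroids: np.ndarray, track: TrackRect):
    """(side, distance-from-long-edge, within-length flag) per centroid."""
    along, across = track_frame_coords(centroids[:, 0], centroids[:, 1], track)
    side = np.where(across >= 0, "right", "left")
    dist = np.abs(across) - track.width_um / 2.0
    in_len = np.abs(along) <= track.length_um / 2.0
    return side, dist, in_len


@dataclass
class DensityProfile:
    """Binned neuron densities on the two long sides of the track."""

    table: pd.DataFrame            # side, bin_start_um, count, density, normalized
    n_ignored: int                 # centroids outside the binned region
    bin_width_um: float = BIN_WIDTH_UM
    bin_length_um: float = BIN_LENGTH_UM

    def mean_normalized(self) -> pd.Series:
        """Normalized density per bin averaged across the two sides."""
        return self.table.groupby("bin_start_um")["normalized"].mean()


def binned_density_profile(
    centroids: np.ndarray,
    track: TrackRect,
    bin_width_um: float = BIN_WIDTH_UM,
    n_bins: int = N_BINS_PER_SIDE,
    norm_range_um: tuple = NORM_RANGE_UM,
) -> DensityProfile:
    """Count somata in [d, d+20) um distance bins on each side, 0-400 um.

    Distance is measured from the nearest long edge of the track
    rectangle; only centroids within the track's 100 um length band are
    binned.  Densities are normalized per side to the mean density of
    the bins fully inside ``norm_range_um`` (160-400 um), then the two
    sides can be averaged.
    """
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    max_d = n_bins * bin_width_um
    edges = np.arange(n_bins + 1) * bin_width_um
    bin_area_mm2 = (bin_width_um / 1000.0) * (BIN_LENGTH_UM / 1000.0)

    if len(centroids):
        side, dist, in_len = _side_distance(centroids, track)
        ok = in_len & (dist >= 0) & (dist < max_d)
    else:
        side = np.empty(0, dtype=object)
        dist = np.empty(0)
        ok = np.empty(0, dtype=bool)
    n_ignored = int(len(centroids) - ok.sum())

    rows = []
    norm_lo, norm_hi = norm_range_um
    for sd in ("left", "right"):
        sel = ok & (side == sd)
        counts, _ = np.histogram(dist[sel], bins=edges)
        density = counts / bin_area_mm2
        ref_bins = (edges[:-1] >= norm_lo) & (edges[1:] <= norm_hi)
        ref = density[ref_bins].mean() if ref_bins.any() else np.nan
        normalized = density / ref if ref and np.isfinite(ref) and ref > 0 else np.full(
            n_bins, np.nan
        )
        for b in range(n_bins):
            rows.append(
                {
                    "side": sd,
                    "bin_start_um": edges[b],
                    "count": int(counts[b]),
                    "density_per_mm2": density[b],
                    "normalized": normalized[b],
                }
            )
    return DensityProfile(pd.DataFrame(rows), n_ignored, bin_width_um)


@dataclass
class ZoneDensity:
    """Neuron densities in the SU (0-50 um) and control (50-100 um) zones."""

    su_density_per_mm2: float
    control_density_per_mm2: float

    @property
    def ratio_pct(self) -> float:
        """SU / control density in percent; NaN when the control is empty."""
        if not self.control_density_per_mm2 > 0:
            return float("nan")
        return 100.0 * self.su_density_per_mm2 / self.control_density_per_mm2


def zone_density_ratio(
    centroids: np.ndarray,
    track: TrackRect,
    su_zone_um: tuple = SU_ZONE_UM,
    control_zone_um: tuple = CONTROL_ZONE_UM,
) -> ZoneDensity:
    """Density ratio between the SU zone and the control zone (both sides
    pooled), the manual-counting complement to the binned profile."""
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if len(centroids):
        _, dist, in_len = _side_distance(centroids, track)
    else:
        dist = np.empty(0)
        in_len = np.empty(0, dtype=bool)

    def zone_density(lo, hi):
        count = int(np.count_nonzero(in_len & (dist >= lo) & (dist < hi)))
        area_mm2 = 2.0 * ((hi - lo) / 1000.0) * (BIN_LENGTH_UM / 1000.0)
        return count / area_mm2

    return ZoneDensity(
        zone_density(*su_zone_um), zone_density(*control_zone_um)
    )
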