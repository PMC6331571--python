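"""Synthetic NeuN-like section images with planted density deficits.

A horizontal section through the insertion site is emulated as a 2-D
image of compact bright somata on a dark background.  Cell centers are
drawn from a planted density field: uniform far from the probe track and
multiplied by a distance-dependent deficit factor near it (the lesion).
The planted centroids are recorded so soma detection and density
profiling can be validated against exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import tifffile

__all__ = ["TrackRect", "SectionImage", "render_section_image",
           "track_frame_coords", "write_section_image", "read_section_image"]


@dataclass(frozen=True)
class TrackRect:
    """The probe-track lesion: a 100 x 10 um^2 rectangle.

    ``angle_deg`` orients the long (100 um) axis relative to the image
    x-axis.
    """

    cx_um: float
    cy_um: float
    length_um: float = 100.0
    width_um: float = 10.0
    angle_deg: float = 0.0


def track_frame_coords(x_um, y_um, rect: TrackRect):
    """Rotate points into the track frame.

    Returns ``(along, across)``: coordinates along the long axis
    (centered) and across it (signed; the two long sides are across > 0
    and across < 0).
    """
    a = np.deg2rad(rect.angle_deg)
    dx = np.asarray(x_um, dtype=float) - rect.cx_um
    dy = np.asarray(y_um, dtype=float) - rect.cy_um
    along = dx * np.cos(a) + dy * np.sin(a)
    across = -dx * np.sin(a) + dy * np.cos(a)
    return along, across


def distance_to_track(x_um, y_um, rect: TrackRect):
    """Euclidean distance to the track rectangle (0 inside it)."""
    along, across = track_frame_coords(x_um, y_um, rect)
    du = np.maximum(np.abs(along) - rect.length_um / 2.0, 0.0)
    dv = np.maximum(np.abs(across) - rect.width_um / 2.0, 0.0)
    return np.hypot(du, dv)


@dataclass
class SectionImage:
    """Rendered section: pixel grid + calibration + planted ground truth."""

    pixels: np.ndarray  # 2-D uint16 intensity grid, [row, col]
    scale_um_per_px: float
    track: TrackRect
    planted_centroids_um: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2))
    )  # (x_um, y_um); x = col * scale, y = row * scale

    def __post_init__(self) -> None:
        h, w = self.pixels.shape
        if not (
            0 <= self.track.cx_um <= w * self.scale_um_per_px
            and 0 <= self.track.cy_um <= h * self.scale_um_per_px
        ):
            raise ValueError("track rectangle must lie inside the image")

    @property
    def extent_um(self) -> tuple[float, float]:
        h, w = self.pixels.shape
        return w * self.scale_um_per_px, h * self.scale_um_per_px


def render_section_image(
    size_um: tuple[float, float],
    scale_um_per_px: float,
    track: TrackRect,
    density_per_mm2: float,
    deficit: Callable[[np.ndarray], np.ndarray] | None,
    seed,
    soma_radius_um: float = 6.0,
    background: int = 800,
    soma_intensity: int = 30000,
    noise_counts: float = 60.0,
) -> SectionImage:
    """Render a section image with a planted density deficit.

    Parameters
    ----------
    deficit : callable or None
        Maps distance-to-track (um) to a survival factor in [0, 1]; the
        local soma density is ``density_per_mm2 * deficit(d)``.  ``None``
        means no deficit (uniform field).
    """
    if scale_um_per_px <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    w_um, h_um = size_um
    area_mm2 = (w_um / 1000.0) * (h_um / 1000.0)
    n = rng.poisson(density_per_mm2 * area_mm2)
    x = rng.uniform(0.0, w_um, n)
    y = rng.uniform(0.0, h_um, n)
    if deficit is not None:
        d = distance_to_track(x, y, track)
        f = np.asarray(deficit(d), dtype=float)
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("deficit factor must lie in [0, 1]")
        keep = rng.random(n) < f
        x, y = x[keep], y[keep]

    h_px = int(round(h_um / scale_um_per_px))
    w_px = int(round(w_um / scale_um_per_px))
    img = np.zeros((h_px, w_px), dtype=np.float64)

    # paste a smooth radial blob per soma
    r_px = soma_radius_um / scale_um_per_px
    k = int(np.ceil(2.2 * r_px))
    ky, kx = np.mgrid[-k : k + 1, -k : k + 1]
    for xi, yi in zip(x / scale_um_per_px, y / scale_um_per_px):
        r, c = int(round(yi)), int(round(xi))
        rr = np.hypot(ky + (r - yi), kx + (c - xi)) / r_px
        blob = np.clip(1.0 - rr**2, 0.0, None) ** 1.5
        r0, r1 = max(r - k, 0), min(r + k + 1, h_px)
        c0, c1 = max(c - k, 0), min(c + k + 1, w_px)
        img[r0:r1, c0:c1] += (
            soma_intensity * blob[r0 - (r - k) : r1 - (r - k), c0 - (c - k) : c1 - (c - k)]
        )

    img += background + rng.normal(0.0, noise_counts, img.shape)
    pixels = np.clip(img, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return SectionImage(
        pixels, scale_um_per_px, track, np.column_stack([x, y])
    )


def write_section_image(path: str | Path, section: SectionImage) -> Path:
    """TIFF + JSON sidecar (scale, track rectangle, planted centroids)."""
    path = Path(path)
    tifffile.imwrite(path.with_suffix(".tif"), section.pixels)
    meta = {
        "scale_um_per_px": section.scale_um_per_px,
        "track_rect": {
            "cx_um": section.track.cx_um,
            "cy_um": section.track.cy_um,
            "length_um": section.track.length_um,
            "width_um": section.track.width_um,
            "angle_deg": section.track.angle_deg,
        },
        "planted_centroids_um": section.planted_centroids_um.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path.with_suffix(".tif")


def read_section_image(path: str | Path) -> SectionImage:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    pixels = tifffile.imread(path.with_suffix(".tif"))
    tr = meta["track_rect"]
    return SectionImage(
        pixels,
        meta["scale_um_per_px"],
        TrackRect(
            tr["cx_um"], tr["cy_um"], tr["length_um"], tr["width_um"], tr["angle_deg"]
        ),
        np.asarray(meta["planted_centroids_um"], dtype=float).reshape(-1, 2),
    )
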