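"""Probe geometries.

Two single-shank silicon probes are supported: a 128-site dense array
(32 rows x 4 columns of 20 x 20 um^2 sites separated by 2.5 um gaps on a
50-um-thick shank) and a 32-site linear array (25 um site pitch on a
15-um-thick shank).  Site positions anchor every distance computation in
the simulator, so coordinates are explicit: ``(lateral_um, depth_um)``
site centers, lateral across the shank face, depth along it (0 = tip-most
site row).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ProbeLayout", "make_probe_layout", "subset_channels", "PROBE_MODELS"]


@dataclass(frozen=True)
class ProbeLayout:
    """Site coordinates and geometry for one probe model.

    Attributes
    ----------
    model_id : str
        Probe model label (``dense128`` or ``linear32``).
    site_positions : ndarray, shape (n_channels, 2)
        ``(lateral_um, depth_um)`` center of each recording site; channel
        index equals row index.
    site_size_um : float
        Edge length of the (square) recording site in micrometers.
    shank_thickness_um : float
        Shank thickness in micrometers.
    """

    model_id: str
    site_positions: np.ndarray
    site_size_um: float
    shank_thickness_um: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.site_positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("site_positions must have shape (n_channels, 2)")
        object.__setattr__(self, "site_positions", pos)
        # no two site squares may overlap
        if len(pos) > 1:
            d_lat = np.abs(pos[:, None, 0] - pos[None, :, 0])
            d_dep = np.abs(pos[:, None, 1] - pos[None, :, 1])
            overlap = (d_lat < self.site_size_um) & (d_dep < self.site_size_um)
            np.fill_diagonal(overlap, False)
            if overlap.any():
                raise ValueError("site rectangles overlap")

    @property
    def n_channels(self) -> int:
        return len(self.site_positions)

    @property
    def depth_extent_um(self) -> float:
        """Span of site centers along the shank."""
        d = self.site_positions[:, 1]
        return float(d.max() - d.min())


def _dense128() -> ProbeLayout:
    # 32 rows x 4 columns; 20 um sites, 2.5 um gaps -> 22.5 um pitch both axes
    pitch = 22.5
    cols, rows = np.meshgrid(np.arange(4), np.arange(32))
    pos = np.column_stack([cols.ravel() * pitch, rows.ravel() * pitch])
    return ProbeLayout("dense128", pos, site_size_um=20.0, shank_thickness_um=50.0)


def _linear32() -> ProbeLayout:
    # 25 um pitch edge-style linear array, 177 um^2 sites (~13.3 um square)
    pos = np.column_stack([np.zeros(32), np.arange(32) * 25.0])
    return ProbeLayout("linear32", pos, site_size_um=13.3, shank_thickness_um=15.0)


PROBE_MODELS = {"dense128": _dense128, "linear32": _linear32}


def make_probe_layout(model_id: str) -> ProbeLayout:
    """Build the layout for a supported probe model.

    Raises
    ------
    ValueError
        If ``model_id`` is not one of ``dense128`` / ``linear32``.
    """
    try:
        factory = PROBE_MODELS[model_id]
    except KeyError:
        raise ValueError(
            f"unknown probe model {model_id!r}; supported models: "
            + ", ".join(sorted(PROBE_MODELS))
        ) from None
    return factory()


def subset_channels(layout: ProbeLayout, n_channels: int) -> ProbeLayout:
    """Restrict a layout to its first ``n_channels`` sites (tip-most rows).

    Used for reduced-scale virtual experiments; the returned layout keeps
    the parent geometry and is tagged ``<model_id>[:n]``.
    """
    if not 1 <= n_channels <= layout.n_channels:
        raise ValueError("n_channels out of range")
    return ProbeLayout(
        f"{layout.model_id}[:{n_channels}]",
        layout.site_positions[:n_channels].copy(),
        layout.site_size_um,
        layout.shank_thickness_um,
    )
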