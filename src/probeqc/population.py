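"""Ground-truth neuron populations around an inserted shank.

Neurons are placed by a homogeneous Poisson point process in a tissue
slab next to the shank; each one survives the insertion with the
speed- and distance-dependent probability from
:func:`probeqc.insertion.survival_probability`, is narrow- or
wide-spiking with a configurable base fraction, and (if it survives)
resumes firing after an exponentially distributed onset latency whose
mean grows with insertion speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .insertion import InsertionProtocol, survival_probability
from .probes import ProbeLayout
from .templates import spike_template

__all__ = ["GroundTruthUnit", "simulate_population"]


@dataclass
class GroundTruthUnit:
    """One simulated neuron with its ground truth."""

    unit_id: int
    position_um: tuple  # (lateral distance from shank surface, depth along shank)
    cell_class: str  # "narrow" | "wide"
    ttp_ms: float  # planted trough-to-peak time
    pp_ref_uv: float  # peak-to-peak amplitude at the 1 um reference distance
    rate_up_hz: float  # up-state firing rate
    survived: bool
    onset_time_s: float  # first allowed spike time after probe arrival
    template: np.ndarray = field(repr=False)  # waveform at reference distance, uV
    spike_times_s: np.ndarray = field(
        default_factory=lambda: np.empty(0), repr=False
    )

    def __post_init__(self) -> None:
        if not self.survived and len(self.spike_times_s):
            raise ValueError("dead units carry no spikes")


def simulate_population(
    layout: ProbeLayout,
    protocol: InsertionProtocol,
    config: SimulationConfig,
    seed,
) -> list[GroundTruthUnit]:
    """Draw the neuron population for one penetration.

    Deterministic for a fixed seed; a zero density yields an empty list.
    """
    rng = np.random.default_rng(seed)
    depths = layout.site_positions[:, 1]
    d_lo = depths.min() - config.depth_margin_um
    d_hi = depths.max() + config.depth_margin_um
    volume_mm3 = (
        (config.lateral_extent_um / 1000.0)
        * ((d_hi - d_lo) / 1000.0)
        * (config.slab_um / 1000.0)
    )
    n = rng.poisson(config.neuron_density_per_mm3 * volume_mm3)
    if n == 0:
        return []

    lateral = rng.uniform(0.0, config.lateral_extent_um, n)
    depth = rng.uniform(d_lo, d_hi, n)
    p_survive = survival_probability(lateral, protocol.speed_mm_s, config.survival)
    survived = rng.random(n) < p_survive
    narrow = rng.random(n) < config.narrow_fraction
    ttp = np.where(
        narrow,
        rng.uniform(*config.narrow_ttp_range_ms, n),
        rng.uniform(*config.wide_ttp_range_ms, n),
    )
    pp_ref = config.pp_ref_median_uv * np.exp(
        rng.normal(0.0, config.pp_ref_sigma, n)
    )
    rate = config.rate_up_hz * np.exp(rng.normal(0.0, config.rate_sigma, n))
    mean_lat = config.latency.mean_latency_s(protocol.speed_mm_s)
    onset = rng.exponential(mean_lat, n)

    units = []
    for i in range(n):
        units.append(
            GroundTruthUnit(
                unit_id=i,
                position_um=(float(lateral[i]), float(depth[i])),
                cell_class="narrow" if narrow[i] else "wide",
                ttp_ms=float(ttp[i]),
                pp_ref_uv=float(pp_ref[i]),
                rate_up_hz=float(rate[i]),
                survived=bool(survived[i]),
                onset_time_s=float(onset[i]),
                template=spike_template(float(ttp[i]), config.fs_hz, float(pp_ref[i])),
            )
        )
    return units
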