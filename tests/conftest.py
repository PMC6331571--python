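import pytest

from probeqc.config import SimulationConfig
from probeqc.insertion import InsertionProtocol
from probeqc.population import simulate_population
from probeqc.probes import make_probe_layout, subset_channels
from probeqc.recording import simulate_recording


@pytest.fixture(scope="session")
def small_layout():
    """Eight tip-most sites of the linear probe (fast to simulate)."""
    return subset_channels(make_probe_layout("linear32"), 8)


@pytest.fixture(scope="session")
def sparse_sim():
    """Low-density, low-rate simulation config for fast unit tests."""
    return SimulationConfig(
        neuron_density_per_mm3=8000.0,
        lfp_amp_uv=100.0,
    )


@pytest.fixture(scope="session")
def short_recording(small_layout, sparse_sim):
    """A 35 s penetration at the slowest speed with its ground truth."""
    units = simulate_population(
        small_layout, InsertionProtocol(0.002), sparse_sim, seed=11
    )
    rec, spikes = simulate_recording(units, small_layout, sparse_sim, 35.0, seed=12)
    return rec, spikes, units
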