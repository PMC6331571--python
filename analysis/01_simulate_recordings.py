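"""Simulate one slow and one fast penetration and write their artifacts.

Generates a ground-truth neuron population next to an 8-channel probe
subset for the slowest (0.002 mm/s) and fastest (1 mm/s) insertion
speeds, synthesizes 60 s of 20 kHz voltage data for each, and writes:

* int16 binary recordings + JSON metadata under scratch/recordings/
  (binary bulk stays out of results/),
* ground-truth unit and spike-time tables under results/recordings/.

Later scripts re-read these artifacts through the package's readers, so
this doubles as an on-disk format round-trip.
"""

from pathlib import Path

import numpy as np

import dataclasses

from probeqc import (
    InsertionProtocol,
    LatencyParams,
    SimulationConfig,
    make_probe_layout,
    simulate_population,
    simulate_recording,
    subset_channels,
)
from probeqc.io import units_to_frame, write_recording, write_spike_times

SEED = 5
DURATION_S = 60.0
SPEEDS = (0.002, 1.0)

scratch = Path(__file__).resolve().parents[1] / "scratch" / "recordings"
results = Path(__file__).resolve().parents[1] / "results" / "recordings"
scratch.mkdir(parents=True, exist_ok=True)
results.mkdir(parents=True, exist_ok=True)

layout = subset_channels(make_probe_layout("linear32"), 8)
# onset latencies scaled to the reduced duration (same convention as the
# virtual experiments)
sim = SimulationConfig(latency=LatencyParams(scale=DURATION_S / 2700.0))
ss = np.random.SeedSequence(SEED)

for speed, (s_pop, s_rec) in zip(SPEEDS, zip(ss.spawn(2), ss.spawn(4)[2:])):
    units = simulate_population(layout, InsertionProtocol(speed), sim, s_pop)
    rec, spikes = simulate_recording(units, layout, sim, DURATION_S, s_rec)
    stem = f"speed{speed:g}".replace(".", "p")
    write_recording(scratch / stem, rec, layout_id=layout.model_id)
    write_spike_times(results / f"{stem}_spikes.csv", spikes)
    units_to_frame(units).to_csv(results / f"{stem}_units.csv", index=False)
    n_surv = sum(u.survived for u in units)
    print(
        f"{speed:g} mm/s: {len(units)} neurons simulated, {n_surv} survived, "
        f"{sum(len(t) for t in spikes.values())} spikes in {DURATION_S:.0f} s"
    )
print(f"recordings -> {scratch}")
print(f"ground truth -> {results}")
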