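"""Virtual insertion-speed experiments: simulate -> analyze -> compare.

One experiment mirrors the in-vivo design: several penetrations per
insertion speed (order balanced across virtual animals), a fixed-length
recording per penetration analyzed for SNR and single-unit metrics, a
NeuN-like section per penetration quantified for peri-track neuron
density, and the group statistics over it all.

Default sizes are scaled for desk runtime (minutes of recording on a
channel subset); ``full_scale=True`` restores 45-minute, full-array
penetrations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as pstats
from .config import SimulationConfig
from .histology import binned_density_profile, detect_somata, zone_density_ratio
from .insertion import STUDY_SPEEDS_MM_S, InsertionProtocol, survival_probability
from .io import units_to_frame
from .population import simulate_population
from .probes import make_probe_layout, subset_channels
from .recording import simulate_recording
from .sections import TrackRect, render_section_image
from .signal import SNRSeries, snr_series, snr_timecourse
from .units import classify_units, unit_metrics_table

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "randomize_speed_sequence",
    "run_virtual_experiment",
    "summarize_units",
]

FULL_DURATION_S = 2700.0  # 45 min -> 90 segments of 30 s


@dataclass(frozen=True)
class ExperimentConfig:
    speeds_mm_s: tuple = STUDY_SPEEDS_MM_S
    penetrations_per_speed: int = 2
    probe_model: str = "linear32"
    n_channels: int | None = 16        # channel subset; None = full array
    duration_s: float = 150.0          # recording length per penetration
    target_depth_um: float = 1700.0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    neo_k: float = 8.0
    dip_reps: int = 500
    section_density_per_mm2: float = 2000.0
    section_size_um: tuple = (800.0, 600.0)
    section_scale_um_per_px: float = 1.0
    sections_per_penetration: int = 3
    soma_radius_um: float = 4.5
    # detection threshold a bit above half the soma peak so touching
    # somata split into separate components
    soma_detect_threshold: float = 800.0 + 0.55 * 30000.0
    soma_min_area_um2: float = 6.0
    soma_max_area_um2: float = 300.0
    scale_latency_to_duration: bool = True
    # per-penetration damage variability: SD (um) of a random shift of the
    # survival-curve midpoint, shared between a penetration's recording and
    # its sections; reproduces the large insertion-to-insertion spread of
    # unit yields and zone ratios
    damage_jitter_um: float = 10.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.speeds_mm_s:
            raise ValueError("need at least one insertion speed")
        if any(s <= 0 for s in self.speeds_mm_s):
            raise ValueError("speeds must be positive")
        if self.duration_s < 30.0:
            raise ValueError("need at least one 30 s segment")

    @classmethod
    def full_scale(cls, **overrides) -> "ExperimentConfig":
        """45-minute penetrations on the full 128-site dense array."""
        base = dict(
            probe_model="dense128",
            n_channels=None,
            duration_s=FULL_DURATION_S,
            penetrations_per_speed=8,
            scale_latency_to_duration=False,
        )
        base.update(overrides)
        return cls(**base)

    def effective_sim(self) -> SimulationConfig:
        """Simulation config with the onset-latency scale tied to the
        recording length (so reduced-duration runs keep the latency
        structure proportionally)."""
        if not self.scale_latency_to_duration:
            return self.sim
        scale = self.duration_s / FULL_DURATION_S
        return dataclasses.replace(
            self.sim, latency=dataclasses.replace(self.sim.latency, scale=scale)
        )

    def null_effect(self) -> "ExperimentConfig":
        """Zero-damage control: survival flat at 1, latency speed-blind."""
        sim = dataclasses.replace(
            self.sim,
            survival=dataclasses.replace(
                self.sim.survival, midpoint_um=-1e6, midpoint_per_decade=0.0
            ),
            latency=dataclasses.replace(self.sim.latency, per_decade_s=0.0),
        )
        return dataclasses.replace(self, sim=sim)


def randomize_speed_sequence(speeds, n_experiments: int, seed) -> list[tuple]:
    """Per-experiment insertion-speed orderings, balanced across position.

    Experiments are grouped into blocks of len(speeds); within a block
    each speed occupies each position exactly once (a randomly chosen
    cyclic Latin square with shuffled rows and columns), so across 8
    experiments with 4 speeds each speed appears twice in each position.
    """
    speeds = list(speeds)
    if not speeds:
        raise ValueError("need at least one speed")
    k = len(speeds)
    rng = np.random.default_rng(seed)
    orders: list[tuple] = []
    while len(orders) < n_experiments:
        base = rng.permutation(k)
        rows = rng.permutation(k)
        for r in rows:
            orders.append(tuple(speeds[base[(r + c) % k]] for c in range(k)))
    return orders[:n_experiments]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    unit_table: pd.DataFrame           # all units, all penetrations
    yield_table: pd.DataFrame          # per penetration: speed, well-isolated count
    snr_by_speed: dict                 # speed -> list[SNRSeries]
    snr_segments: pd.DataFrame         # per penetration x segment channel means
    snr_grand: pd.DataFrame            # grand-average time course per speed
    histology_table: pd.DataFrame      # per section: speed, zone densities, ratio
    zone_by_penetration: pd.DataFrame  # pooled per-penetration zone ratios
    profile_tables: pd.DataFrame       # binned normalized densities per section
    classification: pd.DataFrame       # per speed narrow/wide counts
    stats_report: pd.DataFrame

    def save(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.unit_table.to_csv(out / "units.csv", index=False)
        self.yield_table.to_csv(out / "unit_yield.csv", index=False)
        self.snr_segments.to_csv(out / "snr_segments.csv", index=False)
        self.snr_grand.to_csv(out / "snr_grand_average.csv", index=False)
        self.histology_table.to_csv(out / "zone_density.csv", index=False)
        self.zone_by_penetration.to_csv(out / "zone_density_by_penetration.csv", index=False)
        self.profile_tables.to_csv(out / "density_profile.csv", index=False)
        self.classification.to_csv(out / "cell_classes.csv", index=False)
        self.stats_report.to_csv(out / "stats_report.csv", index=False)
        summarize_units(self.unit_table, self.yield_table).to_csv(
            out / "unit_summary.csv", index=False
        )


def _jittered_sim(sim, delta_um):
    if not delta_um:
        return sim
    surv = dataclasses.replace(
        sim.survival, midpoint_um=sim.survival.midpoint_um + delta_um
    )
    return dataclasses.replace(sim, survival=surv)


def _simulate_penetration(layout, speed, cfg, sim, seed, damage_delta_um=0.0):
    """One penetration: population, recording, SNR series, unit metrics."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_pop, s_rec = ss.spawn(2)
    protocol = InsertionProtocol(speed, cfg.target_depth_um)
    units = simulate_population(layout, protocol, _jittered_sim(sim, damage_delta_um), s_pop)
    rec, spikes = simulate_recording(units, layout, sim, cfg.duration_s, s_rec)
    series = snr_series(rec, k=cfg.neo_k)
    metrics = unit_metrics_table(rec, spikes, t0_s=rec.t0_s)
    truth = units_to_frame(units)
    if not metrics.empty:
        metrics = metrics.merge(
            truth[["unit_id", "survived", "onset_time_s", "lateral_um"]],
            on="unit_id",
            how="left",
        )
    return series, metrics


def _section_for_speed(cfg, speed, seed, damage_delta_um=0.0):
    w, h = cfg.section_size_um
    track = TrackRect(cx_um=w / 2.0, cy_um=h / 2.0)
    surv = _jittered_sim(cfg.sim, damage_delta_um).survival
    deficit = lambda d: survival_probability(d, speed, surv)
    return render_section_image(
        cfg.section_size_um,
        cfg.section_scale_um_per_px,
        track,
        cfg.section_density_per_mm2,
        deficit,
        seed,
        soma_radius_um=cfg.soma_radius_um,
    )


def reduced_two_speed_config(master_seed: int = 0, **overrides) -> ExperimentConfig:
    """Desk-scale slowest-vs-fastest benchmark experiment.

    Mirrors the thin-probe design (two speeds only) at reduced scale:
    six penetrations per speed, 90 s recordings on an 8-channel subset,
    three analyzed sections per penetration.  Sized so the planted
    damage model's directional effects (SNR, unit yield, zone density,
    yield-density correlation) are resolvable in a single seeded run.
    """
    kw = dict(
        speeds_mm_s=(0.002, 1.0),
        penetrations_per_speed=8,
        n_channels=8,
        duration_s=90.0,
        dip_reps=200,
        # densities and section counts sized so each penetration's zone
        # ratio carries >= ~100 cells per zone (Poisson error below the
        # planted slow/fast gap)
        section_density_per_mm2=3000.0,
        soma_radius_um=3.5,
        sections_per_penetration=4,
        master_seed=master_seed,
    )
    kw.update(overrides)
    return ExperimentConfig(**kw)


def run_virtual_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full virtual experiment for one configuration."""
    cfg = config
    layout = make_probe_layout(cfg.probe_model)
    if cfg.n_channels is not None and cfg.n_channels < layout.n_channels:
        layout = subset_channels(layout, cfg.n_channels)
    sim = cfg.effective_sim()

    ss = np.random.SeedSequence(cfg.master_seed)
    n_pen = len(cfg.speeds_mm_s) * cfg.penetrations_per_speed
    pen_seeds = ss.spawn(n_pen + 2)
    hist_root = pen_seeds[-2]
    jitter_rng = np.random.default_rng(pen_seeds[-1])
    damage_deltas = jitter_rng.normal(0.0, cfg.damage_jitter_um, n_pen)

    unit_rows, yield_rows, seg_rows = [], [], []
    snr_by_speed: dict[float, list[SNRSeries]] = {s: [] for s in cfg.speeds_mm_s}
    pen_idx = 0
    for speed in cfg.speeds_mm_s:
        for rep in range(cfg.penetrations_per_speed):
            series, metrics = _simulate_penetration(
                layout, speed, cfg, sim, pen_seeds[pen_idx],
                damage_delta_um=damage_deltas[pen_idx],
            )
            snr_by_speed[speed].append(series)
            n_iso = 0
            if not metrics.empty:
                metrics.insert(0, "speed_mm_s", speed)
                metrics.insert(1, "penetration", pen_idx)
                unit_rows.append(metrics)
                n_iso = int(metrics["well_isolated"].sum())
            yield_rows.append(
                {"speed_mm_s": speed, "penetration": pen_idx, "n_units": n_iso}
            )
            df = series.to_frame()
            df.insert(0, "speed_mm_s", speed)
            df.insert(1, "penetration", pen_idx)
            seg_rows.append(df)
            pen_idx += 1

    unit_table = (
        pd.concat(unit_rows, ignore_index=True) if unit_rows else pd.DataFrame()
    )
    yield_table = pd.DataFrame(yield_rows)
    snr_segments = pd.concat(seg_rows, ignore_index=True)
    snr_grand = snr_timecourse(snr_by_speed)

    # histology: one (or more) sections per penetration with the matching
    # planted damage field
    hist_rows, prof_rows = [], []
    hist_seeds = hist_root.spawn(n_pen * cfg.sections_per_penetration)
    hs = 0
    for speed in cfg.speeds_mm_s:
        for rep in range(cfg.penetrations_per_speed):
            pen = cfg.speeds_mm_s.index(speed) * cfg.penetrations_per_speed + rep
            for sec_i in range(cfg.sections_per_penetration):
                section = _section_for_speed(
                    cfg, speed, hist_seeds[hs], damage_delta_um=damage_deltas[pen]
                )
                hs += 1
                cents = detect_somata(
                    section,
                    min_area_um2=cfg.soma_min_area_um2,
                    max_area_um2=cfg.soma_max_area_um2,
                    threshold=cfg.soma_detect_threshold,
                    smooth_um=1.0,
                )
                zones = zone_density_ratio(cents, section.track)
                hist_rows.append(
                    {
                        "speed_mm_s": speed,
                        "penetration": pen,
                        "section": sec_i,
                        "n_detected": len(cents),
                        "su_density_per_mm2": zones.su_density_per_mm2,
                        "control_density_per_mm2": zones.control_density_per_mm2,
                        "zone_ratio_pct": zones.ratio_pct,
                    }
                )
                prof = binned_density_profile(cents, section.track)
                mn = prof.mean_normalized().reset_index()
                mn.insert(0, "speed_mm_s", speed)
                mn.insert(1, "penetration", pen)
                mn.insert(2, "section", sec_i)
                prof_rows.append(mn)
    histology_table = pd.DataFrame(hist_rows)
    profile_tables = pd.concat(prof_rows, ignore_index=True)
    # per-penetration zone ratio from pooled section counts (more robust
    # than averaging per-section ratios of small Poisson counts)
    zone_by_penetration = (
        histology_table.groupby(["speed_mm_s", "penetration"], as_index=False)[
            ["su_density_per_mm2", "control_density_per_mm2"]
        ]
        .mean()
        .assign(
            zone_ratio_pct=lambda t: 100.0
            * t["su_density_per_mm2"]
            / t["control_density_per_mm2"]
        )
    )

    # cell-class ratios among well-isolated units, per speed, plus the
    # pooled bimodality test of the trough-to-peak distribution
    cls_rows = []
    if not unit_table.empty:
        iso = unit_table[unit_table["well_isolated"]]
        for speed in cfg.speeds_mm_s:
            ttp = iso.loc[iso["speed_mm_s"] == speed, "ttp_ms"].dropna().to_numpy()
            n_narrow = int((ttp < 0.6).sum())
            cls_rows.append(
                {
                    "speed_mm_s": speed,
                    "n_narrow": n_narrow,
                    "n_wide": len(ttp) - n_narrow,
                    "narrow_pct": 100.0 * n_narrow / len(ttp) if len(ttp) else np.nan,
                }
            )
        pooled = iso["ttp_ms"].dropna().to_numpy()
        if cfg.dip_reps > 0 and len(pooled) >= 8:
            res = classify_units(
                pooled, dip_reps=cfg.dip_reps, seed=cfg.master_seed
            )
            cls_rows.append(
                {
                    "speed_mm_s": "pooled",
                    "n_narrow": int((res.labels == "narrow").sum()),
                    "n_wide": int((res.labels == "wide").sum()),
                    "narrow_pct": res.narrow_fraction_pct,
                    "dip_statistic": res.dip_statistic,
                    "dip_p": res.dip_p,
                }
            )
    classification = pd.DataFrame(cls_rows)

    stats_report = _group_statistics(
        cfg, unit_table, yield_table, snr_segments, zone_by_penetration
    )
    return ExperimentResult(
        config=cfg,
        unit_table=unit_table,
        yield_table=yield_table,
        snr_by_speed=snr_by_speed,
        snr_segments=snr_segments,
        snr_grand=snr_grand,
        histology_table=histology_table,
        zone_by_penetration=zone_by_penetration,
        profile_tables=profile_tables,
        classification=classification,
        stats_report=stats_report,
    )


def _kw_row(name, groups, labels):
    try:
        res = pstats.kruskal_dunn(groups)
        return {
            "test": "kruskal_wallis",
            "variable": name,
            "groups": ";".join(str(l) for l in labels),
            "n": ";".join(str(len(g)) for g in groups),
            "statistic": res.statistic,
            "p": res.p,
        }
    except ValueError as e:
        return {"test": "kruskal_wallis", "variable": name, "error": str(e)}


def _group_statistics(cfg, unit_table, yield_table, snr_segments, histology_table):
    rows = []
    speeds = list(cfg.speeds_mm_s)

    snr_groups = [
        snr_segments.loc[
            (snr_segments["speed_mm_s"] == s) & (~snr_segments["excluded"]),
            "channel_mean_db",
        ]
        .dropna()
        .to_numpy()
        for s in speeds
    ]
    if all(len(g) >= 2 for g in snr_groups) and len(speeds) >= 2:
        rows.append(_kw_row("snr_db", snr_groups, speeds))

    yield_groups = [
        yield_table.loc[yield_table["speed_mm_s"] == s, "n_units"].to_numpy()
        for s in speeds
    ]
    if all(len(g) >= 2 for g in yield_groups) and len(speeds) >= 2:
        rows.append(_kw_row("unit_yield", yield_groups, speeds))

    if not unit_table.empty:
        iso = unit_table[unit_table["well_isolated"]]
        for var in ("peak_to_peak_uv", "first_latency_s", "isolation_distance"):
            groups = [
                iso.loc[iso["speed_mm_s"] == s, var].dropna().to_numpy()
                for s in speeds
            ]
            if all(len(g) >= 2 for g in groups) and len(speeds) >= 2:
                rows.append(_kw_row(var, groups, speeds))

    if len(speeds) >= 2 and not histology_table.empty:
        slow, fast = min(speeds), max(speeds)
        a = histology_table.loc[
            histology_table["speed_mm_s"] == slow, "zone_ratio_pct"
        ].dropna()
        b = histology_table.loc[
            histology_table["speed_mm_s"] == fast, "zone_ratio_pct"
        ].dropna()
        if len(a) >= 2 and len(b) >= 2:
            t, p = pstats.t_test(a, b)
            rows.append(
                {
                    "test": "t_test",
                    "variable": "zone_ratio_pct",
                    "groups": f"{slow};{fast}",
                    "n": f"{len(a)};{len(b)}",
                    "statistic": t,
                    "p": p,
                }
            )

    # unit yield vs SU-zone density across penetrations
    merged = yield_table.merge(
        histology_table.groupby("penetration", as_index=False)["zone_ratio_pct"].mean(),
        on="penetration",
        how="inner",
    ).dropna(subset=["zone_ratio_pct"])
    if len(merged) >= 3 and merged["n_units"].std() > 0 and merged["zone_ratio_pct"].std() > 0:
        r, p = pstats.pearson_r(merged["n_units"], merged["zone_ratio_pct"])
        rows.append(
            {
                "test": "pearson",
                "variable": "yield_vs_zone_density",
                "groups": "all",
                "n": str(len(merged)),
                "statistic": r,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def summarize_units(unit_table: pd.DataFrame, yield_table: pd.DataFrame) -> pd.DataFrame:
    """Per-speed summary of well-isolated units (mean +/- SD per metric),
    the virtual analogue of the printed single-unit property tables."""
    if unit_table.empty:
        return pd.DataFrame()
    iso = unit_table[unit_table["well_isolated"]]
    rows = []
    for speed, grp in iso.groupby("speed_mm_s"):
        y = yield_table.loc[yield_table["speed_mm_s"] == speed, "n_units"]
        row = {
            "speed_mm_s": speed,
            "total_units": len(grp),
            "units_per_penetration_mean": y.mean(),
            "units_per_penetration_sd": y.std(ddof=1) if len(y) > 1 else np.nan,
        }
        for col, name in [
            ("peak_to_peak_uv", "peak_to_peak_uv"),
            ("first_latency_s", "first_latency_s"),
            ("isolation_distance", "isolation_distance"),
            ("violation_pct", "violation_pct"),
        ]:
            vals = grp[col].dropna()
            row[f"{name}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{name}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
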