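"""End-to-end orchestration: raw logs (or the simulator) to output tables.

Stage order: speed filter -> trip segmentation -> 1 s interpolation ->
ethogram -> dives -> foraging events -> budgets -> foraging grid ->
niche metrics.  Stages whose inputs are missing are skipped with a
warning and everything downstream of them is skipped too.  Every run
writes a manifest (config hash, input checksums, versions, seeds, output
list) so outputs are traceable.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, SimConfig, config_hash
from .dives import (
    correct_surface_drift,
    detect_dives,
    dive_seconds_mask,
    dives_table,
    fleet_descent_rate,
    pressure_to_depth,
    validate_detection,
)
from .ethogram import compute_ethogram, foraging_rate
from .grid import grid_foraging_time
from .io import (
    AccelTrace,
    GpsTrack,
    file_checksum,
    write_outputs,
    write_points,
)
from .niche import niche_summary, ssd_table
from .trips import (
    bimodality_coefficient,
    estimate_modes,
    filter_speed,
    interpolate,
    mcp_area,
    segment_trips,
    trips_table,
)

log = logging.getLogger("petrelbio")


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict[str, int]
    version: str
    python: str
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> Path:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
        return path


def setup_logging(out_dir: Optional[Path] = None, level: int = logging.INFO) -> None:
    """Log to stderr and, when an output directory is given, to run.log."""
    root = logging.getLogger("petrelbio")
    root.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in root.handlers):
        root.addHandler(logging.StreamHandler())
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        root.addHandler(fh)


def analyse_deployment(
    gps: Optional[GpsTrack],
    trace: Optional[AccelTrace],
    ana: AnalysisConfig,
    seed: int = 0,
    atmospheric_pressure_mbar: float = 1013.0,
) -> dict:
    """Run all stages available for one deployment's inputs.

    Returns a dict of result tables/objects; missing inputs cause the
    dependent stages to be skipped (and logged), not to fail.
    """
    results: dict = {}

    trips = []
    dense = None
    if gps is not None and len(gps) > 0:
        clean = filter_speed(gps, ana.speed_filter_ms)
        trips = segment_trips(clean, ana)
        results["trips"] = trips_table(trips, ana.colony)
        if trips:
            allfix = pd.concat([t.fixes for t in trips])
            if allfix[["lat", "lon"]].drop_duplicates().shape[0] >= 3:
                results["home_range_km2"] = mcp_area(allfix["lat"], allfix["lon"])
            dense = interpolate(trips[0], ana.interp_interval_s)
        durations = results["trips"]["duration_h"]
        if len(durations) >= 4:
            results["bimodality_coefficient"] = bimodality_coefficient(durations)
        if len(durations) >= 10:
            results["modes_h"] = estimate_modes(durations, seed=seed)
    else:
        log.warning("no GPS input: trip stage skipped")

    dives = []
    dive_secs = None
    if trace is not None and trace.pressure is not None:
        depth = pressure_to_depth(trace.pressure, atmospheric_pressure_mbar)
        depth = correct_surface_drift(
            depth, trace.pressure_rate_hz, ana.zoc_window_s, ana.zoc_quantile
        )
        dives = detect_dives(
            depth, ana.dive_threshold_m, trace.pressure_rate_hz, ana.surface_band_m
        )
        results["dives"] = dives_table(dives)
        if len(dives) >= 3:
            rate, per_dive = fleet_descent_rate(dives)
            results["fleet_descent_rate_ms"] = rate
        n_sec = int(trace.duration_s)
        dive_secs = dive_seconds_mask(dives, n_sec)
    elif trace is not None:
        log.info("no pressure channel: dive stage skipped")

    if trace is not None:
        local_hour = None
        if dense is not None:
            t0 = trace.start_time
            secs = np.arange(int(trace.duration_s))
            utc_hour = (t0.hour + t0.minute / 60 + secs / 3600.0) % 24
            mean_lon = float(dense["lon"].mean())
            local_hour = (utc_hour + mean_lon / 15.0) % 24
        etho = compute_ethogram(
            trace,
            ana,
            seed=seed,
            dive_seconds=dive_secs,
            track=dense,
            local_hour=local_hour,
        )
        results["ethogram"] = etho
        if dives:
            results["pct_dives_detected"] = validate_detection(
                etho.events, dives, ana.match_window_s
            )
        if trips:
            # events span the whole acceleration record, so rate is per
            # deployment hour; distance summed over all trips
            total_km = float(results["trips"]["total_distance_km"].sum())
            results["foraging_rate"] = foraging_rate(
                etho.events, trace.duration_s / 3600.0, total_km
            )
        if dense is not None:
            results["foraging_grid"] = grid_foraging_time(
                dense, etho.seconds["is_foraging"].to_numpy(), ana.grid_cell_deg
            )
    else:
        log.warning("no acceleration input: ethogram stage skipped")
    return results


def run_pipeline(
    out_dir: str | Path,
    sim: Optional[SimConfig] = None,
    ana: Optional[AnalysisConfig] = None,
    gps: Optional[GpsTrack] = None,
    trace: Optional[AccelTrace] = None,
    morpho: Optional[pd.DataFrame] = None,
    isotopes: Optional[pd.DataFrame] = None,
    seed: int = 0,
    input_paths: Optional[dict[str, Path]] = None,
) -> RunManifest:
    """Full pipeline to an output directory; returns the run manifest.

    With ``sim`` set, inputs are simulated (including bird tables);
    otherwise the provided domain objects are analysed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    setup_logging(out_dir)
    ana = ana or AnalysisConfig()
    pa = 1013.0
    if sim is not None:
        from .simulate import simulate_bird_tables, simulate_deployment

        sim = SimConfig(**{**sim.__dict__, "seed": seed if sim.seed == 0 else sim.seed})
        gps, trace, _truth = simulate_deployment(sim)
        morpho, isotopes = simulate_bird_tables(16, 13, seed=sim.seed)
        ana = AnalysisConfig(**{**ana.__dict__, "colony": sim.colony})
        pa = sim.atmospheric_pressure_mbar

    results = analyse_deployment(gps, trace, ana, seed=seed, atmospheric_pressure_mbar=pa)

    tables: dict[str, pd.DataFrame] = {}
    scalars: dict[str, object] = {}
    if "trips" in results:
        tables["trip_metrics"] = results["trips"]
    if "dives" in results:
        tables["dives"] = results["dives"]
    if "ethogram" in results:
        etho = results["ethogram"]
        tables["ethogram_seconds"] = etho.seconds
        tables["activity_budget"] = pd.DataFrame([etho.budget])
        if len(etho.hourly):
            tables["hourly_budget"] = etho.hourly
        ev = pd.DataFrame(
            [
                {
                    "start_s": e.start_s,
                    "end_s": e.end_s,
                    "duration_s": e.duration_s,
                    "type": e.type,
                    "lat": e.lat,
                    "lon": e.lon,
                }
                for e in etho.events
            ]
        )
        tables["foraging_events"] = ev
        if len(ev) and ev["lat"].notna().any():
            write_points(ev.dropna(subset=["lat"]), out_dir / "foraging_events_points.csv")
    if "foraging_grid" in results:
        tables["foraging_grid"] = results["foraging_grid"]
    if morpho is not None:
        tables["ssd"] = ssd_table(morpho)
    if isotopes is not None:
        tables["niche"] = niche_summary(isotopes, seed=seed)
    for key in ("home_range_km2", "bimodality_coefficient", "fleet_descent_rate_ms",
                "pct_dives_detected"):
        if key in results:
            scalars[key] = results[key]
    if "foraging_rate" in results:
        scalars.update(results["foraging_rate"])
    if "modes_h" in results:
        scalars["modes_h"] = results["modes_h"]
    if scalars:
        tables["summary"] = pd.DataFrame(
            [{"quantity": k, "value": json.dumps(v) if isinstance(v, list) else v}
             for k, v in scalars.items()]
        )

    cfgs = [ana] + ([sim] if sim is not None else [])
    manifest = RunManifest(
        config_hash=config_hash(*cfgs),
        seeds={"pipeline": seed},
        version=__version__,
        python=platform.python_version(),
        input_checksums={
            str(k): file_checksum(v) for k, v in (input_paths or {}).items()
        },
    )
    meta = {"petrelbio_version": __version__, "config_hash": manifest.config_hash}
    paths = write_outputs(tables, out_dir, meta)
    manifest.outputs = sorted(str(p) for p in paths.values())
    manifest.write(out_dir / "manifest.json")
    return manifest
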