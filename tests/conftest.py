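"""Shared fixtures: synthetic deployments at the default study conditions.

The heavy fixture (`deployment_batch`) runs the full pipeline on ten
default 48 h deployments once per session; cheaper tests use a single
short deployment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from petrelbio.config import AnalysisConfig, SimConfig
from petrelbio.dives import (
    correct_surface_drift,
    detect_dives,
    fleet_descent_rate,
    pressure_to_depth,
    validate_detection,
)
from petrelbio.ethogram import compute_ethogram
from petrelbio.simulate import simulate_deployment


@dataclass
class DeploymentRun:
    seed: int
    truth_labels: np.ndarray
    dive_log: list
    event_log: list
    seconds: "object"  # ethogram per-second table
    events: list
    budget: dict
    dives: list
    fleet_rate: float
    pct_detected: float
    config: SimConfig


def _run_one(seed: int, **overrides) -> DeploymentRun:
    cfg = SimConfig(seed=seed, **overrides)
    ana = AnalysisConfig(colony=cfg.colony)
    gps, trace, truth = simulate_deployment(cfg)
    depth = correct_surface_drift(
        pressure_to_depth(trace.pressure, cfg.atmospheric_pressure_mbar),
        trace.pressure_rate_hz,
    )
    dives = detect_dives(depth, ana.dive_threshold_m, trace.pressure_rate_hz)
    from petrelbio.dives import dive_seconds_mask

    mask = dive_seconds_mask(dives, int(trace.duration_s))
    etho = compute_ethogram(trace, ana, seed=seed, dive_seconds=mask)
    rate, _ = fleet_descent_rate(dives)
    pct = validate_detection(etho.events, dives, ana.match_window_s)
    return DeploymentRun(
        seed=seed,
        truth_labels=truth.labels,
        dive_log=truth.dive_log,
        event_log=truth.event_log,
        seconds=etho.seconds,
        events=etho.events,
        budget=etho.budget,
        dives=dives,
        fleet_rate=rate,
        pct_detected=pct,
        config=cfg,
    )


@pytest.fixture(scope="session")
def deployment_batch() -> list[DeploymentRun]:
    """Ten default-condition deployments, seeds 1-10, fully analysed."""
    return [_run_one(seed) for seed in range(1, 11)]


@pytest.fixture(scope="session")
def short_deployment():
    """One cheap 4 h deployment for unit-level checks."""
    cfg = SimConfig(seed=11, trip_duration_h=4)
    return cfg, simulate_deployment(cfg)
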