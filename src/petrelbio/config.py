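"""Configuration objects for simulation and analysis.

All analysis constants (speed filter, pitch threshold, dive threshold,
grid size, ...) live in :class:`AnalysisConfig`; the synthetic-biologger
study conditions live in :class:`SimConfig`.  Both can be loaded from a
single YAML file with ``simulate:`` and ``analysis:`` sections.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ParameterError

#: Colony location of the study population (Punakaiki, New Zealand).
DEFAULT_COLONY = (-42.146, 171.341)


@dataclass
class SimConfig:
    """Study conditions for the synthetic biologger.

    Defaults emulate a chick-rearing Westland petrel deployment: a ~2-day
    central-place trip within ~150 km of the colony, a flap-glide flight
    style with a dominant wingbeat cycle, rafting bouts on the water, brief
    (~1-2 s) head-down surface-foraging strikes and shallow V-shaped dives
    descending at 0.84 m/s, recorded by a 25 Hz tri-axial accelerometer
    with a 1 Hz pressure channel (5 mBar sensor noise).
    """

    seed: int = 0
    trip_duration_h: float = 48.0
    colony: tuple[float, float] = DEFAULT_COLONY
    max_range_km: float = 150.0
    behaviour_fractions: dict[str, float] = field(
        default_factory=lambda: {"flap": 0.514, "glide": 0.137, "raft": 0.349}
    )
    foraging_events_per_h: float = 2.7
    surface_event_duration_s: float = 1.2
    dive_fraction_of_foraging: float = 0.25
    wingbeat_cycle_s: float = 0.3
    flap_amplitude_g: float = 0.4
    glide_heave_sd_g: float = 0.03
    raft_heave_sd_g: float = 0.03
    descent_rate_ms: float = 0.84
    dive_depth_range_m: tuple[float, float] = (0.7, 2.0)
    pressure_noise_mbar: float = 5.0
    atmospheric_pressure_mbar: float = 1013.0
    gps_interval_s: float = 180.0
    accel_rate_hz: float = 25.0
    pressure_rate_hz: float = 1.0
    # signal-shape parameters (air vs water static heave separation)
    flight_static_heave_g: float = 1.0
    raft_heave_offset_g: float = 0.15
    wave_freq_hz: float = 0.2
    wave_amplitude_g: float = 0.05
    forage_pitch_deg: float = -40.0
    forage_surge_sd_g: float = 0.5
    forage_sway_sd_g: float = 0.3
    forage_heave_sd_g: float = 0.08
    flight_speed_kmh: float = 18.0
    start_time: str = "2017-08-12T00:00:00Z"

    def __post_init__(self) -> None:
        fr = self.behaviour_fractions
        if set(fr) != {"flap", "glide", "raft"}:
            raise ParameterError(
                "behaviour_fractions must have exactly the keys flap, glide, raft"
            )
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"behaviour_fractions sum to {total}, expected 1")
        if any(v < 0 for v in fr.values()):
            raise ParameterError("behaviour_fractions must be non-negative")
        for name in (
            "trip_duration_h",
            "max_range_km",
            "surface_event_duration_s",
            "wingbeat_cycle_s",
            "flap_amplitude_g",
            "glide_heave_sd_g",
            "raft_heave_sd_g",
            "descent_rate_ms",
            "atmospheric_pressure_mbar",
            "gps_interval_s",
            "accel_rate_hz",
            "pressure_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.foraging_events_per_h < 0 or self.pressure_noise_mbar < 0:
            raise ParameterError("rates and noise levels must be >= 0")
        lo, hi = self.dive_depth_range_m
        if not (0 < lo <= hi):
            raise ParameterError("dive_depth_range_m must satisfy 0 < min <= max")
        if not 0 <= self.dive_fraction_of_foraging <= 1:
            raise ParameterError("dive_fraction_of_foraging must be in [0, 1]")
        # foraging must fit inside rafting time, with room for event separation
        n_events = self.foraging_events_per_h * self.trip_duration_h
        needed_s = n_events * (self.surface_event_duration_s + 10.0)
        raft_s = fr["raft"] * self.trip_duration_h * 3600.0
        if needed_s > raft_s:
            raise ParameterError(
                "infeasible config: foraging events do not fit within the "
                f"rafting fraction ({needed_s:.0f} s needed, {raft_s:.0f} s rafting)"
            )


@dataclass
class AnalysisConfig:
    """Thresholds and constants of the analysis pipeline.

    Attributes
    ----------
    speed_filter_ms : maximum plausible travel speed (m/s); faster implied
        GPS fixes are treated as position errors.
    interp_interval_s : interval of the dense, linearly interpolated track.
    decompose_window_s : running-mean window separating static (postural)
        from dynamic acceleration.
    pitch_threshold_deg : body pitch below which a non-flying second is a
        foraging (head-down strike) second.
    event_gap_s : maximum separation for merging foraging seconds into one
        foraging event.
    dive_threshold_m : minimum submergence (one body length) counted as a
        dive; strictly greater-than.
    descent_rate_ms : fleet descent rate used to estimate depth from dive
        duration on pressure-less loggers.
    grid_cell_deg : side of the square grid used to standardise time spent
        foraging.
    tau_water_g / water_band_g : per-second raw-heave s.d. ceiling and
        static-heave band that characterise a bird sitting on water.
    """

    speed_filter_ms: float = 25.0
    interp_interval_s: float = 1.0
    decompose_window_s: float = 1.0
    pitch_threshold_deg: float = -25.0
    event_gap_s: float = 5.0
    dive_threshold_m: float = 0.55
    descent_rate_ms: float = 0.84
    grid_cell_deg: float = 0.04
    colony: tuple[float, float] = DEFAULT_COLONY
    colony_radius_km: float = 1.0
    kmeans_k: int = 2
    match_window_s: float = 2.0
    tau_water_g: float = 0.12
    water_band_g: tuple[float, float] = (0.70, 0.95)
    smooth_window_s: int = 3
    surface_band_m: float = 0.1
    zoc_window_s: float = 600.0
    zoc_quantile: float = 0.02

    def __post_init__(self) -> None:
        if self.pitch_threshold_deg >= 0:
            raise ParameterError("pitch_threshold_deg must be negative")
        if self.grid_cell_deg <= 0:
            raise ParameterError("grid_cell_deg must be > 0")
        for name in (
            "speed_filter_ms",
            "interp_interval_s",
            "decompose_window_s",
            "event_gap_s",
            "dive_threshold_m",
            "descent_rate_ms",
            "colony_radius_km",
            "match_window_s",
        ):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ParameterError(f"{name} must be finite")
            if v < 0:
                raise ParameterError(f"{name} must be >= 0")


def _as_dict(cfg: Any) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def config_hash(*cfgs: Any) -> str:
    """Stable SHA-256 hash of one or more config dataclasses."""
    blob = json.dumps([_as_dict(c) for c in cfgs], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _coerce(cls, raw: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ParameterError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in raw.items():
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> tuple[SimConfig, AnalysisConfig]:
    """Load ``simulate:`` and ``analysis:`` sections from a YAML file.

    Missing sections fall back to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config file {path} must be a mapping")
    sim = _coerce(SimConfig, raw.get("simulate", {}) or {})
    ana = _coerce(AnalysisConfig, raw.get("analysis", {}) or {})
    return sim, ana
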