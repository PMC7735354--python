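"""Per-second at-sea ethogram from tri-axial acceleration.

The processing chain mirrors standard accelerometry practice for
flap-gliding seabirds:

1. split each axis into a static (1 s running mean, i.e. posture) and a
   dynamic (raw minus static, i.e. movement) component;
2. per-second Fourier spectrum of the heave axis gives the dominant cycle
   and its amplitude; K-means (k = 2) on these features separates flapping
   from non-flapping seconds;
3. non-flapping seconds are split into rafting on water (low raw-heave
   variability and a static heave level in the "water band") and
   soaring/gliding flight;
4. a non-flying second whose minimum body pitch drops below -25 deg is a
   surface-foraging second (head-down strike); pressure-detected dive
   seconds also count as foraging;
5. foraging seconds closer than 5 s are merged into foraging events.

VeDBA (vectorial dynamic body acceleration) summarises movement cost.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .config import AnalysisConfig
from .errors import ParameterError, SchemaError
from .io import AccelTrace

log = logging.getLogger("petrelbio")

LABELS = ("flap", "glide", "raft")


@dataclass
class StaticDynamic:
    """Static/dynamic decomposition of a tri-axial trace (static + dynamic = raw)."""

    rate_hz: float
    static: dict[str, np.ndarray]
    dynamic: dict[str, np.ndarray]


def running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with the window shrinking at the edges."""
    n = len(x)
    h = window // 2
    c = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    lo = np.clip(np.arange(n) - h, 0, n)
    hi = np.clip(np.arange(n) + (window - h), 0, n)
    return (c[hi] - c[lo]) / (hi - lo)


def decompose(trace: AccelTrace, window_s: float = 1.0) -> StaticDynamic:
    """Separate postural (static) from movement (dynamic) acceleration."""
    window = int(round(trace.rate_hz * window_s))
    if window < 3:
        raise ParameterError("decompose window must span >= 3 samples")
    if len(trace.ax) < window:
        raise SchemaError("trace shorter than the decomposition window")
    static = {}
    dynamic = {}
    for name, raw in (("ax", trace.ax), ("ay", trace.ay), ("az", trace.az)):
        s = running_mean(np.asarray(raw, float), window)
        static[name] = s
        dynamic[name] = np.asarray(raw, float) - s
    return StaticDynamic(trace.rate_hz, static, dynamic)


def body_pitch(static: StaticDynamic) -> np.ndarray:
    """Body pitch (deg) per sample: atan(surge / norm(sway, heave)).

    Strongly negative values indicate a head-down posture.  An all-zero
    static vector yields NaN.
    """
    ax = static.static["ax"]
    ay = static.static["ay"]
    az = static.static["az"]
    denom = np.sqrt(ay**2 + az**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pitch = np.degrees(np.arctan2(ax, denom))
    zero = (denom == 0) & (ax == 0)
    if np.any(zero):
        pitch = pitch.astype(float)
        pitch[zero] = np.nan
    return pitch


def vedba(dynamic: StaticDynamic) -> np.ndarray:
    """VeDBA (g) per sample: Euclidean norm of the three dynamic axes."""
    return np.sqrt(
        dynamic.dynamic["ax"] ** 2
        + dynamic.dynamic["ay"] ** 2
        + dynamic.dynamic["az"] ** 2
    )


def _per_second(x: np.ndarray, rate: int) -> np.ndarray:
    n_sec = len(x) // rate
    return x[: n_sec * rate].reshape(n_sec, rate)


def heave_spectral_features(
    heave: np.ndarray, rate_hz: float, window_s: float = 1.0
) -> pd.DataFrame:
    """Dominant cycle (s) and amplitude (g) of the heave axis per window.

    Discrete Fourier magnitude spectrum per non-overlapping window, DC
    excluded; the amplitude is ``2|c|/N`` at the dominant frequency.
    """
    if rate_hz < 10:
        raise ParameterError("spectral features need rate_hz >= 10")
    rate = int(round(rate_hz * window_s))
    win = _per_second(np.asarray(heave, float), rate)
    spec = np.abs(np.fft.rfft(win, axis=1))
    spec[:, 0] = 0.0  # exclude DC
    freqs = np.fft.rfftfreq(rate, d=window_s / rate)
    kmax = np.argmax(spec, axis=1)
    amp = 2.0 * spec[np.arange(len(win)), kmax] / rate
    cycle = 1.0 / freqs[np.maximum(kmax, 1)]
    return pd.DataFrame({"dominant_cycle_s": cycle, "cycle_amplitude_g": amp})


def cluster_flapping(
    features: pd.DataFrame, k: int = 2, seed: int = 0
) -> np.ndarray:
    """K-means (k = 2) on standardized spectral features; returns a boolean
    flapping flag per second (cluster with the higher mean amplitude)."""
    X = features[["dominant_cycle_s", "cycle_amplitude_g"]].to_numpy(float)
    if len(np.unique(X, axis=0)) < k:
        warnings.warn("identical spectral features; no flapping flagged")
        return np.zeros(len(X), bool)
    Xs = StandardScaler().fit_transform(X)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(Xs)
    amp = features["cycle_amplitude_g"].to_numpy(float)
    means = [amp[labels == c].mean() for c in range(k)]
    flap_cluster = int(np.argmax(means))
    return labels == flap_cluster


def _majority_smooth(codes: np.ndarray, window: int, n_classes: int) -> np.ndarray:
    """Sliding-window majority vote on integer label codes (ties keep original)."""
    if window <= 1:
        return codes
    onehot = np.zeros((len(codes), n_classes))
    onehot[np.arange(len(codes)), codes] = 1.0
    counts = np.column_stack(
        [running_mean(onehot[:, c], window) for c in range(n_classes)]
    )
    best = np.argmax(counts, axis=1)
    top = counts[np.arange(len(codes)), best]
    own = counts[np.arange(len(codes)), codes]
    out = np.where(top > own + 1e-12, best, codes)
    return out


def classify_behaviour(
    flapping: np.ndarray,
    heave_sd: np.ndarray,
    static_heave: np.ndarray,
    cfg: AnalysisConfig,
) -> np.ndarray:
    """Assign flap / raft / glide to each second.

    Flapping flag wins; otherwise a second with raw-heave s.d. at or below
    ``tau_water_g`` and a static heave inside ``water_band_g`` is rafting
    on water; anything else is gliding (soaring) flight.  A 3 s majority
    vote removes single-second flicker.
    """
    if cfg.tau_water_g is None or cfg.water_band_g is None:
        raise ParameterError("water thresholds not configured")
    lo, hi = cfg.water_band_g
    on_water = (heave_sd <= cfg.tau_water_g) & (static_heave >= lo) & (static_heave <= hi)
    codes = np.where(flapping, 0, np.where(on_water, 2, 1))
    codes = _majority_smooth(codes, int(cfg.smooth_window_s), 3)
    return np.array(LABELS)[codes]


def detect_foraging(
    labels: np.ndarray,
    min_pitch: np.ndarray,
    cfg: AnalysisConfig,
    dive_seconds: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Foraging second = not flying (rafting) with minimum within-second
    pitch below the threshold; pressure-detected dive seconds also count."""
    forage = (labels == "raft") & (min_pitch < cfg.pitch_threshold_deg)
    if dive_seconds is not None:
        forage = forage | dive_seconds
    return forage


@dataclass
class ForagingEvent:
    start_s: int
    end_s: int
    duration_s: int
    type: str  # surface | dive
    lat: float | None = None
    lon: float | None = None
    depth_m: float | None = None


def segment_events(
    is_foraging: np.ndarray,
    gap_s: float = 5.0,
    dive_seconds: Optional[np.ndarray] = None,
    track: Optional[pd.DataFrame] = None,
) -> list[ForagingEvent]:
    """Merge foraging seconds separated by at most ``gap_s`` into events.

    Event type is ``dive`` if it contains a dive second; the location is
    the interpolated track position at the event start.
    """
    secs = np.flatnonzero(np.asarray(is_foraging, bool))
    events: list[ForagingEvent] = []
    if len(secs) == 0:
        return events
    starts = [secs[0]]
    ends = []
    for prev, cur in zip(secs[:-1], secs[1:]):
        if cur - prev > gap_s:
            ends.append(prev)
            starts.append(cur)
    ends.append(secs[-1])
    for s, e in zip(starts, ends):
        etype = "surface"
        if dive_seconds is not None and np.any(dive_seconds[s : e + 1]):
            etype = "dive"
        lat = lon = None
        if track is not None and s < len(track):
            lat = float(track["lat"].iloc[s])
            lon = float(track["lon"].iloc[s])
        events.append(ForagingEvent(int(s), int(e), int(e - s + 1), etype, lat, lon))
    return events


def activity_budget(
    labels: np.ndarray,
    is_foraging: np.ndarray,
    local_hour: Optional[np.ndarray] = None,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Percent of trip seconds per behaviour, plus an hourly profile.

    Foraging is reported separately (it overlaps rafting/diving seconds),
    so flap + glide + raft = 100.
    """
    n = len(labels)
    budget = {lab: 100.0 * np.mean(labels == lab) for lab in LABELS}
    budget["foraging"] = 100.0 * float(np.mean(is_foraging))
    if local_hour is None:
        hourly = pd.DataFrame()
    else:
        df = pd.DataFrame({"hour": np.asarray(local_hour, int) % 24})
        for lab in LABELS:
            df[lab] = (labels == lab).astype(float) * 100.0
        df["foraging"] = np.asarray(is_foraging, float) * 100.0
        hourly = df.groupby("hour").mean().reset_index()
    return budget, hourly


def foraging_rate(
    events: Sequence[ForagingEvent],
    trip_duration_h: float,
    total_distance_km: float | None = None,
) -> dict[str, float]:
    """Events per hour and (when a distance is given) km travelled per event."""
    if trip_duration_h <= 0:
        raise ParameterError("trip duration must be > 0")
    n = len(events)
    out = {"n_events": float(n), "events_per_h": n / trip_duration_h}
    if total_distance_km is not None:
        out["km_per_event"] = total_distance_km / n if n else float("nan")
    return out


@dataclass
class EthogramResult:
    """Per-second ethogram plus the derived event list."""

    seconds: pd.DataFrame  # second_index, label, is_foraging, pitch_deg, vedba_g, ...
    events: list[ForagingEvent]
    budget: dict[str, float]
    hourly: pd.DataFrame


class EthogramClassifier(BaseEstimator):
    """Sklearn-style estimator wrapping the ethogram chain.

    ``fit`` learns the flapping / non-flapping K-means split from the
    per-second heave spectral features of a trace; ``predict`` returns the
    per-second behaviour labels.  The rule-based thresholds come from the
    :class:`AnalysisConfig` passed at construction.
    """

    def __init__(self, cfg: Optional[AnalysisConfig] = None, seed: int = 0):
        self.cfg = cfg
        self.seed = seed

    def _features(self, trace: AccelTrace):
        cfg = self.cfg or AnalysisConfig()
        rate = int(round(trace.rate_hz))
        sd = decompose(trace, cfg.decompose_window_s)
        feats = heave_spectral_features(trace.az, trace.rate_hz)
        raw_sec = _per_second(np.asarray(trace.az, float), rate)
        static_sec = _per_second(sd.static["az"], rate)
        pitch_sec = _per_second(body_pitch(sd), rate)
        vedba_sec = _per_second(vedba(sd), rate)
        n = len(feats)
        return cfg, sd, feats, {
            "heave_sd": raw_sec.std(axis=1, ddof=0)[:n],
            "static_heave": static_sec.mean(axis=1)[:n],
            "min_pitch": pitch_sec.min(axis=1)[:n],
            "vedba": vedba_sec.mean(axis=1)[:n],
        }

    def fit(self, trace: AccelTrace, y=None) -> "EthogramClassifier":
        cfg, _, feats, _ = self._features(trace)
        X = feats[["dominant_cycle_s", "cycle_amplitude_g"]].to_numpy(float)
        if len(np.unique(X, axis=0)) < cfg.kmeans_k:
            self.kmeans_ = None
            self.scaler_ = None
        else:
            self.scaler_ = StandardScaler().fit(X)
            self.kmeans_ = KMeans(
                n_clusters=cfg.kmeans_k, n_init=10, random_state=self.seed
            ).fit(self.scaler_.transform(X))
            amp = feats["cycle_amplitude_g"].to_numpy(float)
            lab = self.kmeans_.labels_
            self.flap_cluster_ = int(
                np.argmax([amp[lab == c].mean() for c in range(cfg.kmeans_k)])
            )
        return self

    def predict(self, trace: AccelTrace) -> np.ndarray:
        if not hasattr(self, "kmeans_"):
            raise ParameterError("EthogramClassifier is not fitted")
        cfg, _, feats, per_sec = self._features(trace)
        if self.kmeans_ is None:
            warnings.warn("identical spectral features; no flapping flagged")
            flapping = np.zeros(len(feats), bool)
        else:
            X = self.scaler_.transform(
                feats[["dominant_cycle_s", "cycle_amplitude_g"]].to_numpy(float)
            )
            flapping = self.kmeans_.predict(X) == self.flap_cluster_
        return classify_behaviour(
            flapping, per_sec["heave_sd"], per_sec["static_heave"], cfg
        )


def compute_ethogram(
    trace: AccelTrace,
    cfg: Optional[AnalysisConfig] = None,
    seed: int = 0,
    dive_seconds: Optional[np.ndarray] = None,
    track: Optional[pd.DataFrame] = None,
    local_hour: Optional[np.ndarray] = None,
) -> EthogramResult:
    """Run the full per-second classification on one deployment."""
    cfg = cfg or AnalysisConfig()
    clf = EthogramClassifier(cfg, seed=seed)
    clf.fit(trace)
    _, _, feats, per_sec = clf._features(trace)
    labels = clf.predict(trace)
    if dive_seconds is not None:
        dive_seconds = np.asarray(dive_seconds, bool)[: len(labels)]
        # pressure is authoritative: a submerged bird is on/under water
        labels = labels.copy()
        labels[dive_seconds] = "raft"
    forage = detect_foraging(labels, per_sec["min_pitch"], cfg, dive_seconds)
    events = segment_events(forage, cfg.event_gap_s, dive_seconds, track)
    budget, hourly = activity_budget(labels, forage, local_hour)
    flapping = labels == "flap"
    seconds = pd.DataFrame(
        {
            "second_index": np.arange(len(labels)),
            "label": labels,
            "is_foraging": forage,
            "pitch_deg": per_sec["min_pitch"],
            "vedba_g": per_sec["vedba"],
            "dominant_cycle_s": feats["dominant_cycle_s"].to_numpy(),
            "cycle_amplitude_g": feats["cycle_amplitude_g"].to_numpy(),
            "flapping_flag": flapping,
        }
    )
    return EthogramResult(seconds, events, budget, hourly)
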