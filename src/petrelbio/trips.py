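"""GPS cleaning, central-place trip segmentation and trip statistics.

Distances are great-circle (haversine) on a sphere of radius 6371 km;
home range is the convex hull of trip locations with its area measured by
spherical excess.  Trip-duration modality is assessed with the
skewness/kurtosis bimodality coefficient and normal-mixture mode
estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.stats import kurtosis, skew
from sklearn.mixture import GaussianMixture

from .config import AnalysisConfig
from .errors import ParameterError, SchemaError
from .io import GpsTrack

log = logging.getLogger("petrelbio")

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance (km) between coordinate pairs in degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class Trip:
    """A maximal at-sea excursion outside the colony radius."""

    deployment_id: str
    fixes: pd.DataFrame
    start: pd.Timestamp
    end: pd.Timestamp


@dataclass
class TripMetrics:
    duration_h: float
    max_distance_km: float
    total_distance_km: float
    mean_speed_kmh: float
    n_fixes: int


def filter_speed(track: GpsTrack, vmax_ms: float = 25.0) -> GpsTrack:
    """Drop fixes implying travel faster than ``vmax_ms`` m/s.

    Forward pass: each fix is tested against the last *retained* fix; the
    first fix is always kept.  Idempotent by construction.
    """
    df = track.fixes
    if len(df) <= 1:
        return track
    lat = df["lat"].to_numpy(float)
    lon = df["lon"].to_numpy(float)
    t = df["timestamp"].astype("int64").to_numpy() / 1e9
    keep = [0]
    last = 0
    for i in range(1, len(df)):
        dt = t[i] - t[last]
        d_m = haversine_km(lat[last], lon[last], lat[i], lon[i]) * 1000.0
        if dt > 0 and d_m / dt <= vmax_ms:
            keep.append(i)
            last = i
    dropped = len(df) - len(keep)
    if dropped:
        log.info("speed filter removed %d of %d fixes", dropped, len(df))
    return GpsTrack(df.iloc[keep].reset_index(drop=True), track.deployment_id)


def segment_trips(track: GpsTrack, cfg: AnalysisConfig) -> list[Trip]:
    """Split a deployment into trips: maximal runs of fixes outside the
    colony radius, bracketed by the nearest inside fixes.

    Runs with fewer than 3 fixes are discarded.  Fixes inside the radius
    stand in for on-land records (no landmask is applied).
    """
    df = track.fixes.reset_index(drop=True)
    if len(df) == 0:
        return []
    d = haversine_km(df["lat"], df["lon"], cfg.colony[0], cfg.colony[1])
    outside = np.asarray(d) > cfg.colony_radius_km
    trips: list[Trip] = []
    i = 0
    n = len(df)
    while i < n:
        if not outside[i]:
            i += 1
            continue
        j = i
        while j < n and outside[j]:
            j += 1
        if j - i >= 3:
            lo = max(i - 1, 0)
            hi = min(j, n - 1)
            sub = df.iloc[lo : hi + 1].reset_index(drop=True)
            trips.append(
                Trip(
                    deployment_id=track.deployment_id,
                    fixes=sub,
                    start=sub["timestamp"].iloc[0],
                    end=sub["timestamp"].iloc[-1],
                )
            )
        i = j
    if not trips:
        log.info("track %s never leaves the colony radius", track.deployment_id)
    return trips


def trip_metrics(trip: Trip, colony: tuple[float, float]) -> TripMetrics:
    """Duration, range, cumulative distance and mean speed of one trip."""
    df = trip.fixes
    dur_h = (trip.end - trip.start).total_seconds() / 3600.0
    if dur_h <= 0:
        raise SchemaError("zero-duration trip")
    lat = df["lat"].to_numpy(float)
    lon = df["lon"].to_numpy(float)
    legs = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    total = float(np.sum(legs))
    max_d = float(np.max(haversine_km(lat, lon, colony[0], colony[1])))
    return TripMetrics(
        duration_h=dur_h,
        max_distance_km=max_d,
        total_distance_km=total,
        mean_speed_kmh=total / dur_h,
        n_fixes=len(df),
    )


def interpolate(trip: Trip, interval_s: float = 1.0) -> pd.DataFrame:
    """Linearly interpolate the trip to a dense track.

    Returns a DataFrame (timestamp, lat, lon) sampled every ``interval_s``
    from the first fix; length ``floor(duration / interval) + 1``.
    """
    df = trip.fixes
    if len(df) < 2:
        raise SchemaError("interpolation needs >= 2 fixes")
    t = df["timestamp"].astype("int64").to_numpy() / 1e9
    dur = t[-1] - t[0]
    tq = t[0] + np.arange(int(np.floor(dur / interval_s)) + 1) * interval_s
    lat = np.interp(tq, t, df["lat"].to_numpy(float))
    lon = np.interp(tq, t, df["lon"].to_numpy(float))
    return pd.DataFrame(
        {
            "timestamp": pd.to_datetime((tq * 1e9).astype("int64"), utc=True),
            "lat": lat,
            "lon": lon,
        }
    )


def _sph_triangle_excess(a, b, c) -> float:
    # l'Huilier's theorem on unit vectors
    def ang(u, v):
        return 2 * np.arcsin(np.clip(np.linalg.norm(u - v) / 2, 0, 1))

    s1, s2, s3 = ang(a, b), ang(b, c), ang(c, a)
    s = (s1 + s2 + s3) / 2
    t = (
        np.tan(s / 2)
        * np.tan((s - s1) / 2)
        * np.tan((s - s2) / 2)
        * np.tan((s - s3) / 2)
    )
    return 4 * np.arctan(np.sqrt(max(t, 0.0)))


def mcp_area(lat, lon) -> float:
    """Area (km^2) of the convex hull of locations, by spherical excess.

    The hull is built in longitude/latitude coordinates (adequate at the
    sub-degree extents of foraging trips); its area is the sum of the
    spherical-triangle excesses of a fan triangulation times R^2.
    """
    pts = np.unique(np.column_stack([np.asarray(lon, float), np.asarray(lat, float)]),
                    axis=0)
    if len(pts) < 3:
        raise ParameterError("mcp_area needs >= 3 distinct points")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:
        raise ParameterError(f"degenerate (collinear?) point set: {exc}") from exc
    verts = pts[hull.vertices]  # counter-clockwise
    lam = np.radians(verts[:, 0])
    phi = np.radians(verts[:, 1])
    xyz = np.column_stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
    )
    excess = 0.0
    for i in range(1, len(xyz) - 1):
        excess += _sph_triangle_excess(xyz[0], xyz[i], xyz[i + 1])
    return float(excess * EARTH_RADIUS_KM**2)


def bimodality_coefficient(durations) -> float:
    """Sample bimodality coefficient BC = (g^2 + 1) / (k + 3(n-1)^2/((n-2)(n-3))).

    ``g`` is the bias-corrected sample skewness and ``k`` the bias-corrected
    excess kurtosis.  BC exceeding 5/9 (the uniform limit) flags possible
    bimodality; a normal sample tends to 1/3.
    """
    x = np.asarray(durations, float)
    n = len(x)
    if n < 4:
        raise ParameterError("bimodality coefficient needs n >= 4")
    g = skew(x, bias=False)
    k = kurtosis(x, bias=False, fisher=True)
    return float((g**2 + 1) / (k + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


BC_BIMODAL_THRESHOLD = 5.0 / 9.0


def estimate_modes(durations, max_components: int = 2, seed: int = 0):
    """Estimate mode locations by normal-mixture fit with BIC selection.

    Fits 1- and 2-component Gaussian mixtures on the untransformed values
    and returns ``[(location, weight), ...]`` sorted by location for the
    BIC-preferred model.  Degenerate samples fall back to a single mode.
    """
    x = np.asarray(durations, float).reshape(-1, 1)
    if len(x) < 10:
        raise ParameterError("mode estimation needs n >= 10")
    if np.ptp(x) < 1e-12:
        return [(float(x[0, 0]), 1.0)]
    best = None
    best_bic = np.inf
    for k in range(1, max_components + 1):
        gm = GaussianMixture(n_components=k, random_state=seed, n_init=3,
                             reg_covar=1e-6)
        gm.fit(x)
        bic = gm.bic(x)
        if np.any(gm.covariances_.ravel() < 1e-10):
            log.warning("degenerate %d-component fit; skipping", k)
            continue
        if bic < best_bic:
            best_bic, best = bic, gm
    if best is None:
        return [(float(np.mean(x)), 1.0)]
    modes = sorted(zip(best.means_.ravel().tolist(), best.weights_.tolist()))
    return [(float(m), float(w)) for m, w in modes]


def trips_table(trips: list[Trip], colony: tuple[float, float]) -> pd.DataFrame:
    """Per-trip metrics as a tidy table."""
    rows = []
    for k, trip in enumerate(trips):
        m = trip_metrics(trip, colony)
        rows.append(
            {
                "deployment_id": trip.deployment_id,
                "trip": k,
                "start": trip.start,
                "end": trip.end,
                "duration_h": m.duration_h,
                "max_distance_km": m.max_distance_km,
                "total_distance_km": m.total_distance_km,
                "mean_speed_kmh": m.mean_speed_kmh,
                "n_fixes": m.n_fixes,
            }
        )
    return pd.DataFrame(rows)
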