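"""Dive detection from a 1 Hz pressure channel.

Pressure converts to depth as D = 0.01 (Pm - Pa) with Pm the measured and
Pa the atmospheric pressure in mBar.  After zero-offset (surface-drift)
correction, a dive is a positive depth excursion whose maximum exceeds one
body length (0.55 m, strictly).  The fleet descent rate is the
zero-intercept least-squares slope of maximum depth on descent duration;
it converts dive durations into depth estimates for loggers without a
pressure sensor (symmetric V-shaped dives: descent occupies half the
dive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .ethogram import ForagingEvent

log = logging.getLogger("petrelbio")


@dataclass
class Dive:
    start_s: float
    end_s: float
    duration_s: float
    max_depth_m: float
    descent_duration_s: float
    descent_rate_ms: float
    source: str = "pressure"  # pressure | estimated


def pressure_to_depth(pm_mbar: np.ndarray, pa_mbar: float) -> np.ndarray:
    """Depth (m) from measured pressure: D = 0.01 (Pm - Pa).

    Negative values are permitted before surface-drift correction.
    """
    if pa_mbar <= 0:
        raise ParameterError("atmospheric pressure must be > 0")
    return 0.01 * (np.asarray(pm_mbar, float) - pa_mbar)


def _rolling_quantile(x: np.ndarray, window: int, q: float) -> np.ndarray:
    s = pd.Series(x)
    return (
        s.rolling(window, min_periods=1, center=True).quantile(q).to_numpy()
    )


def correct_surface_drift(
    depth: np.ndarray,
    rate_hz: float = 1.0,
    window_s: float = 600.0,
    quantile: float = 0.02,
) -> np.ndarray:
    """Zero-offset correction: re-anchor the surface reading to 0 m.

    Subtracts a rolling lower-quantile baseline (default 2% over 10 min);
    because a low quantile of noisy surface samples sits below the true
    surface by about ``z_q`` standard deviations, the sensor noise s.d. is
    estimated robustly from first differences and the corresponding offset
    added back, so the corrected surface is unbiased.  A window longer
    than the series degrades to a single global baseline.
    """
    x = np.asarray(depth, float)
    window = int(round(window_s * rate_hz))
    if window >= len(x):
        base = np.full_like(x, np.quantile(x, quantile))
    else:
        base = _rolling_quantile(x, window, quantile)
    # robust noise sd from lag-1 differences: sd(diff) = sqrt(2) * sigma
    d = np.diff(x)
    sigma = float(np.median(np.abs(d - np.median(d)))) / 0.6744897501960817 / np.sqrt(2)
    from scipy.stats import norm

    z = abs(norm.ppf(quantile))
    return x - base - z * sigma


def detect_dives(
    depth: np.ndarray,
    threshold_m: float = 0.55,
    rate_hz: float = 1.0,
    surface_band_m: float = 0.1,
) -> list[Dive]:
    """Detect dives on a corrected depth series.

    A candidate excursion is a maximal run of samples with depth above a
    small surface band (default 0.1 m, ~2 sigma of a 5 mBar sensor);
    boundaries are refined by linear interpolation to the zero crossing.
    Excursions are retained iff the maximum depth strictly exceeds
    ``threshold_m``.  Descent duration runs from the (interpolated) start
    to the time of maximum depth; descent rate is their ratio.
    """
    x = np.asarray(depth, float)
    above = x > surface_band_m
    dives: list[Dive] = []
    n = len(x)
    i = 0
    dt = 1.0 / rate_hz
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        # run [i, j); refine boundaries toward depth == 0
        k_apex = i + int(np.argmax(x[i:j]))
        max_depth = float(x[k_apex])
        if max_depth > threshold_m:
            # start refinement: with >= 2 samples on the descent leg the
            # zero crossing extrapolates from the leg's fitted line (the
            # bracketing surface sample is noise, not on the leg);
            # otherwise interpolate against the bracketing sample, whose
            # noise may push the unbiased crossing just outside it
            if k_apex > i:
                tt = np.arange(i, k_apex + 1, dtype=float)
                slope, icpt = np.polyfit(tt, x[i : k_apex + 1], 1)
                if slope > 0:
                    t_start = np.clip(-icpt / slope, i - 2.0, i) * dt
                else:
                    t_start = i * dt
            elif i > 0 and x[i] > x[i - 1]:
                frac = (0.0 - x[i - 1]) / (x[i] - x[i - 1])
                t_start = (i - 1 + np.clip(frac, -0.5, 1.0)) * dt
            else:
                t_start = i * dt
            if j < n and x[j - 1] > x[j]:
                frac = (x[j - 1] - 0.0) / (x[j - 1] - x[j])
                t_end = (j - 1 + np.clip(frac, 0.0, 1.5)) * dt
            else:
                t_end = (j - 1) * dt
            descent = max(k_apex * dt - t_start, dt / 2)
            dives.append(
                Dive(
                    start_s=float(t_start),
                    end_s=float(t_end),
                    duration_s=float(t_end - t_start),
                    max_depth_m=max_depth,
                    descent_duration_s=float(descent),
                    descent_rate_ms=max_depth / descent,
                )
            )
        i = j
    return dives


def fleet_descent_rate(dives: Sequence[Dive]) -> tuple[float, np.ndarray]:
    """Zero-intercept least-squares slope of max depth on descent duration.

    Returns ``(fleet rate m/s, per-dive rates)``; needs >= 3 pressure dives.
    """
    if len(dives) < 3:
        raise ParameterError("fleet descent rate needs >= 3 dives")
    d = np.array([dv.max_depth_m for dv in dives])
    t = np.array([dv.descent_duration_s for dv in dives])
    slope = float(np.sum(d * t) / np.sum(t**2))
    return slope, d / t


def depth_from_duration(duration_s: float, rate_ms: float) -> float:
    """Estimate dive depth from duration for a pressure-less logger.

    Symmetric V-shape: the descent occupies half the dive, so
    ``depth = rate * duration / 2``.
    """
    if duration_s < 0 or rate_ms <= 0:
        raise ParameterError("duration must be >= 0 and rate > 0")
    return rate_ms * duration_s / 2.0


def validate_detection(
    accel_events: Sequence[ForagingEvent],
    pressure_dives: Sequence[Dive],
    match_window_s: float = 2.0,
) -> float:
    """Percent of pressure dives overlapped (within +/- match_window_s) by an
    acceleration-derived foraging event.  NaN when there are no dives."""
    if len(pressure_dives) == 0:
        return float("nan")
    if len(accel_events) == 0:
        return 0.0
    starts = np.array([e.start_s - match_window_s for e in accel_events])
    ends = np.array([e.end_s + match_window_s for e in accel_events])
    hit = 0
    for dv in pressure_dives:
        if np.any((starts <= dv.end_s) & (ends >= dv.start_s)):
            hit += 1
    return 100.0 * hit / len(pressure_dives)


def dive_seconds_mask(dives: Sequence[Dive], n_seconds: int) -> np.ndarray:
    """Boolean per-second mask of seconds lying within any dive."""
    mask = np.zeros(n_seconds, bool)
    for dv in dives:
        lo = int(np.floor(dv.start_s))
        hi = int(np.ceil(dv.end_s))
        mask[max(lo, 0) : min(hi + 1, n_seconds)] = True
    return mask


def dives_table(dives: Sequence[Dive]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_s": dv.start_s,
                "end_s": dv.end_s,
                "duration_s": dv.duration_s,
                "max_depth_m": dv.max_depth_m,
                "descent_duration_s": dv.descent_duration_s,
                "descent_rate_ms": dv.descent_rate_ms,
                "source": dv.source,
            }
            for dv in dives
        ]
    )
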