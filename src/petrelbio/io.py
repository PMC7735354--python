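"""Readers and writers for the pipeline's delimited-text artifacts.

All files are plain delimited text (comma by default, tab accepted) with a
header row; file-level metadata (start time, sampling rate, deployment id)
travels in ``# key=value`` comment lines above the header.  Readers
validate schemas strictly and report the offending line; writers
round-trip losslessly at the written precision.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import SchemaError

log = logging.getLogger("petrelbio")

GPS_COLUMNS = ["timestamp", "lat", "lon"]
MORPHO_COLUMNS = [
    "bird_id",
    "sex",
    "culmen_depth_mm",
    "culmen_width_mm",
    "culmen_length_mm",
    "wing_length_mm",
    "tarsus_length_mm",
    "mass_g",
]
ISOTOPE_COLUMNS = ["bird_id", "sex", "year", "d15N", "d13C"]


@dataclass
class GpsTrack:
    """Timestamped GPS fixes for one deployment."""

    fixes: pd.DataFrame  # columns: timestamp (UTC datetime), lat, lon
    deployment_id: str = "unknown"

    def __post_init__(self) -> None:
        df = self.fixes
        missing = [c for c in GPS_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"GPS track missing columns {missing}")
        if len(df) == 0:
            return
        ts = df["timestamp"]
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            bad = int(np.flatnonzero(ts.diff().dt.total_seconds().fillna(1) <= 0)[0])
            raise SchemaError(
                f"GPS timestamps not strictly increasing at row {bad} "
                f"({ts.iloc[bad]!s})"
            )
        if (df["lat"].abs() > 90).any():
            bad = int(df.index[df["lat"].abs() > 90][0])
            raise SchemaError(f"latitude out of [-90, 90] at row {bad}")
        if (df["lon"].abs() > 180).any():
            bad = int(df.index[df["lon"].abs() > 180][0])
            raise SchemaError(f"longitude out of [-180, 180] at row {bad}")

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class AccelTrace:
    """25 Hz tri-axial acceleration (g), with optional 1 Hz pressure (mBar).

    Axis convention: ``ax`` surge (anterior positive), ``ay`` sway,
    ``az`` heave (dorsal positive).
    """

    start_time: pd.Timestamp
    rate_hz: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    pressure: Optional[np.ndarray] = None
    pressure_rate_hz: float = 1.0
    deployment_id: str = "unknown"

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise SchemaError("rate_hz must be > 0")
        n = len(self.ax)
        if not (len(self.ay) == len(self.az) == n):
            raise SchemaError(
                f"axis length mismatch: ax={len(self.ax)} ay={len(self.ay)} "
                f"az={len(self.az)}"
            )
        if self.pressure is not None:
            dur_s = n / self.rate_hz
            npress = len(self.pressure)
            expected = dur_s * self.pressure_rate_hz
            if abs(npress - expected) > max(2.0, 0.01 * expected):
                raise SchemaError(
                    f"pressure length {npress} inconsistent with "
                    f"{dur_s:.0f} s at {self.pressure_rate_hz} Hz"
                )

    @property
    def duration_s(self) -> float:
        return len(self.ax) / self.rate_hz


def _read_meta_and_table(path: Path, parse_dates: list[str] | None = None):
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if line.startswith("#"):
                pos += len(line)
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
            else:
                break
        fh.seek(pos)
        text = fh.read()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    try:
        df = pd.read_csv(_io.StringIO(text), sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise SchemaError(f"{path}: unparsable table ({exc})") from exc
    if parse_dates:
        for col in parse_dates:
            if col in df.columns:
                try:
                    df[col] = pd.to_datetime(df[col], utc=True, format="ISO8601")
                except (ValueError, TypeError) as exc:
                    raise SchemaError(f"{path}: bad timestamp in '{col}': {exc}")
    return meta, df


def read_gps(path: str | Path) -> GpsTrack:
    """Read a GPS log (columns timestamp, lat, lon; ISO-8601 UTC times)."""
    path = Path(path)
    meta, df = _read_meta_and_table(path, parse_dates=["timestamp"])
    missing = [c for c in GPS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in ("lat", "lon"):
        if not np.issubdtype(df[col].dtype, np.number) or df[col].isna().any():
            bad = int(df.index[~pd.to_numeric(df[col], errors="coerce").notna()][0])
            raise SchemaError(f"{path}: unparsable {col} at row {bad}")
    try:
        return GpsTrack(df[GPS_COLUMNS].copy(), meta.get("deployment_id", path.stem))
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_gps(track: GpsTrack, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# deployment_id={track.deployment_id}\n")
        df = track.fixes.copy()
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
        df.to_csv(fh, index=False, float_format="%.8f")
    return path


def read_accel(path: str | Path, pressure_path: str | Path | None = None) -> AccelTrace:
    """Read a tri-axial acceleration log (columns ax, ay, az).

    Sampling metadata comes from ``# start_time=``, ``# rate_hz=`` comment
    lines.  Pressure, sampled at its own (lower) rate, lives in a separate
    file with a ``pressure_mbar`` column.
    """
    path = Path(path)
    meta, df = _read_meta_and_table(path)
    missing = [c for c in ("ax", "ay", "az") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in ("ax", "ay", "az"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(df.index[vals.isna()][0])
            raise SchemaError(f"{path}: unparsable or missing {col} at row {bad}")
    if "start_time" not in meta or "rate_hz" not in meta:
        raise SchemaError(f"{path}: missing '# start_time=' / '# rate_hz=' metadata")
    pressure = None
    p_rate = 1.0
    if pressure_path is not None:
        pmeta, pdf = _read_meta_and_table(Path(pressure_path))
        if "pressure_mbar" not in pdf.columns:
            raise SchemaError(f"{pressure_path}: missing column pressure_mbar")
        pressure = pdf["pressure_mbar"].to_numpy(float)
        p_rate = float(pmeta.get("rate_hz", 1.0))
    try:
        return AccelTrace(
            start_time=pd.Timestamp(meta["start_time"]),
            rate_hz=float(meta["rate_hz"]),
            ax=df["ax"].to_numpy(float),
            ay=df["ay"].to_numpy(float),
            az=df["az"].to_numpy(float),
            pressure=pressure,
            pressure_rate_hz=p_rate,
            deployment_id=meta.get("deployment_id", path.stem),
        )
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_accel(trace: AccelTrace, path: str | Path,
                pressure_path: str | Path | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# deployment_id={trace.deployment_id}\n")
        fh.write(f"# start_time={trace.start_time.isoformat()}\n")
        fh.write(f"# rate_hz={trace.rate_hz:g}\n")
        pd.DataFrame({"ax": trace.ax, "ay": trace.ay, "az": trace.az}).to_csv(
            fh, index=False, float_format="%.6f"
        )
    if trace.pressure is not None and pressure_path is not None:
        with open(pressure_path, "w") as fh:
            fh.write(f"# deployment_id={trace.deployment_id}\n")
            fh.write(f"# start_time={trace.start_time.isoformat()}\n")
            fh.write(f"# rate_hz={trace.pressure_rate_hz:g}\n")
            pd.DataFrame({"pressure_mbar": trace.pressure}).to_csv(
                fh, index=False, float_format="%.4f"
            )
    return path


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a morphometric (``kind='morpho'``) or isotope (``'isotope'``) table."""
    path = Path(path)
    cols = {"morpho": MORPHO_COLUMNS, "isotope": ISOTOPE_COLUMNS}
    if kind not in cols:
        raise SchemaError(f"unknown table kind {kind!r}")
    _, df = _read_meta_and_table(path)
    missing = [c for c in cols[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad_sex = ~df["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise SchemaError(f"{path}: invalid sex at row {int(df.index[bad_sex][0])}")
    numeric = [c for c in cols[kind] if c not in ("bird_id", "sex")]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        if not np.isfinite(vals).all():
            raise SchemaError(
                f"{path}: non-finite {col} at row "
                f"{int(df.index[~np.isfinite(vals)][0])}"
            )
    if kind == "morpho":
        meas = df[[c for c in MORPHO_COLUMNS if c.endswith(('_mm', '_g'))]]
        if (meas <= 0).any().any():
            raise SchemaError(f"{path}: non-positive measurement")
    if kind == "isotope" and df.duplicated(["bird_id", "year"]).any():
        raise SchemaError(f"{path}: duplicate bird-year row")
    return df[cols[kind]].copy()


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> Path:
    """Write any result table as delimited text with optional metadata lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)
    return path


def write_points(df: pd.DataFrame, path: str | Path,
                 lat: str = "lat", lon: str = "lon") -> Path:
    """Export rows with coordinates as WKT point-geometry text (CSV + WKT column)."""
    out = df.copy()
    out["geometry_wkt"] = [
        f"POINT ({x:.8f} {y:.8f})" for x, y in zip(out[lon], out[lat])
    ]
    return write_table(out, path)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(results: dict[str, pd.DataFrame], out_dir: str | Path,
                  meta: dict | None = None) -> dict[str, Path]:
    """Write a named set of result tables into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in sorted(results):
        paths[name] = write_table(results[name], out_dir / f"{name}.csv", meta)
        log.info("wrote %s", paths[name])
    return paths
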