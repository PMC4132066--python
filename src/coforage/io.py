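"""Tabular input/output: GPS fixes, depth samples, deployment metadata, results.

All readers accept plain comma-separated text with a header row (UTF-8).
Timestamps are parsed to UTC; naive timestamps are assumed UTC and a
warning is logged.  Times are stored internally as timezone-naive
``datetime64[ns]`` values on the UTC timeline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

GPS_SCHEMA = {"id": "id", "timestamp": "timestamp", "lat": "lat", "lon": "lon"}
TDR_SCHEMA = {"id": "id", "timestamp": "timestamp", "depth": "depth_m"}
DEPLOYMENT_SCHEMA = {
    "id": "id",
    "sex": "sex",
    "nest_id": "nest_id",
    "nest_lat": "nest_lat",
    "nest_lon": "nest_lon",
    "date": "date",
}


class SchemaError(ValueError):
    """A required column is absent or a configuration value is invalid."""


class RowError(ValueError):
    """A data row violates a parsing rule or a field invariant."""


@dataclass(frozen=True)
class ColonySite:
    """The central place all trips start from and return to."""

    lat: float
    lon: float
    rafting_radius_m: float = 1000.0

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0 and -180.0 < self.lon <= 180.0):
            raise ValueError(f"colony coordinates out of range: {self.lat}, {self.lon}")
        if self.rafting_radius_m <= 0:
            raise ValueError("rafting_radius_m must be positive")


def _resolve_schema(schema: Mapping[str, str] | None, default: Mapping[str, str]) -> dict:
    out = dict(default)
    if schema:
        unknown = set(schema) - set(default)
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        out.update(schema)
    return out


def _require_columns(df: pd.DataFrame, cols: Mapping[str, str], path) -> None:
    for key, name in cols.items():
        if name not in df.columns:
            raise SchemaError(f"{path}: missing required column '{name}' (role: {key})")


def parse_timestamps(series: pd.Series, context: str = "") -> pd.Series:
    """Parse a string column to tz-naive UTC timestamps.

    Raises :class:`RowError` naming the first offending line (1-based,
    header counted as line 1) when a value cannot be parsed.
    """
    try:
        parsed = pd.to_datetime(series, errors="coerce")
    except (ValueError, TypeError):
        parsed = pd.to_datetime(series, errors="coerce", utc=True)
    if parsed.isna().any():
        bad = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise RowError(
            f"{context}: unparseable timestamp {series.iloc[bad]!r} at line {bad + 2}"
        )
    if getattr(parsed.dt, "tz", None) is None:
        logger.warning("%s: naive timestamps assumed to be UTC", context or "timestamps")
        return parsed
    return parsed.dt.tz_convert("UTC").dt.tz_localize(None)


def _read_csv(path) -> pd.DataFrame | None:
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return None


def _sort_dedup(df: pd.DataFrame, context: str) -> pd.DataFrame:
    """Sort by time and collapse exact-duplicate timestamps to the first row."""
    df = df.sort_values("time", kind="stable").reset_index(drop=True)
    dup = df["time"].duplicated(keep="first")
    if dup.any():
        logger.warning("%s: dropped %d duplicate-timestamp rows", context, int(dup.sum()))
        df = df[~dup].reset_index(drop=True)
    return df


def read_gps_csv(path, schema: Mapping[str, str] | None = None) -> dict[str, pd.DataFrame]:
    """Read a GPS fix table.

    Parameters
    ----------
    path :
        CSV file with columns ``id, timestamp, lat, lon`` (names
        configurable through `schema`).
    schema :
        Optional mapping overriding the default column names, keyed by
        role (``id``, ``timestamp``, ``lat``, ``lon``).

    Returns
    -------
    dict
        ``individual_id -> DataFrame(time, lat, lon)``, each frame sorted by
        time with exact-duplicate timestamps collapsed to the first occurrence.
    """
    cols = _resolve_schema(schema, GPS_SCHEMA)
    raw = _read_csv(path)
    if raw is None or raw.empty:
        logger.warning("%s: empty GPS file", path)
        return {}
    _require_columns(raw, cols, path)
    lat = pd.to_numeric(raw[cols["lat"]], errors="coerce")
    lon = pd.to_numeric(raw[cols["lon"]], errors="coerce")
    bad = ~((lat >= -90) & (lat <= 90) & (lon > -180) & (lon <= 180))
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowError(
            f"{path}: coordinate out of range (lat={lat.iloc[i]}, lon={lon.iloc[i]}) "
            f"at line {i + 2}"
        )
    df = pd.DataFrame(
        {
            "individual_id": raw[cols["id"]].astype(str),
            "time": parse_timestamps(raw[cols["timestamp"]], str(path)),
            "lat": lat.astype(float),
            "lon": lon.astype(float),
        }
    )
    out: dict[str, pd.DataFrame] = {}
    n_in, n_out = len(df), 0
    for ind, sub in df.groupby("individual_id", sort=True):
        sub = _sort_dedup(sub[["time", "lat", "lon"]], f"{path}:{ind}")
        out[str(ind)] = sub
        n_out += len(sub)
    logger.info("%s: read %d fixes for %d individuals (%d rows dropped)",
                path, n_out, len(out), n_in - n_out)
    return out


def read_tdr_csv(path, schema: Mapping[str, str] | None = None) -> dict[str, pd.DataFrame]:
    """Read a time-depth record table into ``id -> DataFrame(time, depth_m)``.

    Depth is metres, positive downward; negative values are retained
    (pre-correction baseline drift is expected).  The modal sampling
    interval per individual is computed and logged.
    """
    cols = _resolve_schema(schema, TDR_SCHEMA)
    raw = _read_csv(path)
    if raw is None or raw.empty:
        logger.warning("%s: empty TDR file", path)
        return {}
    _require_columns(raw, cols, path)
    depth = pd.to_numeric(raw[cols["depth"]], errors="coerce")
    if not np.isfinite(depth.to_numpy(dtype=float)).all():
        i = int(np.flatnonzero(~np.isfinite(depth.to_numpy(dtype=float)))[0])
        raise RowError(f"{path}: non-finite depth at line {i + 2}")
    df = pd.DataFrame(
        {
            "individual_id": raw[cols["id"]].astype(str),
            "time": parse_timestamps(raw[cols["timestamp"]], str(path)),
            "depth_m": depth.astype(float),
        }
    )
    out: dict[str, pd.DataFrame] = {}
    for ind, sub in df.groupby("individual_id", sort=True):
        sub = _sort_dedup(sub[["time", "depth_m"]], f"{path}:{ind}")
        out[str(ind)] = sub
        if len(sub) > 1:
            steps = np.diff(sub["time"].to_numpy().astype("datetime64[ns]").astype("int64")) / 1e9
            vals, counts = np.unique(steps, return_counts=True)
            mode = float(vals[np.argmax(counts)])
            frac = counts.max() / len(steps)
            logger.info("%s:%s mode sampling interval %.3g s (%.0f%% of steps)",
                        path, ind, mode, 100 * frac)
            if frac < 0.9:
                logger.warning("%s:%s sampling interval not near-constant", path, ind)
    return out


def read_deployments_csv(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read deployment metadata: id, sex, nest_id, nest coordinates, date."""
    cols = _resolve_schema(schema, DEPLOYMENT_SCHEMA)
    raw = _read_csv(path)
    if raw is None or raw.empty:
        logger.warning("%s: empty deployments file", path)
        return pd.DataFrame(
            columns=["individual_id", "sex", "nest_id", "nest_lat", "nest_lon", "date"]
        )
    _require_columns(raw, cols, path)
    sex = raw[cols["sex"]].astype(str).str.strip().str.lower()
    sex = sex.where(sex.isin(["female", "male"]), "unknown")
    df = pd.DataFrame(
        {
            "individual_id": raw[cols["id"]].astype(str),
            "sex": sex,
            "nest_id": raw[cols["nest_id"]].astype(str),
            "nest_lat": pd.to_numeric(raw[cols["nest_lat"]]),
            "nest_lon": pd.to_numeric(raw[cols["nest_lon"]]),
            "date": pd.to_datetime(raw[cols["date"]]).dt.date.astype(str),
        }
    )
    dup = df.duplicated(subset=["individual_id", "date"])
    if dup.any():
        raise RowError(f"{path}: duplicate individual/date rows: "
                       f"{df.loc[dup, 'individual_id'].tolist()}")
    return df


def read_colony(path) -> ColonySite:
    """Read a colony site description from YAML or JSON ({lat, lon, rafting_radius_m})."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict) or "lat" not in data or "lon" not in data:
        raise SchemaError(f"{path}: colony file must define 'lat' and 'lon'")
    return ColonySite(
        lat=float(data["lat"]),
        lon=float(data["lon"]),
        rafting_radius_m=float(data.get("rafting_radius_m", 1000.0)),
    )


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    """Write each named table as ``<out_dir>/<name>.csv``.

    Empty tables produce header-only files.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in tables.items():
        p = out_dir / f"{name}.csv"
        table.to_csv(p, index=False)
        written[name] = p
        logger.info("wrote %s (%d rows)", p, len(table))
    return written


def track_geojson(tracks: Mapping[str, pd.DataFrame]) -> dict:
    """Build a GeoJSON FeatureCollection of LineStrings, one per individual.

    `tracks` maps individual id to a frame with ``lat``/``lon`` columns in
    time order.  Intended for quick map inspection only.
    """
    features = []
    for ind, df in tracks.items():
        coords = [[float(x), float(y)] for x, y in zip(df["lon"], df["lat"])]
        features.append(
            {
                "type": "Feature",
                "properties": {"individual_id": str(ind)},
                "geometry": {"type": "LineString", "coordinates": coords},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_track_geojson(tracks: Mapping[str, pd.DataFrame], path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(track_geojson(tracks)))
    return path
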