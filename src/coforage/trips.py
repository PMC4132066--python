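"""Trip processing: speed filtering, colony-based trip segmentation,
regular-grid linear interpolation and per-trip summaries.

Interpolation is done in raw latitude/longitude.  At the trip scales this
package targets (tens of kilometres, mid latitudes) the error relative to a
projected interpolation is well below GPS accuracy; this is a documented
limitation, not a general-purpose geodesy routine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from coforage._timeutil import from_seconds, to_seconds
from coforage.io import ColonySite

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in metres on a sphere of radius 6,371,000 m.

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return float(d) if d.ndim == 0 else d


@dataclass
class Trip:
    """One complete foraging trip: colony departure to colony return."""

    individual_id: str
    departure_time: pd.Timestamp
    return_time: pd.Timestamp
    fixes: pd.DataFrame  # columns: time, lat, lon (filtered, time-sorted)

    def __post_init__(self) -> None:
        if not self.departure_time < self.return_time:
            raise ValueError("departure_time must precede return_time")

    @property
    def duration_h(self) -> float:
        return (self.return_time - self.departure_time).total_seconds() / 3600.0

    @property
    def path_distance_km(self) -> float:
        lat = self.fixes["lat"].to_numpy()
        lon = self.fixes["lon"].to_numpy()
        if len(lat) < 2:
            return 0.0
        return float(np.sum(haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:]))) / 1000.0


@dataclass
class InterpolatedTrack:
    """A trip resampled onto a regular time grid anchored at departure."""

    individual_id: str
    grid_step_s: float
    times_s: np.ndarray  # float seconds since epoch, strictly increasing
    lat: np.ndarray
    lon: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return from_seconds(self.times_s)

    @property
    def start_s(self) -> float:
        return float(self.times_s[0])

    @property
    def end_s(self) -> float:
        return float(self.times_s[-1])

    def positions_at(self, t_s) -> tuple[np.ndarray, np.ndarray]:
        """Linear interpolation of (lat, lon) at float-second instants.

        Instants outside the track span yield NaN.
        """
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        lat = np.interp(t, self.times_s, self.lat)
        lon = np.interp(t, self.times_s, self.lon)
        outside = (t < self.times_s[0]) | (t > self.times_s[-1])
        lat[outside] = np.nan
        lon[outside] = np.nan
        return lat, lon

    def path_length_km(self, start_s: float | None = None, end_s: float | None = None) -> float:
        """Path length along the track between two instants (clipped to the span)."""
        t0 = self.start_s if start_s is None else max(start_s, self.start_s)
        t1 = self.end_s if end_s is None else min(end_s, self.end_s)
        if t1 <= t0:
            return 0.0
        interior = self.times_s[(self.times_s > t0) & (self.times_s < t1)]
        ts = np.concatenate(([t0], interior, [t1]))
        lat, lon = self.positions_at(ts)
        if len(ts) < 2:
            return 0.0
        return float(np.sum(haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:]))) / 1000.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"individual_id": self.individual_id, "time": self.times,
             "lat": self.lat, "lon": self.lon}
        )


def speed_filter(
    fixes: pd.DataFrame, vmax_ms: float = 2.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward-pass speed filter.

    Walks the track keeping a "last retained" fix and drops any fix whose
    speed from that fix strictly exceeds `vmax_ms`.  The first fix is always
    retained.  Returns ``(retained, removed)`` frames.
    """
    if len(fixes) < 2:
        logger.warning("speed_filter: fewer than 2 fixes, returned unchanged")
        return fixes.reset_index(drop=True), fixes.iloc[0:0].reset_index(drop=True)
    t = to_seconds(fixes["time"])
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)
    keep = np.zeros(len(fixes), dtype=bool)
    keep[0] = True
    last = 0
    for i in range(1, len(fixes)):
        dt = t[i] - t[last]
        if dt <= 0:
            continue  # duplicate timestamp survivors: unreachable after ingestion
        v = haversine_m(lat[last], lon[last], lat[i], lon[i]) / dt
        if v <= vmax_ms:
            keep[i] = True
            last = i
    retained = fixes[keep].reset_index(drop=True)
    removed = fixes[~keep].reset_index(drop=True)
    frac = len(removed) / len(fixes)
    logger.info("speed_filter: removed %d/%d fixes (%.1f%%)", len(removed), len(fixes), 100 * frac)
    return retained, removed


def segment_trips(
    fixes: pd.DataFrame,
    colony: ColonySite,
    colony_radius_m: float = 150.0,
    individual_id: str = "",
) -> tuple[list[Trip], int]:
    """Split a filtered fix series into complete foraging trips.

    A trip spans from the last fix within `colony_radius_m` of the colony
    before an excursion to the first fix within the radius after it.
    Excursions that never return before the record ends are counted as
    incomplete and excluded.

    Returns ``(trips, n_incomplete)``.
    """
    if len(fixes) == 0:
        return [], 0
    d = haversine_m(fixes["lat"].to_numpy(), fixes["lon"].to_numpy(), colony.lat, colony.lon)
    inside = np.atleast_1d(d) <= colony_radius_m
    if inside.all():
        logger.warning("segment_trips(%s): no fix ever leaves the colony radius", individual_id)
        return [], 0
    trips: list[Trip] = []
    n_incomplete = 0
    i = 0
    n = len(fixes)
    while i < n:
        if inside[i]:
            i += 1
            continue
        # excursion starting at i; anchor at the previous inside fix if any
        start = i - 1 if i > 0 and inside[i - 1] else i
        j = i
        while j < n and not inside[j]:
            j += 1
        if j == n:
            n_incomplete += 1
            logger.warning("segment_trips(%s): incomplete excursion at record end excluded",
                           individual_id)
            break
        sub = fixes.iloc[start : j + 1].reset_index(drop=True)
        if sub["time"].iloc[0] < sub["time"].iloc[-1]:
            trips.append(
                Trip(
                    individual_id=individual_id,
                    departure_time=pd.Timestamp(sub["time"].iloc[0]),
                    return_time=pd.Timestamp(sub["time"].iloc[-1]),
                    fixes=sub,
                )
            )
        i = j + 1
    return trips, n_incomplete


def interpolate_track(trip: Trip, grid_step_s: float = 60.0) -> InterpolatedTrack:
    """Resample a trip onto a regular grid anchored at the departure time.

    Latitude and longitude are linearly interpolated independently between
    the bracketing retained fixes.  The grid covers departure..return; the
    return instant is appended when the span is not a whole number of steps
    so the track always reaches the final fix.
    """
    t = to_seconds(trip.fixes["time"])
    lat = trip.fixes["lat"].to_numpy(dtype=float)
    lon = trip.fixes["lon"].to_numpy(dtype=float)
    t0, t1 = t[0], t[-1]
    n_steps = int(np.floor((t1 - t0) / grid_step_s + 1e-9))
    grid = t0 + grid_step_s * np.arange(n_steps + 1)
    if grid[-1] < t1 - 1e-9:
        grid = np.append(grid, t1)
    return InterpolatedTrack(
        individual_id=trip.individual_id,
        grid_step_s=float(grid_step_s),
        times_s=grid,
        lat=np.interp(grid, t, lat),
        lon=np.interp(grid, t, lon),
    )


def trip_summary(trip: Trip, colony: ColonySite) -> dict:
    """Duration (h), path distance over retained fixes (km), max range from colony (km)."""
    d = haversine_m(trip.fixes["lat"].to_numpy(), trip.fixes["lon"].to_numpy(),
                    colony.lat, colony.lon)
    return {
        "individual_id": trip.individual_id,
        "departure": trip.departure_time,
        "return": trip.return_time,
        "duration_h": trip.duration_h,
        "distance_km": trip.path_distance_km,
        "max_range_km": float(np.max(np.atleast_1d(d))) / 1000.0,
    }
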