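"""Dive detection, the bout-ending criterion, bout assignment and bout metrics.

The bout-ending criterion (BEC) comes from a two-process exponential
mixture fitted by maximum likelihood to a per-dive sequence variable
(post-dive surface intervals by default, absolute sequential differences
as an option):

    f(t) = p * lf * exp(-lf t) + (1 - p) * ls * exp(-ls t),  lf > ls > 0

The criterion is the crossing point of the two weighted processes,

    BEC = ln( p*lf / ((1-p)*ls) ) / (lf - ls)

Surface intervals shorter than the BEC connect dives into the same bout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from coforage._timeutil import from_seconds, to_seconds
from coforage.trips import InterpolatedTrack, haversine_m

logger = logging.getLogger(__name__)

BOUT_VARIABLES = ("postdive", "postdive_diff", "duration_diff")


@dataclass
class Dive:
    """One detected submergence."""

    individual_id: str
    start_s: float
    duration_s: float
    max_depth_m: float
    postdive_s: float = np.nan  # surface time until the next dive start; NaN for last dive
    lat: float = np.nan
    lon: float = np.nan
    location_ok: bool = False
    bout_id: int = -1

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("dive duration must be positive")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(from_seconds([self.start_s])[0])

    @property
    def end(self) -> pd.Timestamp:
        return pd.Timestamp(from_seconds([self.end_s])[0])


@dataclass
class DiveBout:
    """A run of dives grouped by the bout-ending criterion."""

    individual_id: str
    bout_id: int
    dives: list[Dive]
    horizontal_km: float = np.nan

    @property
    def start_s(self) -> float:
        return self.dives[0].start_s

    @property
    def end_s(self) -> float:
        return self.dives[-1].end_s

    @property
    def duration_min(self) -> float:
        return (self.end_s - self.start_s) / 60.0

    @property
    def n_dives(self) -> int:
        return len(self.dives)


class BoutFitError(RuntimeError):
    """Raised when the two-process model cannot be fitted; carries the best attempt."""

    def __init__(self, message: str, best: "BoutModelFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class BoutModelFit:
    """Maximum-likelihood fit of the two-process exponential mixture."""

    p_fast: float
    lambda_fast: float
    lambda_slow: float
    loglik: float
    n: int
    converged: bool = True

    @property
    def bec_s(self) -> float:
        return bec_from_params(self.p_fast, self.lambda_fast, self.lambda_slow)


def bec_from_params(p_fast: float, lambda_fast: float, lambda_slow: float) -> float:
    """Closed-form bout-ending criterion of the two-process mixture.

    Defined where the fast and slow weighted densities cross:
    ``ln(p*lf / ((1-p)*ls)) / (lf - ls)``.  Returns NaN when the fast
    process never dominates (``p*lf <= (1-p)*ls``).
    """
    num = p_fast * lambda_fast
    den = (1.0 - p_fast) * lambda_slow
    if num <= 0 or den <= 0 or lambda_fast <= lambda_slow:
        return float("nan")
    if num <= den:
        return float("nan")
    return float(np.log(num / den) / (lambda_fast - lambda_slow))


def zero_offset_correct(
    samples: pd.DataFrame, window_s: float = 300.0, quantile: float = 0.02
) -> pd.DataFrame:
    """Remove pressure-sensor surface drift from a constant-interval depth series.

    The surface baseline is the given low quantile of depths in
    consecutive windows of `window_s`, linearly interpolated between
    window centres, subtracted from the series; negative corrected depths
    are clamped to zero.

    Parameters
    ----------
    samples : DataFrame with ``time`` and ``depth_m`` columns.
    """
    if len(samples) == 0:
        return samples.copy()
    t = to_seconds(samples["time"])
    depth = samples["depth_m"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = float(np.median(np.diff(t)))
        if window_s < 3 * dt:
            raise ValueError(f"zoc window {window_s}s shorter than 3 samples ({3 * dt}s)")
    n_win = max(1, int(np.ceil((t[-1] - t[0] + 1e-9) / window_s)))
    centers = np.empty(n_win)
    base = np.empty(n_win)
    for k in range(n_win):
        lo = t[0] + k * window_s
        m = (t >= lo) & (t < lo + window_s)
        if not m.any():  # pragma: no cover - contiguous series always fills windows
            centers[k], base[k] = lo + window_s / 2, np.nan
            continue
        centers[k] = 0.5 * (t[m][0] + t[m][-1])
        base[k] = np.quantile(depth[m], quantile)
    ok = np.isfinite(base)
    baseline = np.interp(t, centers[ok], base[ok])
    corrected = np.clip(depth - baseline, 0.0, None)
    out = samples.copy()
    out["depth_m"] = corrected
    return out


def detect_dives(
    samples: pd.DataFrame, dive_threshold_m: float = 1.0, individual_id: str = ""
) -> list[Dive]:
    """Detect dives as maximal runs of samples at or below ``-threshold`` depth.

    A dive starts at the first sample with depth >= threshold and ends one
    sampling interval after the last such sample, so durations are
    multiples of the sampling interval.  The post-dive interval is the
    surface time until the next dive start (undefined for the last dive).
    """
    if len(samples) == 0:
        return []
    t = to_seconds(samples["time"])
    depth = samples["depth_m"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    wet = depth >= dive_threshold_m
    if not wet.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], wet.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]  # [start, stop) sample-index runs
    dives: list[Dive] = []
    for s, e in zip(starts, stops):
        dives.append(
            Dive(
                individual_id=individual_id,
                start_s=float(t[s]),
                duration_s=float((e - s) * dt),
                max_depth_m=float(depth[s:e].max()),
            )
        )
    for a, b in zip(dives[:-1], dives[1:]):
        a.postdive_s = b.start_s - a.end_s
    return dives


def sequential_differences(values) -> np.ndarray:
    """Absolute differences between successive values of a per-dive variable."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return np.empty(0)
    return np.abs(np.diff(v))


def criterion_values(dives: list[Dive], variable: str = "postdive") -> np.ndarray:
    """Observations of the configured bout variable for BEC fitting.

    ``postdive``: raw post-dive surface intervals (terminal NaN dropped).
    ``postdive_diff``/``duration_diff``: absolute sequential differences of
    post-dive intervals or dive durations.
    """
    if variable not in BOUT_VARIABLES:
        raise ValueError(f"unknown bout variable {variable!r}; choose from {BOUT_VARIABLES}")
    pd_vals = np.array([d.postdive_s for d in dives], dtype=float)
    pd_vals = pd_vals[np.isfinite(pd_vals)]
    if variable == "postdive":
        return pd_vals
    if variable == "postdive_diff":
        return sequential_differences(pd_vals)
    return sequential_differences([d.duration_s for d in dives])


def _mixture_nll(theta: np.ndarray, x: np.ndarray) -> float:
    a, b, c = theta
    log_p, log_q = -np.logaddexp(0, -a), -np.logaddexp(0, a)  # log sigmoid / log(1-sigmoid)
    lf, ls = np.exp(b), np.exp(c)
    ll = np.logaddexp(log_p + b - lf * x, log_q + c - ls * x)
    return -float(np.sum(ll))


def single_exponential_loglik(values) -> float:
    """Log-likelihood of the one-process (single exponential) MLE fit."""
    x = np.asarray(values, dtype=float)
    m = float(np.mean(x))
    if m <= 0:
        raise ValueError("values must have positive mean")
    return float(len(x) * (-np.log(m) - 1.0))


def fit_bout_model(
    values, seed: int = 0, n_starts: int = 6, min_n_warn: int = 30
) -> BoutModelFit:
    """Fit the two-process exponential mixture by multi-start maximum likelihood.

    Starting points are a method-of-moments split at the data median plus
    ``n_starts - 1`` jittered variants (seeded).  Raises
    :class:`BoutFitError` carrying the best partial fit when no start
    converges or the fitted processes are not separable (BEC undefined).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError(f"need at least 4 observations, got {len(x)}")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("values must be finite and non-negative")
    if np.ptp(x) == 0:
        raise ValueError("degenerate data: all values equal")
    if len(x) < min_n_warn:
        logger.warning("fit_bout_model: only %d observations (< %d recommended)", len(x), min_n_warn)

    med = np.median(x)
    fast = x[x <= med]
    slow = x[x > med]
    lf0 = 1.0 / max(np.mean(fast), 1e-6)
    ls0 = 1.0 / max(np.mean(slow), 1e-6)
    if ls0 >= lf0:
        ls0 = lf0 / 10.0
    rng = np.random.default_rng(seed)
    starts = [np.array([logit(0.5), np.log(lf0), np.log(ls0)])]
    for _ in range(max(0, n_starts - 1)):
        jitter = rng.normal(0, [0.7, 0.5, 0.5])
        starts.append(starts[0] + jitter)

    best = None
    best_converged = False
    for theta0 in starts:
        res = minimize(_mixture_nll, theta0, args=(x,), method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
            best_converged = bool(res.success)
        elif res.success and abs(res.fun - best.fun) <= 1e-12:
            best_converged = True

    a, b, c = best.x
    p, lf, ls = float(expit(a)), float(np.exp(b)), float(np.exp(c))
    if lf < ls:  # relabel so the fast process is first
        lf, ls, p = ls, lf, 1.0 - p
    fit = BoutModelFit(p_fast=p, lambda_fast=lf, lambda_slow=ls,
                       loglik=-float(best.fun), n=len(x), converged=best_converged)
    if not best_converged:
        raise BoutFitError("two-process fit did not converge from any start", best=fit)
    if not np.isfinite(fit.bec_s) or fit.bec_s <= 0:
        raise BoutFitError("fitted processes are not separable (BEC undefined)", best=fit)
    return fit


def assign_bouts_from_criterion(
    dives: list[Dive], link_values, bec_s: float, individual_id: str | None = None
) -> list[DiveBout]:
    """Group dives into bouts from explicit link criterion values.

    ``link_values[i]`` connects dive ``i`` to dive ``i+1``; a link value
    >= `bec_s` starts a new bout at dive ``i+1``.
    """
    if len(dives) == 0:
        return []
    links = np.asarray(link_values, dtype=float)
    if len(links) != len(dives) - 1:
        raise ValueError("need exactly one link value per consecutive dive pair")
    ind = dives[0].individual_id if individual_id is None else individual_id
    bouts: list[DiveBout] = []
    current = [dives[0]]
    for link, nxt in zip(links, dives[1:]):
        if link >= bec_s:
            bouts.append(DiveBout(ind, len(bouts), current))
            current = [nxt]
        else:
            current.append(nxt)
    bouts.append(DiveBout(ind, len(bouts), current))
    for bout in bouts:
        for d in bout.dives:
            d.bout_id = bout.bout_id
    return bouts


def bout_link_values(dives: list[Dive], variable: str = "postdive") -> np.ndarray:
    """Per-link criterion values (length ``n_dives - 1``) for bout assignment.

    For difference variables the terminal link cannot be formed (the last
    dive has no post-dive interval); it falls back to comparing the raw
    post-dive interval of the preceding dive, which is on the BEC scale of
    the raw variable and errs toward splitting only after long surface
    periods.
    """
    n = len(dives)
    if n < 2:
        return np.empty(0)
    pd_vals = np.array([d.postdive_s for d in dives], dtype=float)
    if variable == "postdive":
        return pd_vals[:-1]
    if variable == "postdive_diff":
        links = np.abs(np.diff(pd_vals))  # link i -> i+1 uses |pd[i+1] - pd[i]|
        links[-1] = pd_vals[-2] if not np.isfinite(links[-1]) else links[-1]
        return links
    if variable == "duration_diff":
        return np.abs(np.diff([d.duration_s for d in dives]))
    raise ValueError(f"unknown bout variable {variable!r}")


def assign_bouts(dives: list[Dive], bec_s: float, variable: str = "postdive") -> list[DiveBout]:
    """Group a trip's dives into bouts using the configured criterion variable."""
    if len(dives) == 0:
        return []
    return assign_bouts_from_criterion(dives, bout_link_values(dives, variable), bec_s)


def bout_horizontal_distance(bout: DiveBout, track: InterpolatedTrack) -> float:
    """Horizontal distance (km) along the interpolated track spanned by a bout.

    Bouts shorter than one grid step (e.g. single-dive bouts) use the
    distance between the two bracketing grid points covering the dive.
    """
    if bout.end_s - bout.start_s >= track.grid_step_s:
        return track.path_length_km(bout.start_s, bout.end_s)
    t0 = track.start_s + np.floor((bout.start_s - track.start_s) / track.grid_step_s) * track.grid_step_s
    t1 = t0 + track.grid_step_s
    t0 = max(t0, track.start_s)
    t1 = min(t1, track.end_s)
    if t1 <= t0:
        return 0.0
    lat, lon = track.positions_at([t0, t1])
    return float(haversine_m(lat[0], lon[0], lat[1], lon[1])) / 1000.0


def locate_dives(dives: list[Dive], track: InterpolatedTrack) -> list[Dive]:
    """Attach interpolated (lat, lon) at each dive start; flag dives off-track."""
    if not dives:
        return dives
    starts = np.array([d.start_s for d in dives])
    lat, lon = track.positions_at(starts)
    n_flagged = 0
    for d, la, lo in zip(dives, lat, lon):
        d.lat, d.lon = float(la), float(lo)
        d.location_ok = bool(np.isfinite(la) and np.isfinite(lo))
        n_flagged += not d.location_ok
    if n_flagged:
        logger.warning("locate_dives: %d dives outside the track span flagged", n_flagged)
    return dives


def dives_to_frame(dives: list[Dive]) -> pd.DataFrame:
    rows = [
        {
            "individual_id": d.individual_id,
            "start": d.start,
            "end": d.end,
            "duration_s": d.duration_s,
            "max_depth_m": d.max_depth_m,
            "postdive_s": d.postdive_s,
            "lat": d.lat,
            "lon": d.lon,
            "bout_id": d.bout_id,
        }
        for d in dives
    ]
    cols = ["individual_id", "start", "end", "duration_s", "max_depth_m",
            "postdive_s", "lat", "lon", "bout_id"]
    return pd.DataFrame(rows, columns=cols)


def bouts_to_frame(bouts: list[DiveBout]) -> pd.DataFrame:
    rows = [
        {
            "individual_id": b.individual_id,
            "bout_id": b.bout_id,
            "start": pd.Timestamp(from_seconds([b.start_s])[0]),
            "end": pd.Timestamp(from_seconds([b.end_s])[0]),
            "duration_min": b.duration_min,
            "n_dives": b.n_dives,
            "horiz_km": b.horizontal_km,
        }
        for b in bouts
    ]
    cols = ["individual_id", "bout_id", "start", "end", "duration_min", "n_dives", "horiz_km"]
    return pd.DataFrame(rows, columns=cols)
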