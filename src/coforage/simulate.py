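"""Seeded synthetic deployments with ground truth for every pipeline stage.

Each simulated individual performs one out-and-back foraging trip from the
colony: a straight-ish outbound commute, a bounded correlated-random-walk
meander with dive bouts, a homing inbound commute, a stationary "rafting"
period near the colony and a final walk ashore.  Paired individuals are
coupled by construction: the partner's position is the focal position plus
a radial offset whose magnitude follows a piecewise-linear schedule, so
association episodes exist exactly where planned and their boundaries are
known analytically.

Dive bouts follow a two-process surface-interval structure (fast
within-bout intervals, slow shifted between-bout intervals) and planned
synchronous dives share start instants to within the configured offsets.
GPS outlier fixes are injected by displacing points far enough to force
apparent speeds above the filtering threshold.

All randomness derives from the single seed in :class:`SimConfig`;
identical configurations are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from coforage._timeutil import from_seconds, to_seconds
from coforage.association import (
    AssociationEpisode,
    AssociationParameters,
    SyncDivePair,
    annotate_contexts,
    classify_track,
    classifications_to_frame,
)
from coforage.dives import Dive, DiveBout, bouts_to_frame, dives_to_frame
from coforage.io import ColonySite
from coforage.trips import Trip, haversine_m, segment_trips

logger = logging.getLogger(__name__)

M_PER_DEG_LAT = 111_194.93  # 2*pi*R/360 on the shared sphere radius


@dataclass(frozen=True)
class EpisodePlan:
    """One planned association episode, positioned within the at-sea window.

    `start_frac` places the episode start within the feasible at-sea
    window (0 = earliest, 1 = latest given the duration).
    """

    start_frac: float
    duration_s: float
    target_distance_m: float = 300.0
    n_sync_dives: int = 0


@dataclass(frozen=True)
class PairPlan:
    """A coupled dyad: ids, planned episodes and commute behaviour."""

    id_a: str
    id_b: str
    episodes: tuple[EpisodePlan, ...] = ()
    commute_together: bool = False
    suppress_dives_in_episodes: bool = False


def default_pair_plans() -> tuple[PairPlan, ...]:
    """Five dyads spanning the full range of association categories."""
    return (
        PairPlan("P01", "P02", commute_together=True,
                 episodes=(EpisodePlan(0.35, 4800.0, 300.0, 6),
                           EpisodePlan(0.85, 3600.0, 250.0, 4))),
        PairPlan("P03", "P04", commute_together=False,
                 episodes=(EpisodePlan(0.35, 4800.0, 300.0, 5),
                           EpisodePlan(0.85, 3600.0, 300.0, 3))),
        PairPlan("P05", "P06", commute_together=False,
                 episodes=(EpisodePlan(0.5, 4800.0, 300.0, 0),)),
        PairPlan("P07", "P08", commute_together=False, suppress_dives_in_episodes=True,
                 episodes=(EpisodePlan(0.5, 3600.0, 300.0, 0),)),
        PairPlan("P09", "P10", commute_together=True, episodes=()),
    )


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic deployment (all randomness from `seed`)."""

    seed: int = 0
    colony_lat: float = -38.6219
    colony_lon: float = 142.9325
    date: str = "2012-10-01"
    depart_hour: float = 5.0
    gps_step_s: float = 120.0
    tdr_step_s: float = 4.0
    # trip geometry and timing
    trip_duration_mean_h: float = 14.8
    trip_duration_sd_h: float = 4.1
    trip_duration_min_pair_h: float = 10.0
    trip_duration_min_solo_h: float = 8.0
    trip_duration_max_h: float = 24.0
    commute_duration_s: float = 4320.0
    raft_duration_s: float = 1800.0
    raft_distance_m: float = 400.0
    speed_commute_ms: float = 1.3
    # calibrated so the measured mean per-bout horizontal distance (along the
    # interpolated track, bout-edge steps mixing bout and rest speeds) is ~0.99 km
    speed_bout_ms: float = 1.45
    speed_rest_ms: float = 0.2
    crw_turn_sd: float = 0.4
    meander_radius_m: float = 1500.0
    # dive bout structure (two-process surface intervals)
    bout_start_offset_s: float = 1200.0
    dives_per_bout_poisson: float = 13.59
    dive_duration_poisson: float = 8.0  # x tdr_step_s
    postdive_within_mean_s: float = 20.0
    interbout_shift_s: float = 300.0
    interbout_exp_mean_s: float = 500.0
    depth_logmean: float = 1.609
    depth_logsd: float = 0.6
    depth_min_m: float = 1.5
    depth_max_m: float = 26.0
    zoc_drift_amplitude_m: float = 0.35
    zoc_drift_period_s: float = 3600.0
    # pair coupling
    offset_rate_ms: float = 0.5
    far_distance_m: float = 1500.0
    start_offset_m: float = 30.0
    raft_offset_m: float = 25.0
    partner_bout_lag_s: float = 16.0
    # measurement noise
    gps_noise_m: float = 3.0
    outlier_fix_rate: float = 0.07
    outlier_min_m: float = 400.0
    outlier_max_m: float = 900.0
    # thresholds used when computing ground truth
    assoc_radius_m: float = 500.0
    min_duration_s: float = 744.0
    rafting_radius_m: float = 1000.0
    colony_radius_m: float = 150.0
    # deployment plan
    pair_plans: tuple[PairPlan, ...] = field(default_factory=default_pair_plans)
    solo_ids: tuple[str, ...] = ("S01", "S02")

    def colony(self) -> ColonySite:
        return ColonySite(self.colony_lat, self.colony_lon, self.rafting_radius_m)

    @property
    def individual_ids(self) -> list[str]:
        ids = []
        for p in self.pair_plans:
            ids.extend([p.id_a, p.id_b])
        ids.extend(self.solo_ids)
        return ids


@dataclass
class GroundTruth:
    """Generator-side truth, consistent with the raw series by construction."""

    trips: pd.DataFrame          # individual_id, departure, return
    dives: pd.DataFrame          # per-dive rows incl. bout_id
    bouts: pd.DataFrame
    episodes: pd.DataFrame       # id_a, id_b, start, end, context
    sync_dives: pd.DataFrame     # id_a, id_b, t_a, t_b, delta_s
    classification: pd.DataFrame  # individual_id, group
    outlier_fixes: pd.DataFrame  # individual_id, time of each injected outlier
    clean_tracks: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class SimResult:
    gps: pd.DataFrame
    tdr: pd.DataFrame
    deployments: pd.DataFrame
    truth: GroundTruth
    config: SimConfig

    def write(self, out_dir) -> None:
        """Write the raw tables, colony file and ground truth as plain CSV/YAML."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.gps.to_csv(out / "gps.csv", index=False)
        self.tdr.to_csv(out / "tdr.csv", index=False)
        self.deployments.to_csv(out / "deployments.csv", index=False)
        (out / "colony.yaml").write_text(yaml.safe_dump({
            "lat": self.config.colony_lat,
            "lon": self.config.colony_lon,
            "rafting_radius_m": self.config.rafting_radius_m,
        }))
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        self.truth.trips.to_csv(truth_dir / "trips.csv", index=False)
        self.truth.dives.to_csv(truth_dir / "dives.csv", index=False)
        self.truth.bouts.to_csv(truth_dir / "bouts.csv", index=False)
        self.truth.episodes.to_csv(truth_dir / "episodes.csv", index=False)
        self.truth.sync_dives.to_csv(truth_dir / "sync_dives.csv", index=False)
        self.truth.classification.to_csv(truth_dir / "classification.csv", index=False)
        self.truth.outlier_fixes.to_csv(truth_dir / "outlier_fixes.csv", index=False)


# ---------------------------------------------------------------------------
# building blocks

def _round_step(x: float, step: float) -> float:
    return float(np.round(x / step) * step)


def _draw_duration(rng, cfg: SimConfig, is_pair: bool) -> float:
    lo = cfg.trip_duration_min_pair_h if is_pair else cfg.trip_duration_min_solo_h
    T = rng.normal(cfg.trip_duration_mean_h, cfg.trip_duration_sd_h)
    T = float(np.clip(T, lo, cfg.trip_duration_max_h)) * 3600.0
    return _round_step(T, cfg.gps_step_s)


@dataclass
class _Timing:
    """Phase boundaries of one trip, all in seconds relative to departure."""

    T: float
    commute_end: float
    bout_window: tuple[float, float]  # where dive bouts may be placed
    raft_start: float

    @classmethod
    def build(cls, cfg: SimConfig, T: float) -> "_Timing":
        C = cfg.commute_duration_s
        raft_start = T - cfg.raft_duration_s
        D = cfg.speed_commute_ms * C
        inbound_reserve = (D + cfg.meander_radius_m + 1000.0) / cfg.speed_commute_ms
        sea_end = raft_start - inbound_reserve
        lo = C + cfg.bout_start_offset_s
        if sea_end - lo < 2 * cfg.min_duration_s:
            raise ValueError(f"infeasible plan: trip of {T/3600:.1f} h leaves no at-sea window")
        return cls(T=T, commute_end=C, bout_window=(lo, sea_end), raft_start=raft_start)


def _episode_windows(cfg: SimConfig, plan: PairPlan, timing: _Timing) -> list[tuple[float, float, EpisodePlan]]:
    lo, hi = timing.bout_window
    windows = []
    for ep in sorted(plan.episodes, key=lambda e: e.start_frac):
        start = lo + ep.start_frac * max(0.0, hi - lo - ep.duration_s)
        start = _round_step(start, cfg.tdr_step_s)
        windows.append((start, start + ep.duration_s, ep))
    return windows


def _offset_waypoints(cfg: SimConfig, plan: PairPlan, timing: _Timing,
                      windows: list[tuple[float, float, EpisodePlan]]) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear separation schedule m(t) for a coupled dyad.

    Raises ``ValueError`` before any generation when ramps at the
    configured rate cannot connect the planned episodes.
    """
    rate = cfg.offset_rate_ms
    far = cfg.far_distance_m
    pts: list[tuple[float, float]] = [(0.0, cfg.start_offset_m)]

    def extend(t: float, m: float, what: str) -> None:
        t_prev, m_prev = pts[-1]
        need = abs(m - m_prev) / rate
        if t - t_prev + 1e-9 < need:
            raise ValueError(
                f"infeasible association plan ({plan.id_a}/{plan.id_b}): {what} needs "
                f"{need:.0f}s ramp but only {t - t_prev:.0f}s available")
        if t - t_prev > need:
            pts.append((t - need, m_prev))
        pts.append((t, m))

    if plan.commute_together:
        pts.append((timing.commute_end, cfg.start_offset_m))
    t_prev, m_prev = pts[-1]
    pts.append((t_prev + (far - m_prev) / rate, far))  # separate after departure/commute
    for start, end, ep in windows:
        extend(start, ep.target_distance_m, "episode approach")
        pts.append((end, ep.target_distance_m))
        # depart toward far unless the next waypoint comes first; handled lazily
        t_prev, m_prev = pts[-1]
        t_far = t_prev + (far - m_prev) / rate
        nxt = None
        for s2, _, _ in windows:
            if s2 > start:
                nxt = s2
                break
        if nxt is None or t_far < nxt:
            pts.append((t_far, far))
    extend(timing.raft_start, cfg.raft_offset_m, "rafting approach")
    pts.append((timing.T, cfg.raft_offset_m))
    t = np.array([p[0] for p in pts])
    m = np.array([p[1] for p in pts])
    if np.any(np.diff(t) < -1e-9):
        raise ValueError(f"infeasible association plan ({plan.id_a}/{plan.id_b}): overlapping ramps")
    return t, m


def _dive_schedule(rng, cfg: SimConfig, timing: _Timing) -> list[dict]:
    """Dive bouts with two-process surface intervals; times on the TDR grid."""
    step = cfg.tdr_step_s
    lo, hi = timing.bout_window
    t = lo
    dives: list[dict] = []
    while True:
        n_d = 1 + rng.poisson(cfg.dives_per_bout_poisson)
        bout: list[dict] = []
        tb = t
        for k in range(n_d):
            dur = step * max(1, rng.poisson(cfg.dive_duration_poisson))
            depth = float(np.clip(np.exp(rng.normal(cfg.depth_logmean, cfg.depth_logsd)),
                                  cfg.depth_min_m, cfg.depth_max_m))
            bout.append({"start": tb, "dur": dur, "depth": depth})
            tb += dur
            if k < n_d - 1:
                tb += max(step, _round_step(rng.exponential(cfg.postdive_within_mean_s), step))
        if tb > hi:  # whole bouts only: truncation would bias durations low
            return dives
        dives.extend(bout)
        t = tb + _round_step(cfg.interbout_shift_s + rng.exponential(cfg.interbout_exp_mean_s), step)
        if t >= hi:
            return dives


def _partner_schedule(rng, cfg: SimConfig, timing: _Timing, focal: list[dict]) -> list[dict]:
    """A partner's dives: focal bout timing at a fixed lag, fresh depths.

    Mirroring the focal timing keeps both members' bout durations and
    inter-bout gaps identical (no spurious bout merges), while the fixed
    lag (well above the synchrony window) prevents accidental synchrony.
    """
    lag = _round_step(rng.uniform(12.0, 24.0), cfg.tdr_step_s)
    return [
        {"start": d["start"] + lag, "dur": d["dur"],
         "depth": float(np.clip(np.exp(rng.normal(cfg.depth_logmean, cfg.depth_logsd)),
                                cfg.depth_min_m, cfg.depth_max_m))}
        for d in focal
        if d["start"] + lag + d["dur"] <= timing.bout_window[1] + 600.0
    ]


def _split_bouts(schedule: list[dict], gap_s: float) -> list[list[dict]]:
    """Group a dive schedule into bouts: a surface gap >= gap_s starts a new bout."""
    bouts: list[list[dict]] = []
    for d in schedule:
        if bouts and d["start"] - (bouts[-1][-1]["start"] + bouts[-1][-1]["dur"]) < gap_s:
            bouts[-1].append(d)
        else:
            bouts.append([d])
    return bouts


def _bout_intervals(schedule: list[dict], gap_s: float) -> list[tuple[float, float]]:
    return [(b[0]["start"], b[-1]["start"] + b[-1]["dur"]) for b in _split_bouts(schedule, gap_s)]


def _simulate_path(rng, cfg: SimConfig, timing: _Timing, heading: float,
                   bout_iv: list[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Focal track in local metres; returns (times_rel, x, y)."""
    step = cfg.gps_step_s
    n = int(round(timing.T / step)) + 1
    times = np.arange(n) * step
    x = np.zeros(n)
    y = np.zeros(n)
    D = cfg.speed_commute_ms * timing.commute_end
    centroid = np.array([np.cos(heading), np.sin(heading)]) * D
    raft_pt = np.array([np.cos(heading), np.sin(heading)]) * cfg.raft_distance_m
    walk_steps = int(np.ceil(cfg.raft_distance_m / (cfg.speed_commute_ms * step)))
    h = heading
    mode = "commute"
    pos = np.zeros(2)
    iv = np.array(bout_iv).reshape(-1, 2)

    def bout_overlap(t0: float, t1: float) -> float:
        if len(iv) == 0:
            return 0.0
        return float(np.sum(np.clip(np.minimum(iv[:, 1], t1) - np.maximum(iv[:, 0], t0), 0, None)))

    for i in range(1, n):
        t0, t1 = times[i - 1], times[i]
        if mode == "commute":
            h = heading + rng.normal(0, 0.05)
            pos = pos + cfg.speed_commute_ms * step * np.array([np.cos(h), np.sin(h)])
            if t1 >= timing.commute_end:
                mode = "meander"
                h = heading + rng.normal(0, cfg.crw_turn_sd)
        elif mode == "meander":
            to_raft = raft_pt - pos
            d_raft = float(np.hypot(*to_raft))
            remaining = timing.raft_start - t1
            if d_raft >= remaining * cfg.speed_commute_ms:
                mode = "homing"
            else:
                off = pos - centroid
                if float(np.hypot(*off)) > cfg.meander_radius_m:
                    h = float(np.arctan2(-off[1], -off[0])) + rng.normal(0, 0.3)
                else:
                    h += rng.normal(0, cfg.crw_turn_sd)
                ov = bout_overlap(t0, t1)
                dist = cfg.speed_bout_ms * ov + cfg.speed_rest_ms * (step - ov)
                pos = pos + dist * np.array([np.cos(h), np.sin(h)])
                y[i], x[i] = pos[1], pos[0]
                continue
        if mode == "homing":
            to_raft = raft_pt - pos
            d_raft = float(np.hypot(*to_raft))
            if d_raft <= cfg.speed_commute_ms * step:
                pos = raft_pt.copy()
                mode = "raft"
            else:
                pos = pos + to_raft / d_raft * cfg.speed_commute_ms * step
        elif mode == "raft":
            if i >= n - 1 - walk_steps:
                mode = "walk"
            else:
                pos = raft_pt + rng.normal(0, 3.0, size=2)
        if mode == "walk":
            to_colony = -pos
            d = float(np.hypot(*to_colony))
            if i == n - 1 or d <= cfg.speed_commute_ms * step:
                pos = np.zeros(2)
            else:
                pos = pos + to_colony / d * cfg.speed_commute_ms * step
        x[i], y[i] = pos[0], pos[1]
    x[-1], y[-1] = 0.0, 0.0
    return times, x, y


def _xy_to_latlon(cfg: SimConfig, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lat = cfg.colony_lat + np.asarray(y) / M_PER_DEG_LAT
    lon = cfg.colony_lon + np.asarray(x) / (M_PER_DEG_LAT * np.cos(np.radians(cfg.colony_lat)))
    return lat, lon


def _apply_noise_and_outliers(rng, cfg: SimConfig, x: np.ndarray, y: np.ndarray):
    """Small positional jitter plus displaced outlier fixes; returns (x, y, outlier_idx)."""
    n = len(x)
    xo, yo = x.copy(), y.copy()
    if n > 4:
        jitter = rng.normal(0, cfg.gps_noise_m, size=(n - 2, 2))
        xo[1:-1] += jitter[:, 0]
        yo[1:-1] += jitter[:, 1]
    eligible = np.arange(3, n - 3)
    picks = eligible[rng.random(len(eligible)) < cfg.outlier_fix_rate]
    keep = []
    last = -10
    for i in picks:  # no adjacent outliers: keeps per-fix removals independent
        if i - last >= 2:
            keep.append(i)
            last = i
    for i in keep:
        ang = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(cfg.outlier_min_m, cfg.outlier_max_m)
        xo[i] += r * np.cos(ang)
        yo[i] += r * np.sin(ang)
    return xo, yo, np.array(keep, dtype=int)


def _suppress_window(schedule: list[dict], lo: float, hi: float) -> list[dict]:
    return [d for d in schedule if d["start"] + d["dur"] < lo or d["start"] > hi]


def _apply_pair_dive_edits(rng, cfg: SimConfig, plan: PairPlan,
                           windows: list[tuple[float, float, EpisodePlan]],
                           focal: list[dict], partner: list[dict]):
    """Suppress, de-synchronise and inject dives per the pair plan.

    Returns ``(focal, partner, sync_records)`` where sync records are
    ``(t_focal, t_partner)`` relative seconds.
    """
    sync_records: list[tuple[float, float]] = []

    def ramp_pad(ep: EpisodePlan) -> float:
        # the dyad is already within the association radius while ramping
        # between far separation and the episode's target distance
        return max(0.0, cfg.assoc_radius_m - ep.target_distance_m) / cfg.offset_rate_ms

    if plan.suppress_dives_in_episodes:
        for lo, hi, ep in windows:
            pad = ramp_pad(ep) + 60.0
            focal = _suppress_window(focal, lo - pad, hi + pad)
            partner = _suppress_window(partner, lo - pad, hi + pad)
        return focal, partner, sync_records

    for lo, hi, ep in windows:
        pad = ramp_pad(ep) + 30.0
        focal_starts = [d["start"] for d in focal if lo - pad <= d["start"] <= hi + pad]
        # no accidental synchrony: partner keeps clear of every focal start
        partner = [d for d in partner
                   if not any(abs(d["start"] - s) <= 8.0 for s in focal_starts)]
        if ep.n_sync_dives <= 0:
            continue
        candidates = [d for d in focal if lo + 120.0 <= d["start"] <= hi - 120.0 - d["dur"]]
        if len(candidates) < ep.n_sync_dives:
            logger.warning("pair %s/%s: only %d candidate dives for %d planned syncs",
                           plan.id_a, plan.id_b, len(candidates), ep.n_sync_dives)
        chosen_idx = sorted(rng.choice(len(candidates),
                                       size=min(ep.n_sync_dives, len(candidates)),
                                       replace=False)) if candidates else []
        inserted: list[dict] = []
        prev_end = -np.inf
        for ci in chosen_idx:
            d = candidates[ci]
            if d["start"] < prev_end + 120.0:  # keep injected dives well separated
                continue
            prev_end = d["start"] + d["dur"]
            delta = float(cfg.tdr_step_s * rng.integers(0, 2))  # offset in {0, tdr_step}
            s_b = d["start"] + delta
            partner = [q for q in partner
                       if q["start"] >= s_b + d["dur"] + 12.0 or q["start"] + q["dur"] <= s_b - 12.0]
            inserted.append({"start": s_b, "dur": d["dur"],
                             "depth": d["depth"] * float(rng.uniform(0.8, 1.2))})
            sync_records.append((d["start"], s_b))
        partner.extend(inserted)
    partner.sort(key=lambda q: q["start"])
    return focal, partner, sync_records


def _depth_series(cfg: SimConfig, timing: _Timing, schedule: list[dict]) -> tuple[np.ndarray, np.ndarray]:
    """TDR depth samples (relative seconds, depth) including baseline drift."""
    step = cfg.tdr_step_s
    t = np.arange(-600.0, timing.T + 600.0 + step / 2, step)
    amp = cfg.zoc_drift_amplitude_m
    depth = amp + amp * np.sin(2 * np.pi * t / cfg.zoc_drift_period_s)
    for d in schedule:
        i0 = int(round((d["start"] - t[0]) / step))
        ns = int(round(d["dur"] / step))
        frac = (np.arange(ns) + 0.5) / ns
        profile = 1.2 + (d["depth"] - 1.2) * np.sin(np.pi * frac)
        depth[i0 : i0 + ns] += profile
    return t, depth


def _schedule_to_dives(individual_id: str, t0_abs: float, schedule: list[dict],
                       gap_s: float) -> list[Dive]:
    """Truth Dive objects (absolute seconds) with bout ids from the gap rule."""
    dives: list[Dive] = []
    ns = [int(round(d["dur"] / 4)) for d in schedule]
    for d, n in zip(schedule, ns):
        frac = (np.arange(n) + 0.5) / n
        peak = float(np.max(1.2 + (d["depth"] - 1.2) * np.sin(np.pi * frac)))
        dives.append(Dive(individual_id=individual_id, start_s=t0_abs + d["start"],
                          duration_s=d["dur"], max_depth_m=peak))
    for a, b in zip(dives[:-1], dives[1:]):
        a.postdive_s = b.start_s - a.end_s
    bout_id = 0
    for i, d in enumerate(dives):
        if i > 0 and dives[i].start_s - dives[i - 1].end_s >= gap_s:
            bout_id += 1
        d.bout_id = bout_id
    return dives


def _truth_bouts(individual_id: str, dives: list[Dive]) -> list[DiveBout]:
    bouts: dict[int, list[Dive]] = {}
    for d in dives:
        bouts.setdefault(d.bout_id, []).append(d)
    return [DiveBout(individual_id, bid, ds) for bid, ds in sorted(bouts.items())]


def _segments_below(t: np.ndarray, m: np.ndarray, level: float) -> list[tuple[float, float]]:
    """Intervals where the piecewise-linear function m(t) is <= level."""
    segs: list[tuple[float, float]] = []
    open_t = t[0] if m[0] <= level else None
    for i in range(1, len(t)):
        m0, m1, t0, t1 = m[i - 1], m[i], t[i - 1], t[i]
        if m0 == m1:
            continue
        tc = t0 + (level - m0) / (m1 - m0) * (t1 - t0)
        if m0 > level and m1 <= level and t0 <= tc <= t1:
            open_t = tc
        elif m0 <= level and m1 > level and t0 <= tc <= t1 and open_t is not None:
            segs.append((open_t, tc))
            open_t = None
    if open_t is not None:
        segs.append((open_t, float(t[-1])))
    return [(s, e) for s, e in segs if e > s]


def _subtract_mask(seg: tuple[float, float], times: np.ndarray, bad: np.ndarray,
                   min_len: float) -> list[tuple[float, float]]:
    """Remove masked grid instants from an interval; keep pieces >= min_len."""
    s, e = seg
    sel = (times >= s) & (times <= e)
    tt = times[sel]
    bb = bad[sel]
    if len(tt) == 0:
        return []
    out = []
    run_start = None
    prev = None
    for ti, bi in zip(tt, bb):
        if not bi and run_start is None:
            run_start = ti
        elif bi and run_start is not None:
            out.append((run_start, prev))
            run_start = None
        prev = ti
    if run_start is not None:
        out.append((run_start, tt[-1]))
    return [(a, b) for a, b in out if b - a >= min_len]


# ---------------------------------------------------------------------------
# main entry point

def simulate_deployment(config: SimConfig = SimConfig()) -> SimResult:
    """Generate one synthetic deployment with ground truth.

    Returns raw GPS/TDR/deployment tables in the schemas the readers in
    :mod:`coforage.io` expect, plus a :class:`GroundTruth` bundle.
    Raises ``ValueError`` before generating anything when the association
    plan is infeasible.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    colony = cfg.colony()
    t0_base = float(pd.Timestamp(cfg.date).value / 1e9) + cfg.depart_hour * 3600.0

    units: list[tuple[PairPlan | None, str | None]] = [(p, None) for p in cfg.pair_plans]
    units += [(None, s) for s in cfg.solo_ids]
    n_units = len(units)
    base_rot = rng.uniform(0, 2 * np.pi)

    # pre-validate every plan before generating anything
    planned: list[dict] = []
    for k, (plan, solo) in enumerate(units):
        T = _draw_duration(rng, cfg, is_pair=plan is not None)
        timing = _Timing.build(cfg, T)
        heading = base_rot + 2 * np.pi * k / n_units + rng.normal(0, 0.03)
        entry = {"plan": plan, "solo": solo, "T": T, "timing": timing,
                 "heading": heading, "t0": t0_base + k * 300.0}
        if plan is not None:
            windows = _episode_windows(cfg, plan, timing)
            entry["windows"] = windows
            entry["offset"] = _offset_waypoints(cfg, plan, timing, windows)
        planned.append(entry)

    gps_frames, tdr_frames = [], []
    clean_tracks: dict[str, pd.DataFrame] = {}
    truth_trip_rows, truth_episode_rows, truth_sync_rows, outlier_rows = [], [], [], []
    truth_dives: dict[str, list[Dive]] = {}
    truth_bouts: dict[str, list[DiveBout]] = {}
    truth_trips: dict[str, Trip] = {}
    sync_objects: dict[tuple[str, str], list[tuple[float, float]]] = {}
    episodes_by_ind: dict[str, list[AssociationEpisode]] = {}

    for entry in planned:
        plan, timing, heading, t0 = entry["plan"], entry["timing"], entry["heading"], entry["t0"]
        focal_id = plan.id_a if plan else entry["solo"]
        focal_sched = _dive_schedule(rng, cfg, timing)
        members: list[tuple[str, list[dict]]]
        if plan is not None:
            partner_sched = _partner_schedule(rng, cfg, timing, focal_sched)
            focal_sched, partner_sched, syncs = _apply_pair_dive_edits(
                rng, cfg, plan, entry["windows"], focal_sched, partner_sched)
            members = [(plan.id_a, focal_sched), (plan.id_b, partner_sched)]
            sync_objects[(plan.id_a, plan.id_b)] = [(t0 + a, t0 + b) for a, b in syncs]
        else:
            members = [(focal_id, focal_sched)]

        times_rel, fx, fy = _simulate_path(
            rng, cfg, timing, heading, _bout_intervals(focal_sched, cfg.interbout_shift_s))
        tracks_xy = {members[0][0]: (fx, fy)}
        if plan is not None:
            wt, wm = entry["offset"]
            m_t = np.interp(times_rel, wt, wm)
            u = np.array([np.cos(heading), np.sin(heading)])
            tracks_xy[plan.id_b] = (fx + u[0] * m_t, fy + u[1] * m_t)

        for ind, sched in members:
            xs, ys = tracks_xy[ind]
            lat, lon = _xy_to_latlon(cfg, xs, ys)
            abs_times = from_seconds(t0 + times_rel)
            clean = pd.DataFrame({"time": abs_times, "lat": lat, "lon": lon})
            clean_tracks[ind] = clean
            trips, _ = segment_trips(clean, colony, cfg.colony_radius_m, ind)
            if len(trips) != 1:  # pragma: no cover - construction guarantees one trip
                raise RuntimeError(f"simulation produced {len(trips)} trips for {ind}")
            truth_trips[ind] = trips[0]
            truth_trip_rows.append({"individual_id": ind,
                                    "departure": trips[0].departure_time,
                                    "return": trips[0].return_time})
            xn, yn, out_idx = _apply_noise_and_outliers(rng, cfg, xs, ys)
            lat_n, lon_n = _xy_to_latlon(cfg, xn, yn)
            gps_frames.append(pd.DataFrame({
                "id": ind, "timestamp": abs_times, "lat": lat_n, "lon": lon_n}))
            for i in out_idx:
                outlier_rows.append({"individual_id": ind, "time": pd.Timestamp(abs_times[i])})

            td, dd = _depth_series(cfg, timing, sched)
            tdr_frames.append(pd.DataFrame({
                "id": ind, "timestamp": from_seconds(t0 + td), "depth_m": dd}))
            dv = _schedule_to_dives(ind, t0, sched, cfg.interbout_shift_s)
            truth_dives[ind] = dv
            truth_bouts[ind] = _truth_bouts(ind, dv)

        if plan is not None:
            # analytic truth episodes from the separation schedule, rafting removed
            wt, wm = entry["offset"]
            fx_, fy_ = tracks_xy[plan.id_a]
            px_, py_ = tracks_xy[plan.id_b]
            d_a = np.hypot(fx_, fy_)
            d_b = np.hypot(px_, py_)
            both_rafting = (d_a <= cfg.rafting_radius_m) & (d_b <= cfg.rafting_radius_m)
            for seg in _segments_below(wt, wm, cfg.assoc_radius_m):
                for s, e in _subtract_mask(seg, times_rel, both_rafting, cfg.min_duration_s):
                    ep = AssociationEpisode(pair=(plan.id_a, plan.id_b),
                                            start_s=t0 + s, end_s=t0 + e)
                    episodes_by_ind.setdefault(plan.id_a, []).append(ep)
                    episodes_by_ind.setdefault(plan.id_b, []).append(ep)
                    truth_episode_rows.append(ep)

    # contexts + classification from truth parts
    annotate_contexts(truth_episode_rows,
                      {k: v for k, v in truth_bouts.items()},
                      truth_trips)
    sync_pairs_by_ind: dict[str, list[SyncDivePair]] = {}
    sync_rows = []
    for (ida, idb), recs in sync_objects.items():
        by_start_a = {d.start_s: d for d in truth_dives[ida]}
        by_start_b = {d.start_s: d for d in truth_dives[idb]}
        for ta, tb in recs:
            da, db = by_start_a.get(ta), by_start_b.get(tb)
            if da is None or db is None:  # pragma: no cover
                raise RuntimeError("sync record lost during schedule edits")
            sp = SyncDivePair(pair=(ida, idb), dive_a=da, dive_b=db)
            sync_pairs_by_ind.setdefault(ida, []).append(sp)
            sync_pairs_by_ind.setdefault(idb, []).append(sp)
            sync_rows.append({"id_a": ida, "id_b": idb,
                              "t_a": pd.Timestamp(from_seconds([ta])[0]),
                              "t_b": pd.Timestamp(from_seconds([tb])[0]),
                              "delta_s": abs(tb - ta)})

    classifications = []
    for ind, trip in truth_trips.items():
        classifications.append(classify_track(
            trip,
            episodes_by_ind.get(ind, []),
            truth_dives.get(ind, []),
            sync_pairs_by_ind.get(ind, []),
            truth_bouts.get(ind, []),
        ))

    # deployments: nests scattered around the colony, sexes alternating
    dep_rows = []
    for i, ind in enumerate([m for e in planned for m in
                             ([e["plan"].id_a, e["plan"].id_b] if e["plan"] else [e["solo"]])]):
        nx, ny = rng.normal(0, 30.0, size=2)
        nlat, nlon = _xy_to_latlon(cfg, np.array([nx]), np.array([ny]))
        dep_rows.append({"id": ind, "sex": "female" if i % 2 == 0 else "male",
                         "nest_id": f"N{i + 1:02d}",
                         "nest_lat": float(nlat[0]), "nest_lon": float(nlon[0]),
                         "date": cfg.date})

    all_dives = [d for dv in truth_dives.values() for d in dv]
    all_bouts = [b for bs in truth_bouts.values() for b in bs]
    ep_frame = pd.DataFrame(
        [{"id_a": ep.pair[0], "id_b": ep.pair[1], "start": ep.start, "end": ep.end,
          "duration_s": ep.duration_s, "context": ep.context}
         for ep in truth_episode_rows],
        columns=["id_a", "id_b", "start", "end", "duration_s", "context"])
    truth = GroundTruth(
        trips=pd.DataFrame(truth_trip_rows, columns=["individual_id", "departure", "return"]),
        dives=dives_to_frame(all_dives),
        bouts=bouts_to_frame(all_bouts),
        episodes=ep_frame,
        sync_dives=pd.DataFrame(sync_rows, columns=["id_a", "id_b", "t_a", "t_b", "delta_s"]),
        classification=classifications_to_frame(classifications),
        outlier_fixes=pd.DataFrame(outlier_rows, columns=["individual_id", "time"]),
        clean_tracks=clean_tracks,
    )
    return SimResult(
        gps=pd.concat(gps_frames, ignore_index=True),
        tdr=pd.concat(tdr_frames, ignore_index=True),
        deployments=pd.DataFrame(dep_rows),
        truth=truth,
        config=cfg,
    )
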