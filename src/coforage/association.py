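"""Dyadic at-sea association detection, rafting exclusion, dive synchrony
and per-track association classification.

Boundary conventions follow the thresholds' wording: a dyad at exactly the
association radius counts as inside ("within a fixed radius"), dive starts
exactly the synchrony window apart count as synchronous, and only speeds
strictly above the limit are filtered upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from coforage._timeutil import from_seconds
from coforage.dives import Dive, DiveBout
from coforage.io import ColonySite
from coforage.trips import InterpolatedTrack, Trip, haversine_m

logger = logging.getLogger(__name__)

GROUPS = ("1", "2", "3a", "3b", "3c")


@dataclass(frozen=True)
class AssociationParameters:
    """Thresholds of the association analysis.

    ``min_duration_s`` defaults to 744 s (12.4 min, one mean dive-bout
    duration) and ``radius_m`` to 500 m (about half the mean horizontal
    distance covered per dive bout); both can be re-derived from the
    current dataset with :func:`derive_parameters`.
    """

    radius_m: float = 500.0
    min_duration_s: float = 744.0
    sync_window_s: float = 4.0
    rafting_radius_m: float = 1000.0
    merge_gap_s: float = 120.0

    def __post_init__(self) -> None:
        for name in ("radius_m", "min_duration_s", "sync_window_s",
                     "rafting_radius_m", "merge_gap_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def derive_parameters(
    bouts: list[DiveBout], base: AssociationParameters = AssociationParameters()
) -> AssociationParameters:
    """Re-derive radius and minimum duration from the current dataset.

    The minimum association duration becomes the mean bout duration and the
    radius half the mean per-bout horizontal distance.
    """
    durations = [b.duration_min * 60.0 for b in bouts]
    dists = [b.horizontal_km for b in bouts if np.isfinite(b.horizontal_km)]
    if not durations or not dists:
        raise ValueError("cannot derive parameters without bouts")
    return AssociationParameters(
        radius_m=float(np.mean(dists)) * 1000.0 / 2.0,
        min_duration_s=float(np.mean(durations)),
        sync_window_s=base.sync_window_s,
        rafting_radius_m=base.rafting_radius_m,
        merge_gap_s=base.merge_gap_s,
    )


@dataclass
class AssociationEpisode:
    """A maximal interval during which a dyad stays within the radius."""

    pair: tuple[str, str]
    start_s: float
    end_s: float
    mean_distance_m: float = np.nan
    min_distance_m: float = np.nan
    context: str = "at_sea"
    n_dives_a: int = 0
    n_dives_b: int = 0
    n_sync_dives: int = 0

    def __post_init__(self) -> None:
        self.pair = tuple(sorted(map(str, self.pair)))  # unordered dyad

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(from_seconds([self.start_s])[0])

    @property
    def end(self) -> pd.Timestamp:
        return pd.Timestamp(from_seconds([self.end_s])[0])


@dataclass
class SyncDivePair:
    """Two dives initiated within the synchrony window during a shared episode."""

    pair: tuple[str, str]
    dive_a: Dive
    dive_b: Dive
    surface_distance_m: float = np.nan

    def __post_init__(self) -> None:
        self.pair = tuple(sorted(map(str, self.pair)))

    @property
    def time_a_s(self) -> float:
        return self.dive_a.start_s

    @property
    def time_b_s(self) -> float:
        return self.dive_b.start_s

    @property
    def delta_s(self) -> float:
        return abs(self.dive_a.start_s - self.dive_b.start_s)


@dataclass
class TrackClassification:
    """Association category of one foraging track with its time budgets."""

    individual_id: str
    group: str
    pct_travelling_assoc: float = 0.0
    pct_async_diving_assoc: float = 0.0
    pct_sync_diving: float = 0.0
    pct_total_assoc: float = 0.0
    # non-exclusive membership flags (an individual can express several degrees)
    any_commute_assoc: bool = False
    any_at_sea_assoc: bool = False
    any_diving_assoc: bool = False
    any_sync_diving: bool = False
    dive_record_available: bool = True


def dyadic_distance_series(
    track_a: InterpolatedTrack, track_b: InterpolatedTrack
) -> tuple[np.ndarray, np.ndarray]:
    """Dyadic distance at every common grid instant of the temporal overlap.

    Both tracks must use the same grid step; they are evaluated on a common
    epoch-anchored grid so that dyads with different departure instants
    still share sampling times.  Returns ``(times_s, distance_m)``; both
    empty when the trips do not overlap in time.
    """
    if track_a.grid_step_s != track_b.grid_step_s:
        raise ValueError("tracks must share the same grid step")
    step = track_a.grid_step_s
    t0 = max(track_a.start_s, track_b.start_s)
    t1 = min(track_a.end_s, track_b.end_s)
    if t1 < t0:
        return np.empty(0), np.empty(0)
    first = np.ceil(t0 / step - 1e-6) * step
    n_steps = int(np.floor((t1 - first) / step + 1e-6))
    if first > t1 or n_steps < 0:
        return np.empty(0), np.empty(0)
    times = first + step * np.arange(n_steps + 1)
    lat_a, lon_a = track_a.positions_at(times)
    lat_b, lon_b = track_b.positions_at(times)
    return times, np.asarray(haversine_m(lat_a, lon_a, lat_b, lon_b))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Index runs [i, j] (inclusive) of consecutive True values."""
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(s), int(e) - 1) for s, e in zip(edges[::2], edges[1::2])]


def detect_episodes(
    times_s: np.ndarray,
    distance_m: np.ndarray,
    pair: tuple[str, str],
    params: AssociationParameters = AssociationParameters(),
) -> list[AssociationEpisode]:
    """Extract association episodes from a dyadic distance series.

    Maximal runs with distance <= radius (boundary inclusive) are found,
    runs separated by gaps <= ``merge_gap_s`` are merged, and runs shorter
    than ``min_duration_s`` are discarded.  Distance statistics are
    computed over all grid points of the episode interval, merged gaps
    included.
    """
    times_s = np.asarray(times_s, dtype=float)
    distance_m = np.asarray(distance_m, dtype=float)
    inside = np.isfinite(distance_m) & (distance_m <= params.radius_m)
    runs = _runs(inside)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and times_s[s] - times_s[merged[-1][1]] <= params.merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    episodes = []
    for s, e in merged:
        if times_s[e] - times_s[s] < params.min_duration_s:
            continue
        seg = distance_m[s : e + 1]
        episodes.append(
            AssociationEpisode(
                pair=pair,
                start_s=float(times_s[s]),
                end_s=float(times_s[e]),
                mean_distance_m=float(np.nanmean(seg)),
                min_distance_m=float(np.nanmin(seg)),
            )
        )
    return episodes


def exclude_rafting(
    episodes: list[AssociationEpisode],
    colony: ColonySite,
    params: AssociationParameters,
    tracks: dict[str, InterpolatedTrack],
    grid_step_s: float | None = None,
) -> list[AssociationEpisode]:
    """Trim episode portions during which both individuals raft near the colony.

    Grid instants at which both dyad members are within
    ``rafting_radius_m`` of the colony are removed; the surviving portions
    are re-checked against the minimum duration (episodes may split).
    Trimmed intervals are logged for audit.
    """
    out: list[AssociationEpisode] = []
    for ep in episodes:
        a, b = ep.pair
        step = grid_step_s or tracks[a].grid_step_s
        times = ep.start_s + step * np.arange(int(np.floor((ep.end_s - ep.start_s) / step + 1e-6)) + 1)
        lat_a, lon_a = tracks[a].positions_at(times)
        lat_b, lon_b = tracks[b].positions_at(times)
        da = np.asarray(haversine_m(lat_a, lon_a, colony.lat, colony.lon))
        db = np.asarray(haversine_m(lat_b, lon_b, colony.lat, colony.lon))
        rafting = (da <= params.rafting_radius_m) & (db <= params.rafting_radius_m)
        if not rafting.any():
            out.append(ep)
            continue
        if rafting.all():
            logger.info("rafting: removed episode %s [%s..%s]", ep.pair, ep.start, ep.end)
            continue
        for s, e in _runs(~rafting):
            if times[e] - times[s] < params.min_duration_s:
                continue
            out.append(
                AssociationEpisode(
                    pair=ep.pair,
                    start_s=float(times[s]),
                    end_s=float(times[e]),
                    mean_distance_m=ep.mean_distance_m,
                    min_distance_m=ep.min_distance_m,
                    context=ep.context,
                )
            )
        logger.info("rafting: trimmed %d grid instants from episode %s", int(rafting.sum()), ep.pair)
    return out


def _dives_in_interval(dives: list[Dive], start_s: float, end_s: float) -> list[Dive]:
    return [d for d in dives if start_s <= d.start_s <= end_s]


def detect_sync_dives(
    episodes: list[AssociationEpisode],
    dives_a: list[Dive],
    dives_b: list[Dive],
    params: AssociationParameters = AssociationParameters(),
    track_a: InterpolatedTrack | None = None,
    track_b: InterpolatedTrack | None = None,
) -> list[SyncDivePair]:
    """Greedy one-to-one matching of dive initiations within the sync window.

    Dives of the first individual are processed in time order; each is
    matched to the unused dive of the second individual minimising the
    start-time difference (ties resolved toward the earlier dive), subject
    to both starts falling inside a shared episode and
    ``|delta| <= sync_window_s`` (boundary inclusive).
    """
    pairs: list[SyncDivePair] = []
    for ep in episodes:
        a_dives = _dives_in_interval(dives_a, ep.start_s, ep.end_s)
        b_dives = sorted(_dives_in_interval(dives_b, ep.start_s, ep.end_s),
                         key=lambda d: d.start_s)
        used = [False] * len(b_dives)
        ep_pairs = []
        for da in sorted(a_dives, key=lambda d: d.start_s):
            best_j, best_delta = -1, np.inf
            for j, db in enumerate(b_dives):
                if used[j]:
                    continue
                delta = abs(db.start_s - da.start_s)
                if delta <= params.sync_window_s and delta < best_delta:
                    best_j, best_delta = j, delta  # strict <: ties keep the earlier b dive
            if best_j >= 0:
                used[best_j] = True
                ep_pairs.append(SyncDivePair(pair=ep.pair, dive_a=da, dive_b=b_dives[best_j]))
        ep.n_dives_a = len(a_dives)
        ep.n_dives_b = len(b_dives)
        ep.n_sync_dives = len(ep_pairs)
        pairs.extend(ep_pairs)
    if track_a is not None and track_b is not None:
        for sp in pairs:
            la, lo = track_a.positions_at([sp.dive_a.start_s])
            lb, lob = track_b.positions_at([sp.dive_b.start_s])
            sp.surface_distance_m = float(haversine_m(la[0], lo[0], lb[0], lob[0]))
    return pairs


def _interval_union(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def classify_track(
    trip: Trip,
    episodes: list[AssociationEpisode],
    dives: list[Dive] | None,
    sync_pairs: list[SyncDivePair],
    bouts: list[DiveBout] | None,
) -> TrackClassification:
    """Assign the focal track its association category and time budgets.

    Categories: ``1`` no association; ``2`` association wholly inside the
    outward/inward commuting windows with no focal dives during episodes;
    ``3a`` at-sea association without focal dives during episodes; ``3b``
    focal dives during episodes but no synchrony; ``3c`` at least one
    synchronous dive.  The group label is the highest degree attained;
    non-exclusive membership flags are also set.

    Commuting windows span departure to the first bout start and the last
    bout end to return; trips without bouts treat the whole trip as
    commuting.  Without a dive record the label is restricted to
    ``{1, 2, 3a}`` and flagged.
    """
    ind = trip.individual_id
    t_dep = trip.departure_time.value / 1e9
    t_ret = trip.return_time.value / 1e9
    trip_dur = t_ret - t_dep
    has_tdr = dives is not None
    dives = dives or []
    cls = TrackClassification(individual_id=ind, group="1", dive_record_available=has_tdr)
    if not episodes:
        return cls

    if bouts:
        commute_out_end = min(b.start_s for b in bouts)
        commute_in_start = max(b.end_s for b in bouts)
    else:
        commute_out_end = t_ret
        commute_in_start = t_dep

    def in_commute(ep: AssociationEpisode) -> bool:
        return ep.end_s <= commute_out_end or ep.start_s >= commute_in_start

    sync_dives = {id(sp.dive_a) for sp in sync_pairs} | {id(sp.dive_b) for sp in sync_pairs}
    ep_dives: list[Dive] = []
    seen: set[int] = set()
    for ep in episodes:
        for d in _dives_in_interval(dives, ep.start_s, ep.end_s):
            if id(d) not in seen:
                seen.add(id(d))
                ep_dives.append(d)
    focal_sync = [d for d in ep_dives if id(d) in sync_dives]
    focal_async = [d for d in ep_dives if id(d) not in sync_dives]

    cls.any_commute_assoc = any(in_commute(ep) for ep in episodes)
    cls.any_at_sea_assoc = any(not in_commute(ep) for ep in episodes)
    cls.any_diving_assoc = len(ep_dives) > 0
    cls.any_sync_diving = len(focal_sync) > 0

    if cls.any_sync_diving:
        cls.group = "3c"
    elif cls.any_diving_assoc:
        cls.group = "3b"
    elif cls.any_at_sea_assoc:
        cls.group = "3a"
    else:
        cls.group = "2"

    union = _interval_union(
        [(max(ep.start_s, t_dep), min(ep.end_s, t_ret)) for ep in episodes]
    )
    total_assoc = sum(e - s for s, e in union)
    sync_time = sum(d.duration_s for d in focal_sync)
    async_time = sum(d.duration_s for d in focal_async)
    cls.pct_total_assoc = 100.0 * total_assoc / trip_dur
    cls.pct_sync_diving = 100.0 * sync_time / trip_dur
    cls.pct_async_diving_assoc = 100.0 * async_time / trip_dur
    cls.pct_travelling_assoc = max(
        0.0, cls.pct_total_assoc - cls.pct_sync_diving - cls.pct_async_diving_assoc
    )
    return cls


def annotate_contexts(
    episodes: list[AssociationEpisode],
    bouts_by_id: dict[str, list[DiveBout]],
    trips_by_id: dict[str, Trip],
) -> list[AssociationEpisode]:
    """Label each episode commute_out / at_sea / commute_in / mixed.

    The commuting windows of the two dyad members are intersected: an
    episode is ``commute_out`` when it ends before both members' first
    bouts, ``commute_in`` when it starts after both members' last bouts,
    ``at_sea`` when it lies between, and ``mixed`` otherwise.
    """
    for ep in episodes:
        outs, ins = [], []
        for ind in ep.pair:
            bouts = bouts_by_id.get(ind, [])
            trip = trips_by_id.get(ind)
            if bouts:
                outs.append(min(b.start_s for b in bouts))
                ins.append(max(b.end_s for b in bouts))
            elif trip is not None:
                outs.append(trip.return_time.value / 1e9)
                ins.append(trip.departure_time.value / 1e9)
        if not outs:
            ep.context = "at_sea"
            continue
        out_end, in_start = min(outs), max(ins)
        if ep.end_s <= out_end:
            ep.context = "commute_out"
        elif ep.start_s >= in_start:
            ep.context = "commute_in"
        elif ep.start_s >= out_end and ep.end_s <= in_start:
            ep.context = "at_sea"
        else:
            ep.context = "mixed"
    return episodes


def pair_summary(
    episodes: list[AssociationEpisode], sync_pairs: list[SyncDivePair]
) -> pd.DataFrame:
    """Per-dyad summary of association time and synchronous-dive statistics.

    Durations, depths and post-dive intervals pool both members' dives of
    each synchronous pair; medians are reported with the observed range.
    """
    pairs = sorted({ep.pair for ep in episodes} | {sp.pair for sp in sync_pairs})
    rows = []
    for pair in pairs:
        eps = [ep for ep in episodes if ep.pair == pair]
        sps = [sp for sp in sync_pairs if sp.pair == pair]
        dives = [sp.dive_a for sp in sps] + [sp.dive_b for sp in sps]
        durations = [d.duration_s for d in dives]
        depths = [d.max_depth_m for d in dives]
        postdives = [d.postdive_s for d in dives if np.isfinite(d.postdive_s)]
        surf = [sp.surface_distance_m for sp in sps if np.isfinite(sp.surface_distance_m)]

        def mrr(vals):
            if not vals:
                return (np.nan, np.nan, np.nan)
            return (float(np.median(vals)), float(np.min(vals)), float(np.max(vals)))

        dur_med, dur_lo, dur_hi = mrr(durations)
        dep_med, dep_lo, dep_hi = mrr(depths)
        pdi_med, pdi_lo, pdi_hi = mrr(postdives)
        sd_med, sd_lo, sd_hi = mrr(surf)
        rows.append(
            {
                "id_a": pair[0],
                "id_b": pair[1],
                "assoc_duration_min": sum(ep.duration_s for ep in eps) / 60.0,
                "n_sync_dives": len(sps),
                "dive_duration_median_s": dur_med,
                "dive_duration_min_s": dur_lo,
                "dive_duration_max_s": dur_hi,
                "depth_median_m": dep_med,
                "depth_min_m": dep_lo,
                "depth_max_m": dep_hi,
                "postdive_median_s": pdi_med,
                "postdive_min_s": pdi_lo,
                "postdive_max_s": pdi_hi,
                "surface_distance_median_m": sd_med,
                "surface_distance_min_m": sd_lo,
                "surface_distance_max_m": sd_hi,
            }
        )
    cols = ["id_a", "id_b", "assoc_duration_min", "n_sync_dives",
            "dive_duration_median_s", "dive_duration_min_s", "dive_duration_max_s",
            "depth_median_m", "depth_min_m", "depth_max_m",
            "postdive_median_s", "postdive_min_s", "postdive_max_s",
            "surface_distance_median_m", "surface_distance_min_m", "surface_distance_max_m"]
    return pd.DataFrame(rows, columns=cols)


def deployment_day_summary(
    classifications: list[TrackClassification] | pd.DataFrame,
    deployments: pd.DataFrame,
) -> pd.DataFrame:
    """Per deployment date: instrumented count, associating count, percentage.

    An individual counts as associating when its track was classified into
    any category other than ``1`` (i.e. it associated for at least one
    minimum-duration unit).
    """
    if isinstance(classifications, pd.DataFrame):
        cls = classifications[["individual_id", "group"]].copy()
    else:
        cls = pd.DataFrame(
            {"individual_id": [c.individual_id for c in classifications],
             "group": [c.group for c in classifications]}
        )
    merged = deployments.merge(cls, on="individual_id", how="left")
    rows = []
    for date, sub in merged.groupby("date", sort=True):
        n = len(sub)
        n_assoc = int((sub["group"].fillna("1") != "1").sum())
        rows.append(
            {
                "date": date,
                "n_instrumented": n,
                "n_associating": n_assoc,
                "pct_associating": 100.0 * n_assoc / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["date", "n_instrumented", "n_associating", "pct_associating"])


def classifications_to_frame(classifications: list[TrackClassification]) -> pd.DataFrame:
    rows = [
        {
            "individual_id": c.individual_id,
            "group": c.group,
            "pct_travelling_assoc": c.pct_travelling_assoc,
            "pct_async_diving_assoc": c.pct_async_diving_assoc,
            "pct_sync_diving": c.pct_sync_diving,
            "pct_total_assoc": c.pct_total_assoc,
            "any_commute_assoc": c.any_commute_assoc,
            "any_at_sea_assoc": c.any_at_sea_assoc,
            "any_diving_assoc": c.any_diving_assoc,
            "any_sync_diving": c.any_sync_diving,
            "dive_record_available": c.dive_record_available,
        }
        for c in classifications
    ]
    cols = ["individual_id", "group", "pct_travelling_assoc", "pct_async_diving_assoc",
            "pct_sync_diving", "pct_total_assoc", "any_commute_assoc", "any_at_sea_assoc",
            "any_diving_assoc", "any_sync_diving", "dive_record_available"]
    return pd.DataFrame(rows, columns=cols)


def episodes_to_frame(episodes: list[AssociationEpisode]) -> pd.DataFrame:
    rows = [
        {
            "id_a": ep.pair[0],
            "id_b": ep.pair[1],
            "start": ep.start,
            "end": ep.end,
            "duration_s": ep.duration_s,
            "mean_dist_m": ep.mean_distance_m,
            "min_dist_m": ep.min_distance_m,
            "context": ep.context,
            "n_sync_dives": ep.n_sync_dives,
        }
        for ep in episodes
    ]
    cols = ["id_a", "id_b", "start", "end", "duration_s", "mean_dist_m",
            "min_dist_m", "context", "n_sync_dives"]
    return pd.DataFrame(rows, columns=cols)


def sync_to_frame(sync_pairs: list[SyncDivePair]) -> pd.DataFrame:
    rows = [
        {
            "id_a": sp.pair[0],
            "id_b": sp.pair[1],
            "t_a": sp.dive_a.start,
            "t_b": sp.dive_b.start,
            "delta_s": sp.delta_s,
            "surface_dist_m": sp.surface_distance_m,
            "depth_a_m": sp.dive_a.max_depth_m,
            "depth_b_m": sp.dive_b.max_depth_m,
            "duration_a_s": sp.dive_a.duration_s,
            "duration_b_s": sp.dive_b.duration_s,
        }
        for sp in sync_pairs
    ]
    cols = ["id_a", "id_b", "t_a", "t_b", "delta_s", "surface_dist_m",
            "depth_a_m", "depth_b_m", "duration_a_s", "duration_b_s"]
    return pd.DataFrame(rows, columns=cols)
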