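"""End-to-end orchestration: ingest -> filter -> trips -> interpolate ->
dives -> bouts -> episodes -> rafting exclusion -> sync -> classify ->
summaries -> stats, with persisted intermediates and a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import coforage
from coforage._timeutil import to_seconds
from coforage.association import (
    AssociationEpisode,
    AssociationParameters,
    TrackClassification,
    annotate_contexts,
    classifications_to_frame,
    classify_track,
    deployment_day_summary,
    detect_episodes,
    detect_sync_dives,
    dyadic_distance_series,
    episodes_to_frame,
    exclude_rafting,
    pair_summary,
    sync_to_frame,
)
from coforage.dives import (
    BoutFitError,
    Dive,
    DiveBout,
    assign_bouts,
    bout_horizontal_distance,
    bouts_to_frame,
    criterion_values,
    detect_dives,
    dives_to_frame,
    fit_bout_model,
    locate_dives,
    zero_offset_correct,
)
from coforage.io import (
    ColonySite,
    read_colony,
    read_deployments_csv,
    read_gps_csv,
    read_tdr_csv,
    write_results,
    write_track_geojson,
)
from coforage.stats import (
    association_time_matrix,
    mann_whitney,
    mantel_test,
    nest_distance_matrix,
)
from coforage.trips import (
    InterpolatedTrack,
    Trip,
    interpolate_track,
    segment_trips,
    speed_filter,
    trip_summary,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, individual: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed for individual '{individual}': {cause}")
        self.stage = stage
        self.individual = individual
        self.cause = cause


@dataclass
class PipelineConfig:
    """Single configuration object for the whole pipeline (YAML-friendly)."""

    gps_path: str = ""
    tdr_path: str | None = None
    deployments_path: str = ""
    colony_path: str = ""
    out_dir: str = "results"
    # trip processing
    vmax_ms: float = 2.0
    colony_radius_m: float = 150.0
    grid_step_s: float = 60.0
    # dive analysis
    dive_threshold_m: float = 1.0
    zoc_window_s: float = 300.0
    zoc_quantile: float = 0.02
    bout_variable: str = "postdive"
    pooled_bec: bool = False
    min_fit_n: int = 10
    # association
    radius_m: float = 500.0
    min_duration_s: float = 744.0
    sync_window_s: float = 4.0
    rafting_radius_m: float = 1000.0
    merge_gap_s: float = 120.0
    # stats
    n_perm: int = 9999
    seed: int = 0
    geojson: bool = False

    def association_params(self) -> AssociationParameters:
        return AssociationParameters(
            radius_m=self.radius_m,
            min_duration_s=self.min_duration_s,
            sync_window_s=self.sync_window_s,
            rafting_radius_m=self.rafting_radius_m,
            merge_gap_s=self.merge_gap_s,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TrackRecord:
    """Everything derived for one complete foraging trip."""

    individual_id: str
    trip: Trip
    track: InterpolatedTrack
    dives: list[Dive] | None = None
    bouts: list[DiveBout] | None = None
    bec_s: float = np.nan


@dataclass
class ResultBundle:
    records: dict[str, TrackRecord]
    episodes: list[AssociationEpisode]
    sync_pairs: list
    classifications: list[TrackClassification]
    tables: dict[str, pd.DataFrame]
    stats: dict
    removed_fixes: dict[str, pd.DataFrame] = field(default_factory=dict)


def _fit_trip_bec(dives: list[Dive], variable: str, seed: int,
                  min_n: int, pooled_values: np.ndarray | None) -> float:
    vals = criterion_values(dives, variable)
    if len(vals) >= min_n:
        try:
            return fit_bout_model(vals, seed=seed).bec_s
        except (BoutFitError, ValueError) as exc:
            logger.warning("per-trip BEC fit failed (%s); falling back to pooled fit", exc)
    if pooled_values is not None and len(pooled_values) >= min_n:
        try:
            return fit_bout_model(pooled_values, seed=seed).bec_s
        except (BoutFitError, ValueError):
            pass
    return np.nan


def analyze(
    gps: dict[str, pd.DataFrame],
    tdr: dict[str, pd.DataFrame] | None,
    deployments: pd.DataFrame,
    colony: ColonySite,
    cfg: PipelineConfig,
) -> ResultBundle:
    """Run the full analysis on in-memory tables.

    `tdr` may be ``None`` (GPS-only degraded mode): dive-dependent stages
    are skipped and classifications are restricted to groups 1/2/3a.
    """
    params = cfg.association_params()
    records: dict[str, TrackRecord] = {}
    removed_fixes: dict[str, pd.DataFrame] = {}
    trip_rows = []

    for ind, fixes in gps.items():
        try:
            retained, removed = speed_filter(fixes, cfg.vmax_ms)
            removed_fixes[ind] = removed
            trips, n_incomplete = segment_trips(retained, colony, cfg.colony_radius_m, ind)
        except Exception as exc:
            raise PipelineError("trip_processing", ind, exc) from exc
        for k, trip in enumerate(trips):
            key = ind if len(trips) == 1 else f"{ind}#{k}"
            track = interpolate_track(trip, cfg.grid_step_s)
            records[key] = TrackRecord(individual_id=ind, trip=trip, track=track)
            row = trip_summary(trip, colony)
            row["track_id"] = key
            row["n_fixes_removed"] = len(removed)
            trip_rows.append(row)

    has_tdr = bool(tdr)
    if has_tdr:
        # pooled criterion values support trips whose own fit fails
        per_ind_dives: dict[str, list[Dive]] = {}
        for ind, samples in (tdr or {}).items():
            try:
                corrected = zero_offset_correct(samples, cfg.zoc_window_s, cfg.zoc_quantile)
                per_ind_dives[ind] = detect_dives(corrected, cfg.dive_threshold_m, ind)
            except Exception as exc:
                raise PipelineError("dive_detection", ind, exc) from exc
        pooled = [v for ind, dv in per_ind_dives.items()
                  for v in criterion_values(dv, cfg.bout_variable)]
        pooled_vals = np.asarray(pooled, dtype=float)
        for key, rec in records.items():
            dv = per_ind_dives.get(rec.individual_id, [])
            t0 = rec.trip.departure_time.value / 1e9
            t1 = rec.trip.return_time.value / 1e9
            trip_dives = [d for d in dv if t0 <= d.start_s <= t1]
            if trip_dives and np.isfinite(trip_dives[-1].postdive_s):
                # terminal dive of a trip has no defined post-dive interval
                last = trip_dives[-1]
                nxt = [d for d in dv if d.start_s > last.start_s]
                if not nxt or nxt[0].start_s > t1:
                    last.postdive_s = np.nan
            try:
                fit_dives = [] if cfg.pooled_bec else trip_dives
                bec = _fit_trip_bec(fit_dives, cfg.bout_variable, cfg.seed,
                                    cfg.min_fit_n, pooled_vals)
                rec.bec_s = bec
                if np.isfinite(bec):
                    bouts = assign_bouts(trip_dives, bec, cfg.bout_variable)
                else:
                    bouts = assign_bouts(trip_dives, np.inf, cfg.bout_variable) if trip_dives else []
                locate_dives(trip_dives, rec.track)
                for b in bouts:
                    b.horizontal_km = bout_horizontal_distance(b, rec.track)
                rec.dives = trip_dives
                rec.bouts = bouts
            except Exception as exc:
                raise PipelineError("bout_analysis", rec.individual_id, exc) from exc
    else:
        logger.warning("no TDR data: running in GPS-only mode")

    # dyadic association detection
    episodes: list[AssociationEpisode] = []
    sync_pairs: list = []
    tracks = {k: r.track for k, r in records.items()}
    for ka, kb in combinations(sorted(records), 2):
        ra, rb = records[ka], records[kb]
        if ra.individual_id == rb.individual_id:
            continue
        times, dist = dyadic_distance_series(ra.track, rb.track)
        if len(times) == 0:
            continue
        eps = detect_episodes(times, dist, (ka, kb), params)
        eps = exclude_rafting(eps, colony, params, tracks, cfg.grid_step_s)
        if has_tdr and eps:
            pair_sync = detect_sync_dives(eps, ra.dives or [], rb.dives or [], params,
                                          ra.track, rb.track)
            sync_pairs.extend(pair_sync)
        episodes.extend(eps)

    annotate_contexts(
        episodes,
        {k: (r.bouts or []) for k, r in records.items()},
        {k: r.trip for k, r in records.items()},
    )

    classifications = []
    for key, rec in records.items():
        eps = [ep for ep in episodes if key in ep.pair]
        sps = [sp for sp in sync_pairs if key in sp.pair]
        classifications.append(
            classify_track(rec.trip, eps, rec.dives if has_tdr else None, sps, rec.bouts)
        )

    all_dives = [d for r in records.values() for d in (r.dives or [])]
    all_bouts = [b for r in records.values() for b in (r.bouts or [])]
    tables = {
        "trips": pd.DataFrame(trip_rows),
        "dives": dives_to_frame(all_dives),
        "bouts": bouts_to_frame(all_bouts),
        "episodes": episodes_to_frame(episodes),
        "sync_dives": sync_to_frame(sync_pairs),
        "classification": classifications_to_frame(classifications),
        "pair_summary": pair_summary(episodes, sync_pairs),
        "day_summary": deployment_day_summary(classifications, deployments),
    }

    stats: dict = {"seed": cfg.seed}
    cls_df = tables["classification"].merge(deployments, on="individual_id", how="left")
    f = cls_df[cls_df["sex"] == "female"]["pct_total_assoc"].to_numpy()
    m = cls_df[cls_df["sex"] == "male"]["pct_total_assoc"].to_numpy()
    if len(f) and len(m):
        try:
            rt = mann_whitney(f, m)
            stats["sex_test"] = {"U": rt.U, "p": rt.p, "n1": rt.n1, "n2": rt.n2,
                                 "method": rt.method}
        except ValueError as exc:
            stats["sex_test"] = {"error": str(exc)}
    if len(deployments) >= 4:
        try:
            nest = nest_distance_matrix(deployments)
            assoc = association_time_matrix(tables["pair_summary"], deployments)
            mr = mantel_test(nest.to_numpy(), assoc.to_numpy(),
                             n_perm=cfg.n_perm, seed=cfg.seed)
            stats["mantel"] = {"r": mr.r, "p": mr.p, "n_perm": mr.n_perm, "seed": cfg.seed}
        except ValueError as exc:
            stats["mantel"] = {"error": str(exc)}
    return ResultBundle(records=records, episodes=episodes, sync_pairs=sync_pairs,
                        classifications=classifications, tables=tables, stats=stats,
                        removed_fixes=removed_fixes)


def _manifest(cfg: PipelineConfig, bundle: ResultBundle, written: dict[str, Path]) -> dict:
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    hashes = {}
    for name, path in sorted(written.items()):
        hashes[name] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "package_version": coforage.__version__,
        "row_counts": {name: int(len(t)) for name, t in bundle.tables.items()},
        "output_sha256": hashes,
    }


# ---------------------------------------------------------------------------
# converters so each stage can be re-run from persisted intermediates

def tracks_from_interpolated(df: pd.DataFrame) -> dict[str, InterpolatedTrack]:
    out = {}
    key = "track_id" if "track_id" in df.columns else "individual_id"
    for tid, sub in df.groupby(key, sort=True):
        sub = sub.sort_values("time")
        t = to_seconds(pd.to_datetime(sub["time"]))
        step = float(np.median(np.diff(t))) if len(t) > 1 else 60.0
        out[str(tid)] = InterpolatedTrack(
            individual_id=str(sub["individual_id"].iloc[0]) if "individual_id" in sub else str(tid),
            grid_step_s=step, times_s=t,
            lat=sub["lat"].to_numpy(dtype=float), lon=sub["lon"].to_numpy(dtype=float))
    return out


def trips_from_frame(df: pd.DataFrame) -> dict[str, Trip]:
    out = {}
    for _, row in df.iterrows():
        dep = pd.Timestamp(row["departure"])
        ret = pd.Timestamp(row["return"])
        key = str(row["track_id"]) if "track_id" in df.columns else str(row["individual_id"])
        fixes = pd.DataFrame({"time": [dep, ret], "lat": [np.nan, np.nan],
                              "lon": [np.nan, np.nan]})
        out[key] = Trip(individual_id=str(row["individual_id"]),
                        departure_time=dep, return_time=ret, fixes=fixes)
    return out


def dives_from_frame(df: pd.DataFrame) -> dict[str, list[Dive]]:
    out: dict[str, list[Dive]] = {}
    for _, row in df.iterrows():
        start = pd.Timestamp(row["start"]).value / 1e9
        d = Dive(individual_id=str(row["individual_id"]), start_s=start,
                 duration_s=float(row["duration_s"]), max_depth_m=float(row["max_depth_m"]),
                 postdive_s=float(row["postdive_s"]),
                 lat=float(row.get("lat", np.nan)), lon=float(row.get("lon", np.nan)),
                 bout_id=int(row["bout_id"]) if pd.notna(row.get("bout_id")) else -1)
        out.setdefault(d.individual_id, []).append(d)
    for dv in out.values():
        dv.sort(key=lambda d: d.start_s)
    return out


def bouts_from_dives(dives_by_id: dict[str, list[Dive]]) -> dict[str, list[DiveBout]]:
    out: dict[str, list[DiveBout]] = {}
    for ind, dv in dives_by_id.items():
        groups: dict[int, list[Dive]] = {}
        for d in dv:
            groups.setdefault(d.bout_id, []).append(d)
        out[ind] = [DiveBout(ind, bid, ds) for bid, ds in sorted(groups.items()) if bid >= 0]
    return out


def episodes_from_frame(df: pd.DataFrame) -> list[AssociationEpisode]:
    eps = []
    for _, row in df.iterrows():
        eps.append(AssociationEpisode(
            pair=(str(row["id_a"]), str(row["id_b"])),
            start_s=pd.Timestamp(row["start"]).value / 1e9,
            end_s=pd.Timestamp(row["end"]).value / 1e9,
            mean_distance_m=float(row.get("mean_dist_m", np.nan)),
            min_distance_m=float(row.get("min_dist_m", np.nan)),
            context=str(row.get("context", "at_sea"))))
    return eps


def sync_pairs_from_frame(df: pd.DataFrame, dives_by_id: dict[str, list[Dive]]) -> list:
    from coforage.association import SyncDivePair

    pairs = []
    for _, row in df.iterrows():
        ida, idb = str(row["id_a"]), str(row["id_b"])
        ta = pd.Timestamp(row["t_a"]).value / 1e9
        tb = pd.Timestamp(row["t_b"]).value / 1e9
        da = next((d for d in dives_by_id.get(ida, []) if abs(d.start_s - ta) < 1e-6), None)
        db = next((d for d in dives_by_id.get(idb, []) if abs(d.start_s - tb) < 1e-6), None)
        if da is None or db is None:
            logger.warning("sync pair %s/%s at %s not matched to dive rows", ida, idb, row["t_a"])
            continue
        pairs.append(SyncDivePair(pair=(ida, idb), dive_a=da, dive_b=db,
                                  surface_distance_m=float(row.get("surface_dist_m", np.nan))))
    return pairs


def run_pipeline(cfg: PipelineConfig) -> ResultBundle:
    """Read inputs, run :func:`analyze`, persist all tables plus a manifest."""
    gps = read_gps_csv(cfg.gps_path)
    tdr = read_tdr_csv(cfg.tdr_path) if cfg.tdr_path else None
    deployments = read_deployments_csv(cfg.deployments_path)
    colony = read_colony(cfg.colony_path)
    bundle = analyze(gps, tdr, deployments, colony, cfg)

    out_dir = Path(cfg.out_dir)
    tables = dict(bundle.tables)
    interp = pd.concat(
        [r.track.to_frame().assign(track_id=k) for k, r in bundle.records.items()],
        ignore_index=True) if bundle.records else pd.DataFrame(
        columns=["individual_id", "time", "lat", "lon", "track_id"])
    tables["interpolated"] = interp
    written = write_results(tables, out_dir)
    (out_dir / "stats.json").write_text(json.dumps(bundle.stats, indent=2, sort_keys=True))
    written["stats"] = out_dir / "stats.json"
    if cfg.geojson:
        write_track_geojson(
            {k: r.track.to_frame() for k, r in bundle.records.items()},
            out_dir / "tracks.geojson")
    manifest = _manifest(cfg, bundle, written)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return bundle
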