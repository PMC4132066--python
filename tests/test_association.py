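import itertools

import numpy as np
import pandas as pd
import pytest

from coforage.association import (
    AssociationEpisode,
    AssociationParameters,
    classify_track,
    deployment_day_summary,
    derive_parameters,
    detect_episodes,
    detect_sync_dives,
    dyadic_distance_series,
    exclude_rafting,
    pair_summary,
)
from coforage.dives import Dive, DiveBout
from coforage.io import ColonySite
from coforage.trips import InterpolatedTrack, Trip

from conftest import M_PER_DEG, make_fixes

T0 = 1_349_060_400.0  # arbitrary epoch anchor, multiple of 60


def track_from_offsets(ind, offsets_m, step_s=60.0, t0=T0, base_lat=-38.0, lon=142.9):
    """Track moving north; offsets_m shifts each point east (metres)."""
    n = len(offsets_m)
    times = t0 + np.arange(n) * step_s
    lat = base_lat + np.arange(n) * 60.0 / M_PER_DEG  # 1 m/s north
    lon_arr = lon + np.asarray(offsets_m) / (M_PER_DEG * np.cos(np.radians(base_lat)))
    return InterpolatedTrack(ind, step_s, times, lat, lon_arr)


class TestDyadicDistance:
    def test_parallel_tracks_constant(self):
        a = track_from_offsets("a", np.zeros(30))
        b = track_from_offsets("b", np.full(30, 300.0))
        times, dist = dyadic_distance_series(a, b)
        assert len(times) == 30
        assert np.allclose(dist, 300.0, atol=1.0)

    def test_no_overlap_empty(self):
        a = track_from_offsets("a", np.zeros(10))
        b = track_from_offsets("b", np.zeros(10), t0=T0 + 10 * 3600)
        times, dist = dyadic_distance_series(a, b)
        assert len(times) == 0 and len(dist) == 0

    def test_series_length_property(self):
        a = track_from_offsets("a", np.zeros(40))
        b = track_from_offsets("b", np.zeros(25), t0=T0 + 600.0)
        times, dist = dyadic_distance_series(a, b)
        overlap = min(a.end_s, b.end_s) - max(a.start_s, b.start_s)
        assert len(times) == overlap / 60.0 + 1

    def test_mismatched_grid_step_raises(self):
        a = track_from_offsets("a", np.zeros(10))
        b = track_from_offsets("b", np.zeros(10), step_s=30.0)
        with pytest.raises(ValueError):
            dyadic_distance_series(a, b)


def series(distances_m, step_s=60.0, t0=T0):
    t = t0 + np.arange(len(distances_m)) * step_s
    return t, np.asarray(distances_m, dtype=float)


class TestDetectEpisodes:
    params = AssociationParameters()

    def test_twenty_minute_run(self):
        t, d = series([300.0] * 21)  # spans 20 min
        eps = detect_episodes(t, d, ("a", "b"), self.params)
        assert len(eps) == 1
        assert eps[0].duration_s == 1200.0
        assert eps[0].min_distance_m == 300.0

    def test_ten_minute_run_below_threshold_discarded(self):
        t, d = series([300.0] * 11 + [9000.0] * 30)  # 10 min < 12.4 min unit
        assert detect_episodes(t, d, ("a", "b"), self.params) == []

    def test_gap_merge(self):
        # two 8-min runs separated by a 60-s gap -> one 17-min episode
        d = [200.0] * 9 + [9000.0] * 1 + [200.0] * 8
        t, d = series(d)
        eps = detect_episodes(t, d, ("a", "b"), self.params)
        assert len(eps) == 1
        assert eps[0].duration_s == pytest.approx(17 * 60.0)

    def test_boundary_distance_counts_inside(self):
        t, d = series([500.0] * 21)
        eps = detect_episodes(t, d, ("a", "b"), self.params)
        assert len(eps) == 1

    def test_pair_symmetry(self):
        t, d = series([100.0] * 30)
        e1 = detect_episodes(t, d, ("a", "b"), self.params)
        e2 = detect_episodes(t, d, ("b", "a"), self.params)
        assert e1[0].pair == e2[0].pair == ("a", "b")
        assert e1[0].start_s == e2[0].start_s and e1[0].end_s == e2[0].end_s


class TestExcludeRafting:
    colony = ColonySite(lat=-38.0, lon=142.9, rafting_radius_m=1000.0)
    params = AssociationParameters()

    def tracks_at_colony_distance(self, dist_profile_m):
        """Both individuals move north starting dist_profile away from colony."""
        n = len(dist_profile_m)
        times = T0 + np.arange(n) * 60.0
        lat = self.colony.lat + np.asarray(dist_profile_m) / M_PER_DEG
        a = InterpolatedTrack("a", 60.0, times, lat, np.full(n, self.colony.lon))
        b = InterpolatedTrack("b", 60.0, times, lat + 20.0 / M_PER_DEG,
                              np.full(n, self.colony.lon))
        return {"a": a, "b": b}

    def episode(self, n):
        return AssociationEpisode(pair=("a", "b"), start_s=T0, end_s=T0 + n * 60.0)

    def test_fully_inside_buffer_removed(self):
        tracks = self.tracks_at_colony_distance([800.0] * 31)
        out = exclude_rafting([self.episode(30)], self.colony, self.params, tracks)
        assert out == []

    def test_half_inside_trimmed(self):
        profile = [500.0] * 20 + [3000.0] * 21  # first 20 min rafting
        tracks = self.tracks_at_colony_distance(profile)
        out = exclude_rafting([self.episode(40)], self.colony, self.params, tracks)
        assert len(out) == 1
        assert out[0].duration_s >= self.params.min_duration_s
        assert out[0].start_s >= T0 + 19 * 60.0

    def test_far_episode_untouched(self):
        tracks = self.tracks_at_colony_distance([5000.0] * 31)
        eps = [self.episode(30)]
        out = exclude_rafting(eps, self.colony, self.params, tracks)
        assert out == eps


def dive(ind, start, dur=20.0):
    return Dive(individual_id=ind, start_s=start, duration_s=dur, max_depth_m=5.0)


def shared_episode(start=T0, end=T0 + 1200.0):
    return AssociationEpisode(pair=("a", "b"), start_s=start, end_s=end)


class TestSyncDives:
    params = AssociationParameters()

    def test_within_window(self):
        eps = [shared_episode()]
        pairs = detect_sync_dives(eps, [dive("a", T0 + 100)], [dive("b", T0 + 103)], self.params)
        assert len(pairs) == 1
        assert pairs[0].delta_s == 3.0
        assert eps[0].n_sync_dives == 1

    def test_beyond_window_no_pair(self):
        pairs = detect_sync_dives([shared_episode()],
                                  [dive("a", T0 + 100)], [dive("b", T0 + 105)], self.params)
        assert pairs == []

    def test_boundary_inclusive(self):
        pairs = detect_sync_dives([shared_episode()],
                                  [dive("a", T0 + 100)], [dive("b", T0 + 104)], self.params)
        assert len(pairs) == 1

    def test_one_to_one_matching_brute_force(self):
        a_dives = [dive("a", T0 + 100), dive("a", T0 + 104)]
        b_dives = [dive("b", T0 + 102)]
        pairs = detect_sync_dives([shared_episode()], a_dives, b_dives, self.params)
        # brute force: maximal one-to-one matching size over all assignments
        best = 0
        for perm in itertools.permutations(range(len(a_dives)), len(b_dives)):
            ok = sum(abs(a_dives[i].start_s - b.start_s) <= 4.0
                     for i, b in zip(perm, b_dives))
            best = max(best, ok)
        assert best == 1
        assert len(pairs) == 1
        assert {id(p.dive_b) for p in pairs} == {id(b_dives[0])}

    def test_dive_outside_episode_ignored(self):
        pairs = detect_sync_dives([shared_episode()],
                                  [dive("a", T0 + 2000)], [dive("b", T0 + 2001)], self.params)
        assert pairs == []

    def test_surface_distance_computed(self):
        a = track_from_offsets("a", np.zeros(30))
        b = track_from_offsets("b", np.full(30, 100.0))
        pairs = detect_sync_dives([shared_episode()], [dive("a", T0 + 120)],
                                  [dive("b", T0 + 120)], self.params, a, b)
        assert pairs[0].surface_distance_m == pytest.approx(100.0, abs=1.0)


def simple_trip(duration_s=36000.0):
    fixes = make_fixes([0.0, duration_s], [-38.0, -38.0], [142.9, 142.9],
                       start=pd.Timestamp(T0, unit="s"))
    return Trip("a", fixes["time"].iloc[0], fixes["time"].iloc[1], fixes)


def bout(ind, start, end):
    d = dive(ind, start, 20.0)
    d2 = dive(ind, end - 20.0, 20.0)
    return DiveBout(ind, 0, [d, d2])


class TestClassifyTrack:
    def test_no_episodes_group_1(self):
        cls = classify_track(simple_trip(), [], [], [], [])
        assert cls.group == "1"
        assert cls.pct_total_assoc == 0.0

    def test_commute_only_group_2(self):
        trip = simple_trip()
        bouts = [bout("a", T0 + 10000, T0 + 11000)]
        ep = AssociationEpisode(pair=("a", "b"), start_s=T0 + 1000, end_s=T0 + 2000)
        cls = classify_track(trip, [ep], [], [], bouts)
        assert cls.group == "2"
        assert cls.any_commute_assoc and not cls.any_at_sea_assoc

    def test_at_sea_no_dives_group_3a(self):
        trip = simple_trip()
        bouts = [bout("a", T0 + 5000, T0 + 6000), bout("a", T0 + 20000, T0 + 21000)]
        ep = AssociationEpisode(pair=("a", "b"), start_s=T0 + 8000, end_s=T0 + 9000)
        cls = classify_track(trip, [ep], [], [], bouts)
        assert cls.group == "3a"

    def test_dives_during_episode_group_3b(self):
        trip = simple_trip()
        bouts = [bout("a", T0 + 5000, T0 + 6000), bout("a", T0 + 20000, T0 + 21000)]
        ep = AssociationEpisode(pair=("a", "b"), start_s=T0 + 5500, end_s=T0 + 6500)
        dives = [dive("a", T0 + 5600)]
        cls = classify_track(trip, [ep], dives, [], bouts)
        assert cls.group == "3b"
        assert cls.pct_async_diving_assoc > 0

    def test_sync_group_3c_and_budget_ordering(self):
        trip = simple_trip()
        bouts = [bout("a", T0 + 5000, T0 + 6000), bout("a", T0 + 20000, T0 + 21000)]
        ep = AssociationEpisode(pair=("a", "b"), start_s=T0 + 5000, end_s=T0 + 7000)
        dives = [dive("a", T0 + 5600), dive("a", T0 + 5700), dive("a", T0 + 5800)]
        from coforage.association import SyncDivePair
        sps = [SyncDivePair(pair=("a", "b"), dive_a=dives[0], dive_b=dive("b", T0 + 5602))]
        cls = classify_track(trip, [ep], dives, sps, bouts)
        assert cls.group == "3c"
        assert cls.pct_total_assoc >= cls.pct_sync_diving
        assert cls.pct_total_assoc >= cls.pct_async_diving_assoc
        assert cls.pct_total_assoc == pytest.approx(
            cls.pct_travelling_assoc + cls.pct_async_diving_assoc + cls.pct_sync_diving)

    def test_no_dive_record_restricted_and_flagged(self):
        trip = simple_trip()
        ep = AssociationEpisode(pair=("a", "b"), start_s=T0 + 8000, end_s=T0 + 9000)
        cls = classify_track(trip, [ep], None, [], None)
        assert cls.group in {"1", "2", "3a"}
        assert not cls.dive_record_available

    def test_deterministic_and_total(self, sim_bundle):
        groups = sim_bundle.tables["classification"]["group"]
        assert groups.isin(["1", "2", "3a", "3b", "3c"]).all()

    def test_overlapping_episodes_capped(self):
        trip = simple_trip()
        eps = [AssociationEpisode(pair=("a", "b"), start_s=T0, end_s=T0 + 36000.0),
               AssociationEpisode(pair=("a", "c"), start_s=T0, end_s=T0 + 36000.0)]
        cls = classify_track(trip, eps, [], [], [])
        assert cls.pct_total_assoc == pytest.approx(100.0)


class TestSummaries:
    def test_pair_summary_counts(self):
        from coforage.association import SyncDivePair
        ep = shared_episode()
        sps = []
        for k in range(10):
            da = dive("a", T0 + 100 + 60 * k)
            db = dive("b", T0 + 102 + 60 * k)
            sps.append(SyncDivePair(pair=("a", "b"), dive_a=da, dive_b=db))
        table = pair_summary([ep], sps)
        assert len(table) == 1
        assert table["n_sync_dives"].iloc[0] == 10
        assert table["assoc_duration_min"].iloc[0] == pytest.approx(20.0)

    def test_single_sync_range_collapses(self):
        from coforage.association import SyncDivePair
        sp = SyncDivePair(pair=("a", "b"), dive_a=dive("a", T0, 24.0), dive_b=dive("b", T0 + 2, 24.0))
        table = pair_summary([shared_episode()], [sp])
        row = table.iloc[0]
        assert row["dive_duration_min_s"] == row["dive_duration_max_s"] == row["dive_duration_median_s"]

    def test_day_summary(self):
        from coforage.association import TrackClassification
        cls = [TrackClassification("a", "3c"), TrackClassification("b", "1"),
               TrackClassification("c", "2")]
        deployments = pd.DataFrame({
            "individual_id": ["a", "b", "c"],
            "sex": ["female", "male", "female"],
            "nest_id": ["n1", "n2", "n3"],
            "nest_lat": [-38.0] * 3, "nest_lon": [142.9] * 3,
            "date": ["2012-10-01"] * 3,
        })
        out = deployment_day_summary(cls, deployments)
        assert out["n_instrumented"].iloc[0] == 3
        assert out["n_associating"].iloc[0] == 2
        assert out["pct_associating"].iloc[0] == pytest.approx(100 * 2 / 3)


class TestDerivedParameters:
    def test_derive_from_bouts(self):
        dives_ = [dive("a", T0), dive("a", T0 + 700.0)]
        b = DiveBout("a", 0, dives_)
        b.horizontal_km = 1.0
        p = derive_parameters([b, b])
        assert p.min_duration_s == pytest.approx(720.0)
        assert p.radius_m == pytest.approx(500.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            AssociationParameters(radius_m=-5)
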