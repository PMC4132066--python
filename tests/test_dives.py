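import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from coforage.dives import (
    BoutFitError,
    Dive,
    assign_bouts,
    assign_bouts_from_criterion,
    bec_from_params,
    bout_horizontal_distance,
    criterion_values,
    detect_dives,
    fit_bout_model,
    locate_dives,
    sequential_differences,
    single_exponential_loglik,
    zero_offset_correct,
)
from coforage.trips import InterpolatedTrack

from conftest import M_PER_DEG, make_depth_series


class TestZeroOffsetCorrect:
    def test_constant_offset_removed(self):
        # 0.5 m baseline with frequent surface intervals and a few dives
        depths = np.full(600, 0.5)
        for s in range(50, 600, 100):
            depths[s : s + 10] += 5.0
        out = zero_offset_correct(make_depth_series(depths), 300.0, 0.02)
        surface = out["depth_m"].to_numpy()[depths == 0.5]
        assert np.all(surface <= 0.05)

    def test_drift_ramp_brute_force_oracle(self):
        # drift 0 -> 1 m over the record, surfacing every 2 min
        n = 1800  # 2 h at 4 s
        t = np.arange(n) * 4.0
        drift = t / t[-1]
        depths = drift.copy()
        for s in range(15, n - 10, 30):  # dive every 2 min
            depths[s : s + 5] += 6.0
        series = make_depth_series(depths)
        out = zero_offset_correct(series, 300.0, 0.02)

        # oracle: piecewise baseline computed by brute force over the same
        # windows, then linearly interpolated
        window = 300.0
        n_win = int(np.ceil((t[-1] + 1e-9) / window))
        centers, base = [], []
        for k in range(n_win):
            m = (t >= k * window) & (t < (k + 1) * window)
            centers.append(0.5 * (t[m][0] + t[m][-1]))
            base.append(np.quantile(depths[m], 0.02))
        oracle = np.clip(depths - np.interp(t, centers, base), 0, None)
        np.testing.assert_allclose(out["depth_m"].to_numpy(), oracle, atol=1e-12)

        surface_mask = depths == drift
        assert np.max(out["depth_m"].to_numpy()[surface_mask]) < 0.1

    def test_all_zero_unchanged(self):
        series = make_depth_series(np.zeros(300))
        out = zero_offset_correct(series)
        assert (out["depth_m"] == 0).all()

    def test_window_too_short_errors(self):
        with pytest.raises(ValueError):
            zero_offset_correct(make_depth_series(np.zeros(100)), window_s=8.0)


class TestDetectDives:
    def test_rectangular_excursion(self):
        depths = np.zeros(30)
        depths[10:15] = 3.0
        dives = detect_dives(make_depth_series(depths), 1.0, "a")
        assert len(dives) == 1
        d = dives[0]
        assert d.duration_s == 20.0
        assert d.max_depth_m == 3.0
        assert np.isnan(d.postdive_s)

    def test_below_threshold_no_dive(self):
        depths = np.zeros(30)
        depths[10:15] = 0.9
        assert detect_dives(make_depth_series(depths), 1.0) == []

    def test_postdive_interval(self):
        depths = np.zeros(50)
        depths[5:10] = 2.0   # ends at sample 10
        depths[22:27] = 2.0  # starts 12 samples (48 s) later
        dives = detect_dives(make_depth_series(depths), 1.0)
        assert len(dives) == 2
        assert dives[0].postdive_s == 48.0
        assert np.isnan(dives[1].postdive_s)


class TestSequentialDifferences:
    def test_example(self):
        np.testing.assert_array_equal(sequential_differences([10, 12, 100]), [2, 88])

    def test_constant_zeroes(self):
        assert (sequential_differences([7, 7, 7, 7]) == 0).all()

    def test_single_empty(self):
        assert sequential_differences([5]).size == 0


class TestBoutModel:
    def test_closed_form_bec(self):
        assert bec_from_params(0.5, 0.1, 0.01) == pytest.approx(np.log(10) / 0.09, rel=1e-12)
        assert bec_from_params(0.5, 0.1, 0.01) == pytest.approx(25.584, abs=5e-3)

    def test_bec_undefined_when_fast_never_dominates(self):
        assert np.isnan(bec_from_params(0.01, 0.011, 0.01))

    def test_bec_matches_numeric_crossing(self):
        # independent route: solve p*lf*exp(-lf t) = (1-p)*ls*exp(-ls t)
        grid = [(p, lf, ls)
                for p in (0.3, 0.5, 0.7, 0.9)
                for lf in (0.05, 0.1, 0.5)
                for ls in (0.001, 0.005, 0.01)]
        for p, lf, ls in grid:
            if p * lf <= (1 - p) * ls:
                continue
            f = lambda t: p * lf * np.exp(-lf * t) - (1 - p) * ls * np.exp(-ls * t)
            # bracket the crossing by scanning before root-finding (the
            # exponential tails underflow at large t)
            grid = np.logspace(-6, 7, 2000)
            sign = np.sign(f(grid))
            idx = np.flatnonzero(np.diff(sign) != 0)[0]
            t_num = brentq(f, grid[idx], grid[idx + 1], xtol=1e-12)
            assert bec_from_params(p, lf, ls) == pytest.approx(t_num, abs=1e-9)

    def test_bec_monotone_in_lambda_fast(self):
        lfs = np.linspace(0.05, 0.5, 40)
        becs = [bec_from_params(0.6, lf, 0.005) for lf in lfs]
        assert all(b1 > b2 for b1, b2 in zip(becs[:-1], becs[1:]))

    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        p, lf, ls = 0.7, 0.05, 0.005
        n = 2000
        fast = rng.random(n) < p
        x = np.where(fast, rng.exponential(1 / lf, n), rng.exponential(1 / ls, n))
        fit = fit_bout_model(x, seed=0)
        assert fit.p_fast == pytest.approx(p, rel=0.15)
        assert fit.lambda_fast == pytest.approx(lf, rel=0.15)
        assert fit.lambda_slow == pytest.approx(ls, rel=0.15)

    def test_bec_recovery_median_under_10pct(self):
        # 20 seeded simulations at n=1000
        true_bec = bec_from_params(0.7, 0.05, 0.005)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fast = rng.random(1000) < 0.7
            x = np.where(fast, rng.exponential(20.0, 1000), rng.exponential(200.0, 1000))
            fit = fit_bout_model(x, seed=seed)
            errs.append(abs(fit.bec_s - true_bec) / true_bec)
        assert np.median(errs) < 0.10

    def test_mixture_beats_single_exponential(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.exponential(10, 300), rng.exponential(300, 60)])
        fit = fit_bout_model(x, seed=0)
        assert fit.loglik >= single_exponential_loglik(x) - 1e-6

    def test_degenerate_data_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_bout_model(np.full(50, 3.0))

    def test_small_sample_warns(self, caplog):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.exponential(10, 10), rng.exponential(500, 10)])
        with caplog.at_level("WARNING", logger="coforage.dives"):
            fit_bout_model(x, seed=0)
        assert any("recommended" in r.message for r in caplog.records)


def dive_at(start, dur=20.0, pd_s=np.nan, ind="a"):
    return Dive(individual_id=ind, start_s=start, duration_s=dur, max_depth_m=5.0,
                postdive_s=pd_s)


class TestAssignBouts:
    def test_diff_rule_example(self):
        dives = [dive_at(0), dive_at(100), dive_at(300)]
        bouts = assign_bouts_from_criterion(dives, [2, 88], 25.0)
        assert [b.n_dives for b in bouts] == [2, 1]
        assert dives[0].bout_id == dives[1].bout_id == 0
        assert dives[2].bout_id == 1

    def test_all_below_one_bout(self):
        dives = [dive_at(i * 50.0) for i in range(5)]
        bouts = assign_bouts_from_criterion(dives, [1, 1, 1, 1], 25.0)
        assert len(bouts) == 1 and bouts[0].n_dives == 5

    def test_all_above_singletons(self):
        dives = [dive_at(i * 50.0) for i in range(4)]
        bouts = assign_bouts_from_criterion(dives, [99, 99, 99], 25.0)
        assert [b.n_dives for b in bouts] == [1, 1, 1, 1]

    def test_postdive_variable(self):
        # gaps: 30, 500, 30 -> bout boundary after the 500-s surface interval
        starts = [0.0, 50.0, 570.0, 620.0]
        dives = []
        for i, s in enumerate(starts):
            nxt = starts[i + 1] if i + 1 < len(starts) else None
            dives.append(dive_at(s, 20.0, (nxt - s - 20.0) if nxt else np.nan))
        bouts = assign_bouts(dives, bec_s=120.0, variable="postdive")
        assert [b.n_dives for b in bouts] == [2, 2]

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        t = 0.0
        dives = []
        for _ in range(60):
            dives.append(dive_at(t, 20.0))
            t += 20.0 + rng.exponential(40.0)
        for a, b in zip(dives[:-1], dives[1:]):
            a.postdive_s = b.start_s - a.end_s
        bouts = assign_bouts(dives, bec_s=60.0)
        assert sum(b.n_dives for b in bouts) == len(dives)
        ids = [d.bout_id for b in bouts for d in b.dives]
        assert sorted(ids) == sorted(d.bout_id for d in dives)
        for b in bouts:
            assert all(d.bout_id == b.bout_id for d in b.dives)

    def test_criterion_values_variables(self):
        dives = [dive_at(0, 20, 10), dive_at(30, 24, 12), dive_at(66, 28, np.nan)]
        np.testing.assert_array_equal(criterion_values(dives, "postdive"), [10, 12])
        np.testing.assert_array_equal(criterion_values(dives, "postdive_diff"), [2])
        np.testing.assert_array_equal(criterion_values(dives, "duration_diff"), [4, 4])
        with pytest.raises(ValueError):
            criterion_values(dives, "nope")


def straight_track(length_m=2000.0, step_s=60.0, speed=1.0):
    n = int(length_m / (speed * step_s)) + 1
    times = np.arange(n) * step_s
    lats = -38.6 + np.arange(n) * speed * step_s / M_PER_DEG
    return InterpolatedTrack("a", step_s, times + 1e9, lats, np.full(n, 142.9))


class TestBoutGeometry:
    def test_straight_segment_distance(self):
        track = straight_track()
        from coforage.dives import DiveBout
        d1 = dive_at(track.times_s[0], 20.0)
        d2 = dive_at(track.times_s[0] + 980.0, 20.0)
        bout = DiveBout("a", 0, [d1, d2])
        km = bout_horizontal_distance(bout, track)
        assert km == pytest.approx(1.0, rel=1e-3)

    def test_single_dive_bout_uses_bracketing_points(self):
        track = straight_track()
        from coforage.dives import DiveBout
        d = dive_at(track.times_s[3] + 10.0, 20.0)
        bout = DiveBout("a", 0, [d])
        km = bout_horizontal_distance(bout, track)
        assert km == pytest.approx(60.0 / 1000.0, rel=1e-3)  # one grid step at 1 m/s
        assert km >= 0

    def test_locate_dives(self):
        track = straight_track()
        on_grid = dive_at(track.times_s[2])
        midway = dive_at((track.times_s[2] + track.times_s[3]) / 2)
        before = dive_at(track.times_s[0] - 500.0)
        out = locate_dives([on_grid, midway, before], track)
        assert out[0].lat == pytest.approx(track.lat[2])
        assert out[1].lat == pytest.approx((track.lat[2] + track.lat[3]) / 2)
        assert not out[2].location_ok and np.isnan(out[2].lat)
        assert out[0].location_ok


class TestSimBoutRecovery:
    def test_bout_stats_match_generator(self, sim_result, sim_bundle):
        truth_mean = sim_result.truth.bouts["duration_min"].mean()
        det = sim_bundle.tables["bouts"]["duration_min"]
        assert det.mean() == pytest.approx(truth_mean, rel=0.10)
        n_truth = len(sim_result.truth.bouts)
        assert abs(len(det) - n_truth) <= 0.15 * n_truth

    def test_horizontal_distance_target(self, sim_bundle):
        horiz = sim_bundle.tables["bouts"]["horiz_km"]
        se = horiz.std() / np.sqrt(len(horiz))
        assert abs(horiz.mean() - 0.99) <= max(2 * se, 0.05)
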