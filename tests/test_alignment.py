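"""Peri-meal alignment, P_sleep/dP_sleep, initiation, position, speed."""

import itertools

import numpy as np
import pandas as pd
import pytest

import flyarc
from flyarc import alignment, tracking
from flyarc.alignment import (AlignedSleepMatrix, align_to_meals, delta_psleep,
                              delta_speed_motion, paired_prepost_test,
                              position_kinetics, psleep_curve,
                              rel_minute_axis, sleep_initiation_prob,
                              zt_bin_labels)
from flyarc.errors import ParameterError
from flyarc.tracking import ActivitySeries, MotionEvent, SleepBout


def meal_row(fly_id, minute, volume=0.03):
    return {"fly_id": fly_id, "time_s": minute * 60 + 30, "minute": minute,
            "volume_ul": volume}


def meals_df(rows):
    return pd.DataFrame(rows)


class TestAlignToMeals:
    def test_always_asleep_fly_gives_all_ones(self):
        sleep = {0: np.ones(200)}
        mat = align_to_meals(sleep, meals_df([meal_row(0, 100)]), window=30)
        assert mat.values.shape == (1, 60)
        assert np.all(mat.values == 1.0)
        assert mat.valid.all()

    def test_meal_minute_excluded_from_axis(self):
        assert 0 not in rel_minute_axis(60)

    def test_recording_start_masks_early_bins(self):
        sleep = {0: np.ones(1440)}
        mat = align_to_meals(sleep, meals_df([meal_row(0, 10)]), window=60)
        for k in range(-60, -10):
            assert not mat.valid[0, mat.column(k)]
        assert mat.valid[0, mat.column(-10)]
        assert mat.valid[0, mat.column(60)]

    def test_meal_outside_recording_rejected(self):
        sleep = {0: np.ones(100)}
        with pytest.raises(ParameterError):
            align_to_meals(sleep, meals_df([meal_row(0, 200)]), window=10)

    def test_masked_epochs_apply_per_fly(self):
        sleep = {0: np.ones(300)}
        mat = align_to_meals(sleep, meals_df([meal_row(0, 100)]), window=30,
                             masked_minutes={0: np.arange(110, 120)})
        for k in range(10, 20):
            assert not mat.valid[0, mat.column(k)]
        assert mat.valid[0, mat.column(9)]

    def test_cells_match_per_second_recount(self, small_behavior):
        sf = {f.fly_id: tracking.per_minute_sleep_fraction(f.sleep_state_s)
              for f in small_behavior.flies}
        meals = small_behavior.meals
        mat = align_to_meals(sf, meals, window=20)
        flies = {f.fly_id: f for f in small_behavior.flies}
        for i, row in enumerate(meals.itertuples(index=False)):
            state = flies[int(row.fly_id)].sleep_state_s
            m0 = int(row.time_s) // 60
            for j, k in enumerate(mat.rel_minutes):
                m = m0 + int(k)
                if 0 <= m * 60 and (m + 1) * 60 <= len(state):
                    want = state[m * 60:(m + 1) * 60].mean()
                    assert mat.values[i, j] == pytest.approx(want)


class TestPsleepCurve:
    def test_simple_mean(self):
        rel = rel_minute_axis(10)
        values = np.zeros((2, 20))
        values[1, :] = 1.0
        mat = AlignedSleepMatrix(meals_df([meal_row(0, 50), meal_row(1, 50)]),
                                 rel, values, np.ones((2, 20), dtype=bool))
        curve = psleep_curve(mat)
        assert np.all(curve["psleep_mean"] == 0.5)
        assert np.all(curve["n"] == 2)

    def test_empty_bin_reported_missing(self):
        rel = rel_minute_axis(5)
        valid = np.ones((1, 10), dtype=bool)
        valid[0, 0] = False
        mat = AlignedSleepMatrix(meals_df([meal_row(0, 50)]), rel,
                                 np.ones((1, 10)), valid)
        curve = psleep_curve(mat)
        assert np.isnan(curve["psleep_mean"].iloc[0])
        assert curve["n"].iloc[0] == 0


class TestDeltaPsleep:
    def test_post_sleep_pre_wake_gives_one(self):
        rel = rel_minute_axis(20)
        values = np.where(rel > 0, 1.0, 0.0)[None, :].repeat(3, axis=0)
        mat = AlignedSleepMatrix(
            meals_df([meal_row(i, 100) for i in range(3)]), rel, values,
            np.ones_like(values, dtype=bool))
        summ = delta_psleep(mat, 20)
        np.testing.assert_allclose(summ.per_meal, 1.0)
        np.testing.assert_allclose(summ.per_bin, 1.0)

    def test_mirror_symmetry_gives_zero(self):
        rng = np.random.default_rng(0)
        rel = rel_minute_axis(20)
        pre = rng.random((5, 20))
        values = np.concatenate([pre, pre[:, ::-1]], axis=1)
        mat = AlignedSleepMatrix(
            meals_df([meal_row(i, 100) for i in range(5)]), rel, values,
            np.ones_like(values, dtype=bool))
        summ = delta_psleep(mat, 20)
        np.testing.assert_allclose(summ.per_meal, 0.0, atol=1e-12)
        np.testing.assert_allclose(summ.per_bin, 0.0, atol=1e-12)

    def test_per_bin_mean_equals_per_meal_mean_when_unmasked(self):
        rng = np.random.default_rng(1)
        rel = rel_minute_axis(20)
        values = rng.random((50, 40))
        mat = AlignedSleepMatrix(
            meals_df([meal_row(i, 100) for i in range(50)]), rel, values,
            np.ones_like(values, dtype=bool))
        summ = delta_psleep(mat, 20)
        assert summ.per_bin.mean() == pytest.approx(np.mean(summ.per_meal))

    def test_partial_span_meals_excluded_and_counted(self):
        sleep = {0: np.ones(1440)}
        mat = align_to_meals(sleep, meals_df([meal_row(0, 10),
                                              meal_row(0, 700)]), window=20)
        summ = delta_psleep(mat, 20)
        assert summ.n_excluded == 1
        assert np.isnan(summ.per_meal[0]) and np.isfinite(summ.per_meal[1])

    def test_kernel_sweep_monotonicity(self):
        recovered = []
        for amp in (0.0, 0.1, 0.2, 0.3):
            p = flyarc.BehaviorParams(n_flies=10, duration_s=12 * 3600,
                                      seed=77, kernel_amplitude=amp)
            b = flyarc.simulate_behavior(p)
            sf = {f.fly_id: tracking.per_minute_sleep_fraction(f.sleep_state_s)
                  for f in b.flies}
            summ = delta_psleep(align_to_meals(sf, b.meals, window=20), 20)
            recovered.append(summ.mean)
        assert recovered == sorted(recovered)


class TestSleepInitiation:
    def test_single_bout_start(self):
        meals = meals_df([meal_row(0, 100)])
        bouts = {0: [SleepBout(103 * 60, 110 * 60, 7 * 60)]}
        out = sleep_initiation_prob(bouts, meals, window=10)
        hit = out[out["rel_minute"] == 3]["p_initiation"].iloc[0]
        assert hit == 1.0
        assert out["p_initiation"].sum() == 1.0
        assert out.attrs["post_rate"] == 1.0
        assert out.attrs["pre_rate"] == 0.0

    def test_no_bouts_all_zero(self):
        out = sleep_initiation_prob({0: []}, meals_df([meal_row(0, 100)]),
                                    window=10)
        assert np.all(out["p_initiation"] == 0.0)

    def test_matches_recount_on_simulator(self, small_behavior):
        flies = small_behavior.flies
        bouts = {}
        for f in flies:
            tr_bouts = []
            s = f.sleep_state_s
            starts = np.flatnonzero(np.diff(np.concatenate([[0], s])) == 1)
            ends = np.flatnonzero(np.diff(np.concatenate([s, [0]])) == -1) + 1
            for a, b in zip(starts, ends):
                tr_bouts.append(SleepBout(int(a), int(b), int(b - a)))
            bouts[f.fly_id] = tr_bouts
        meals = small_behavior.meals
        out = sleep_initiation_prob(bouts, meals, window=15)
        # literal recount
        for j, k in enumerate(out["rel_minute"]):
            count = 0
            for row in meals.itertuples(index=False):
                m = int(row.time_s) // 60 + int(k)
                start_mins = {b.start_s // 60 for b in bouts[int(row.fly_id)]}
                count += m in start_mins
            assert out["p_initiation"].iloc[j] == pytest.approx(
                count / len(meals))


class TestPositionKinetics:
    def _trace(self, y_values, fly_id=0):
        n = len(y_values)
        return flyarc.PositionTrace(fly_id=fly_id, x=np.full(n, 5.0),
                                    y=np.asarray(y_values, dtype=float),
                                    tracked=np.ones(n, dtype=bool), fbl_px=16.0)

    def test_stationary_fly_flat_kymograph(self):
        tr = self._trace(np.full(7200, 42.0))
        kym, _, _ = position_kinetics({0: tr}, meals_df([meal_row(0, 60)]))
        assert np.allclose(kym["mean_y"], 42.0)

    def test_heatmap_mass_conservation(self):
        rng = np.random.default_rng(0)
        tr = self._trace(rng.uniform(0, 100, 7200))
        kym, pre, post = position_kinetics({0: tr}, meals_df([meal_row(0, 60)]),
                                           window_min=20)
        assert pre.sum() == 20 * 60          # seconds in the pre window
        assert post.sum() == 20 * 60

    def test_post_meal_proximity_bias_recovered(self):
        bias = 25.0
        p = flyarc.BehaviorParams(n_flies=6, duration_s=8 * 3600, seed=21)
        b = flyarc.simulate_behavior(p)
        traces = {t.fly_id: t for t in flyarc.render_position_trace(
            b, post_meal_bias_px=bias, bias_duration_min=20)}
        kym, _, _ = position_kinetics(traces, b.meals, window_min=20)
        pre = np.nanmean(kym.attrs["per_meal_pre_y"])
        post = np.nanmean(kym.attrs["per_meal_post_y"])
        assert (pre - post) == pytest.approx(bias, abs=8.0)


class TestDeltaSpeedMotion:
    def _series(self, events, n=7200):
        disp = np.zeros(n)
        for e in events:
            disp[e.start_s:e.end_s + 1] = e.speed_px_per_s
        return ActivitySeries(0, disp, list(events), 16.0)

    def test_identical_prepost_zero(self):
        events = [MotionEvent(3000, 3000, 10.0, 1, 10.0),
                  MotionEvent(4200, 4200, 10.0, 1, 10.0)]
        ser = self._series(events)
        out = delta_speed_motion({0: ser}, meals_df([meal_row(0, 60)]))
        assert out["delta_speed"].iloc[0] == pytest.approx(0.0)

    def test_doubled_post_speed(self):
        pre = [MotionEvent(3000, 3000, 8.0, 1, 8.0),
               MotionEvent(3200, 3200, 12.0, 1, 12.0)]
        post = [MotionEvent(4000, 4000, 16.0, 1, 16.0),
                MotionEvent(4200, 4200, 24.0, 1, 24.0)]
        ser = self._series(pre + post)
        out = delta_speed_motion({0: ser}, meals_df([meal_row(0, 60)]))
        assert out["delta_speed"].iloc[0] == pytest.approx(10.0)  # mean pre

    def test_meals_without_events_counted(self):
        ser = self._series([])
        out = delta_speed_motion({0: ser}, meals_df([meal_row(0, 60)]))
        assert np.isnan(out["delta_speed"].iloc[0])
        assert out.attrs["n_excluded_speed"] == 1


class TestPairedTest:
    def test_all_ties_p_one(self):
        pre = np.full(10, 0.3)
        stat, p = paired_prepost_test(pre, pre.copy())
        assert p == 1.0

    def test_constant_shift_matches_exact_enumeration(self):
        rng = np.random.default_rng(2)
        pre = rng.random(12)
        post = pre + rng.uniform(0.5, 1.5, 12)  # distinct positive diffs
        _, p = paired_prepost_test(pre, post)
        # literal enumeration of all sign assignments
        d = post - pre
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_obs = ranks[d > 0].sum()
        ws = [np.sum(np.array(signs) * ranks)
              for signs in itertools.product([0, 1], repeat=12)]
        ws = np.array(ws)
        p_or = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
        assert p == pytest.approx(min(p_or, 1.0), rel=1e-9)

    def test_twenty_unit_shifts_extreme_p(self):
        pre = np.zeros(20)
        _, p = paired_prepost_test(pre, pre + 1.0)
        assert p == pytest.approx(2 / 2 ** 20)

    def test_requires_six_pairs(self):
        with pytest.raises(ParameterError):
            paired_prepost_test(np.zeros(5), np.ones(5))


class TestZtPartition:
    def test_bin_labels(self):
        times = np.array([0, 3600 * 5, 3600 * 23]) + 100
        np.testing.assert_array_equal(zt_bin_labels(times), [0, 4, 20])

    def test_offset_and_wraparound(self):
        times = np.array([0])
        assert zt_bin_labels(times, zt0_offset_s=3600)[0] == 20

    def test_partitioned_values_average_back(self, small_behavior):
        sf = {f.fly_id: tracking.per_minute_sleep_fraction(f.sleep_state_s)
              for f in small_behavior.flies}
        meals = small_behavior.meals
        mat = align_to_meals(sf, meals, window=20)
        summ = delta_psleep(mat, 20)
        labels = zt_bin_labels(meals["time_s"].to_numpy())
        total_n = 0
        weighted = 0.0
        for zt in np.unique(labels):
            sel = labels == zt
            vals = summ.per_meal[sel]
            n = np.sum(np.isfinite(vals))
            if n:
                weighted += np.nansum(vals)
                total_n += n
        assert weighted / total_n == pytest.approx(summ.mean)
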