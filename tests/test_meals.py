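"""Meal caller: noise filtration, selection, correction, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flyarc.errors import ParameterError
from flyarc.meals import (Diet, call_meals, correct_meals, estimate_noise,
                          to_volume_and_nutrients)
from flyarc.meniscus import MeniscusTrace

from oracles import meal_selection_oracle, noise_filtration_oracle


def make_trace(delta, flagged=None):
    delta = np.asarray(delta, dtype=float)
    return MeniscusTrace(
        capillary_id=0,
        distance_px=np.cumsum(delta),
        delta_px=delta,
        minutes=np.arange(len(delta), dtype=float),
        flagged=np.zeros(len(delta), dtype=bool) if flagged is None
        else np.asarray(flagged, dtype=bool),
    )


class TestEstimateNoise:
    def test_constant_series_single_iteration(self):
        nm = estimate_noise(np.zeros(100))
        assert (nm.mean_px, nm.sd_px, nm.n_iterations) == (0.0, 0.0, 1)
        nm = estimate_noise(np.full(50, 3.5))
        assert (nm.mean_px, nm.sd_px) == (3.5, 0.0)

    def test_spikes_removed_and_moments_recovered(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0.0, 1.0, 1440)
        series = noise.copy()
        spike_at = [100, 400, 700, 1000, 1300]
        series[spike_at] += 20.0
        nm = estimate_noise(series)
        assert nm.n_retained == 1440 - len(spike_at)
        clean = np.delete(noise, spike_at)
        assert nm.mean_px == pytest.approx(clean.mean(), abs=0.1)
        assert nm.sd_px == pytest.approx(clean.std(ddof=1), abs=0.1)

    def test_cascading_removal_matches_literal_oracle(self):
        rng = np.random.default_rng(1)
        series = rng.lognormal(0.0, 1.5, 500)  # heavy tail forces cascades
        nm = estimate_noise(series)
        mean, sd, n, it = noise_filtration_oracle(series)
        assert nm.mean_px == pytest.approx(mean, rel=1e-12)
        assert nm.sd_px == pytest.approx(sd, rel=1e-12)
        assert (nm.n_retained, nm.n_iterations) == (n, it)
        assert it > 2  # the fixture actually cascades

    def test_retained_set_invariant(self):
        rng = np.random.default_rng(2)
        series = np.concatenate([rng.normal(0, 1, 300),
                                 rng.normal(15, 1, 10)])
        nm = estimate_noise(series)
        kept = series[series <= nm.mean_px + 4.0 * nm.sd_px]
        assert len(kept) >= nm.n_retained

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            estimate_noise(np.zeros(5))

    def test_flagged_frames_excluded(self):
        series = np.zeros(100)
        series[50] = 1000.0
        flagged = np.zeros(100, dtype=bool)
        flagged[50] = True
        nm = estimate_noise(series, flagged)
        assert nm.mean_px == 0.0 and nm.n_retained == 99


class TestCallMeals:
    def test_single_impulse(self):
        delta = np.zeros(200)
        delta[50] = 10.0
        nm = estimate_noise(np.zeros(100))  # mean 0 sd 0 -> threshold 0
        trace = make_trace(delta)
        from flyarc.meals import NoiseModel
        meals = call_meals(trace, NoiseModel(0.0, 1.0, 100, 1))
        assert len(meals) == 1
        m = meals[0]
        assert (m.time_min, m.raw_px) == (50, 10.0)

    def test_adjacent_bouts_merge_with_latter_timestamp(self):
        from flyarc.meals import NoiseModel
        delta = np.zeros(200)
        delta[50], delta[51] = 6.0, 7.0
        meals = call_meals(make_trace(delta), NoiseModel(0.0, 1.0, 100, 1))
        assert len(meals) == 1
        assert meals[0].time_min == 51
        assert meals[0].raw_px == 13.0

    def test_flagged_frames_never_meals(self):
        from flyarc.meals import NoiseModel
        delta = np.zeros(100)
        delta[40] = 50.0
        flagged = np.zeros(100, dtype=bool)
        flagged[40] = True
        meals = call_meals(make_trace(delta, flagged), NoiseModel(0.0, 1.0, 100, 1))
        assert meals == []

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_on_noisy_series(self, seed):
        rng = np.random.default_rng(seed)
        delta = rng.normal(0.1, 1.0, 1440)
        spikes = rng.choice(1440, size=12, replace=False)
        delta[spikes] += rng.uniform(4.0, 25.0, size=12)
        trace = make_trace(delta)
        nm = estimate_noise(delta)
        got = [(m.frame_start, m.frame_end, m.raw_px, m.time_min)
               for m in call_meals(trace, nm)]
        mean, sd, _, _ = noise_filtration_oracle(delta)
        want = [(s, e, pytest.approx(raw), t)
                for s, e, raw, t in meal_selection_oracle(
                    delta, [False] * 1440, mean, sd)]
        assert got == want

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=-5.0, max_value=50.0), min_size=20,
                    max_size=200))
    def test_filtration_oracle_equivalence_property(self, values):
        """Arbitrary finite series: filtration identical to the literal rule."""
        delta = np.asarray(values)
        nm = estimate_noise(delta, min_retained=5)
        mean, sd, n, it = noise_filtration_oracle(delta, min_retained=5)
        assert nm.mean_px == pytest.approx(mean, rel=1e-9, abs=1e-12)
        assert nm.sd_px == pytest.approx(sd, rel=1e-9, abs=1e-12)
        assert (nm.n_retained, nm.n_iterations) == (n, it)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        delta = rng.normal(0.0, 1.0, 1440)
        delta[rng.choice(1440, 20, replace=False)] += rng.uniform(3, 20, 20)
        trace = make_trace(delta)
        nm = estimate_noise(delta)
        counts = [len(call_meals(trace, nm, mult))
                  for mult in (2.5, 3.5, 5.0, 8.0)]
        assert counts == sorted(counts, reverse=True)


class TestCorrectMeals:
    def test_constant_drift_subtracted(self):
        from flyarc.meals import NoiseModel
        delta = np.full(300, 0.2)
        delta[100] = 10.0
        trace = make_trace(delta)
        meals = call_meals(trace, NoiseModel(0.2, 0.5, 300, 1))
        (m,) = correct_meals(meals, delta)
        assert m.corrected_px == pytest.approx(10.0 - 0.2, abs=1e-9)

    def test_zero_drift_unbiased(self):
        rng = np.random.default_rng(3)
        delta = rng.normal(0.0, 0.5, 2000)
        delta[500] = 30.0
        from flyarc.meals import NoiseModel
        meals = call_meals(make_trace(delta), NoiseModel(0.0, 0.5, 2000, 1))
        meals = [m for m in meals if m.frame_start == 500]
        (m,) = correct_meals(meals, delta)
        se = 0.5 / np.sqrt(2000)
        assert abs(m.corrected_px - m.raw_px) <= 2 * se + 0.05

    def test_floor_at_zero(self):
        from flyarc.meals import MealEvent
        delta = np.full(100, 2.0)  # strong drift
        delta[50] = 1.0            # "meal" smaller than the correction
        ev = MealEvent(0, 50, 50, 50, raw_px=1.0)
        (m,) = correct_meals([ev], delta)
        assert m.corrected_px == 0.0

    def test_per_event_mode(self):
        from flyarc.meals import MealEvent
        delta = np.full(200, 0.2)
        delta[100:103] = 5.0
        ev = MealEvent(0, 102, 100, 102, raw_px=15.0)
        (per_frame,) = correct_meals([ev], delta, mode="per_frame")
        (per_event,) = correct_meals([ev], delta, mode="per_event")
        assert per_frame.corrected_px == pytest.approx(15.0 - 0.2 * 3)
        assert per_event.corrected_px == pytest.approx(15.0 - 0.2)

    def test_drift_recovery_on_simulated_day(self):
        """Known volumes + drift: corrected error beats uncorrected bias."""
        rng = np.random.default_rng(8)
        drift = 0.2
        delta = rng.normal(drift, 0.2, 1440)
        meal_frames = np.arange(50, 1440, 140)
        true_px = rng.uniform(2.0, 8.0, len(meal_frames))
        delta[meal_frames] += true_px
        trace = make_trace(delta)
        nm = estimate_noise(delta)
        meals = correct_meals(call_meals(trace, nm), delta)
        got = {m.frame_start: m.corrected_px for m in meals}
        errors = [got[f] - true_px[i]
                  for i, f in enumerate(meal_frames) if f in got]
        assert len(errors) == len(meal_frames)
        assert abs(np.mean(errors)) <= 0.5
        # uncorrected volumes carry the drift bias the correction removes
        raw_errors = [m.raw_px - true_px[i]
                      for i, f in enumerate(meal_frames)
                      for m in meals if m.frame_start == f]
        assert np.mean(raw_errors) > np.mean(errors)


class TestVolumesAndNutrients:
    def test_calibration(self):
        from flyarc.meals import MealEvent
        ev = MealEvent(0, 10, 10, 10, raw_px=3.0, corrected_px=3.0)
        (m,) = to_volume_and_nutrients([ev], 0.01, Diet({}))
        assert m.volume_ul == pytest.approx(0.03)

    def test_sucrose_mass(self):
        from flyarc.meals import MealEvent
        ev = MealEvent(0, 10, 10, 10, raw_px=3.0, corrected_px=3.0)
        (m,) = to_volume_and_nutrients([ev], 0.01, Diet({"sucrose": 5.0}))
        assert m.nutrients_ug["sucrose"] == pytest.approx(1.5)

    def test_salt_supplemented_diet(self):
        from flyarc.meals import MealEvent
        diet = Diet({"sucrose": 2.5, "nacl": 1.0})
        ev = MealEvent(0, 10, 10, 10, raw_px=3.0, corrected_px=3.0)
        (m,) = to_volume_and_nutrients([ev], 0.01, diet)
        assert m.nutrients_ug["sucrose"] == pytest.approx(0.75)
        assert m.nutrients_ug["nacl"] == pytest.approx(0.3)

    def test_negative_calibration_rejected(self):
        with pytest.raises(ParameterError):
            to_volume_and_nutrients([], -0.01, Diet({}))

    def test_negative_diet_rejected(self):
        with pytest.raises(ParameterError):
            Diet({"sucrose": -2.0})
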