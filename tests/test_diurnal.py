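"""Diurnal sugar-exposure simulation and overload metrics."""

import numpy as np
import pytest

from hepgck import (
    Effector,
    KineticParameters,
    MealProfileParams,
    Scenario,
    effective_ki_from_fructose,
    instantaneous_activity,
    integrate_exposure,
    scenario_activity,
    simulate_day,
)
from hepgck.diurnal import ExposureSeries


def one_meal(seed=1, **overrides):
    return MealProfileParams(meal_times=(600.0,), seed=seed, **overrides)


class TestSimulateDay:
    def test_fixed_seed_reproducibility(self):
        a = simulate_day(MealProfileParams(seed=42))
        b = simulate_day(MealProfileParams(seed=42))
        assert np.array_equal(a.plasma_fructose, b.plasma_fructose)
        assert np.array_equal(a.fold_change_vs_fasting, b.fold_change_vs_fasting)

    def test_zero_meals_is_flat_fasting_day(self):
        series = simulate_day(MealProfileParams(meal_times=(), seed=1))
        assert np.allclose(series.plasma_glucose, 5.0)
        assert np.allclose(series.plasma_fructose, 20.0)
        assert np.allclose(series.fold_change_vs_fasting, 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_one_meal_fructose_peak_in_configured_range(self, seed):
        series = simulate_day(one_meal(seed=seed))
        peak = series.plasma_fructose.max()
        assert 300.0 <= peak <= 600.0
        # peak occurs at the meal time
        assert series.timestamps[series.plasma_fructose.argmax()] == 600.0

    def test_concentrations_never_below_fasting(self):
        series = simulate_day(MealProfileParams(seed=3))
        assert (series.plasma_glucose >= 5.0).all()
        assert (series.plasma_fructose >= 20.0).all()

    def test_half_life_of_meal_excursion(self):
        """30 min after the peak the excursion has decayed to half."""
        series = simulate_day(one_meal(seed=2))
        t = series.timestamps
        peak_idx = int(np.argmax(series.plasma_fructose))
        h = series.plasma_fructose[peak_idx] - 20.0
        later = series.plasma_fructose[t == t[peak_idx] + 30.0][0]
        assert later == pytest.approx(20.0 + h / 2, rel=1e-9)
        g_later = series.plasma_glucose[t == t[peak_idx] + 30.0][0]
        assert g_later == pytest.approx(5.0 + 2.0 / 2, rel=1e-9)

    def test_overlapping_meals_sum(self):
        close = MealProfileParams(meal_times=(600.0, 615.0), seed=5)
        series = simulate_day(close)
        single = simulate_day(MealProfileParams(meal_times=(600.0,), seed=5))
        # second excursion adds on top of the first's tail
        t = series.timestamps
        assert series.plasma_glucose[t == 615.0][0] > single.plasma_glucose[t == 615.0][0]

    def test_channel_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ExposureSeries(
                timestamps=np.arange(3.0),
                plasma_glucose=np.ones(2),
                plasma_fructose=np.ones(3),
                effective_ki=np.ones(3),
                relative_activity=np.ones(3),
                fold_change_vs_fasting=np.ones(3),
            )


class TestEffectiveKi:
    def test_zero_fructose_gives_f6p_ki(self, params):
        assert effective_ki_from_fructose(0.0, 10.0, params) == pytest.approx(45.0)

    def test_saturating_fructose_approaches_f1p_ki(self, params):
        ki = effective_ki_from_fructose(1e9, 10.0, params)
        assert ki == pytest.approx(7000.0, rel=1e-3)

    def test_half_occupancy_harmonic_mixture(self, params):
        # theta = 0.5 when hepatocyte fructose equals Kd (plasma = 30 * Kd)
        ki = effective_ki_from_fructose(300.0, 10.0, params)
        assert ki == pytest.approx(2 / (1 / 45 + 1 / 7000), rel=1e-9)

    def test_monotone_nondecreasing_in_fructose(self, params):
        grid = np.linspace(0, 2000, 200)
        ki = effective_ki_from_fructose(grid, 10.0, params)
        assert (np.diff(ki) >= 0).all()

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            effective_ki_from_fructose(-1.0, 10.0, params)
        with pytest.raises(ValueError):
            effective_ki_from_fructose(10.0, 0.0, params)


class TestIntegrateExposure:
    @staticmethod
    def constant_series(fold, minutes, n=101):
        t = np.linspace(0, minutes, n)
        ones = np.ones(n)
        return ExposureSeries(
            timestamps=t,
            plasma_glucose=5 * ones,
            plasma_fructose=20 * ones,
            effective_ki=45 * ones,
            relative_activity=fold * ones,
            fold_change_vs_fasting=fold * ones,
        )

    def test_constant_fold_one_has_zero_auc(self):
        summary = integrate_exposure(self.constant_series(1.0, 1440))
        assert summary.auc_above_fasting == pytest.approx(0.0)
        assert summary.time_averaged_fold_change == pytest.approx(1.0)

    def test_constant_fold_two_closed_form(self):
        summary = integrate_exposure(self.constant_series(2.0, 100))
        assert summary.auc_above_fasting == pytest.approx(100.0)
        assert summary.time_averaged_fold_change == pytest.approx(2.0)
        assert summary.peak_fold_change == pytest.approx(2.0)

    def test_single_point_degenerates_to_zero_auc(self):
        summary = integrate_exposure(self.constant_series(1.7, 0, n=1))
        assert summary.auc_above_fasting == 0.0
        assert summary.peak_fold_change == pytest.approx(1.7)

    def test_peak_at_least_time_average(self):
        series = simulate_day(MealProfileParams(seed=9))
        summary = integrate_exposure(series)
        assert summary.peak_fold_change >= summary.time_averaged_fold_change >= 0

    def test_fructose_strictly_increases_exposure(self):
        """Matched days (same seed): dietary fructose raises activity/AUC."""
        with_fructose = simulate_day(MealProfileParams(seed=11))
        without = simulate_day(MealProfileParams(seed=11, fructose_excursions=False))
        assert np.array_equal(with_fructose.plasma_glucose, without.plasma_glucose)
        assert (with_fructose.relative_activity >= without.relative_activity).all()
        assert (
            integrate_exposure(with_fructose).auc_above_fasting
            > integrate_exposure(without).auc_above_fasting
        )


class TestCrossModuleConsistency:
    def test_saturating_f1p_matches_scenario_engine(self, params):
        """With the effective Ki pinned at the F1P limit, the diurnal
        activity equals the steady-state F1P scenario at the same glucose."""
        for glucose in (7.0, 9.0, 11.0):
            diurnal = instantaneous_activity(glucose, params.ki_f1p, params)
            steady = scenario_activity(
                Scenario(plasma_glucose=glucose, effector=Effector.F1P_100UM, params=params)
            )[0]
            assert diurnal == pytest.approx(steady, rel=1e-12)

    def test_runtime_one_day_at_one_minute_resolution(self):
        import time

        start = time.perf_counter()
        simulate_day(MealProfileParams(seed=1))
        assert time.perf_counter() - start < 5.0
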