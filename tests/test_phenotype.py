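"""Tests for growth-rate fitting, diauxic lag, survival and motility metrics."""

import math

import numpy as np
import pytest

from nutriq import (
    CFUObservation,
    DataError,
    DomainError,
    InsufficientDataError,
    NoRegrowthError,
    NoShiftError,
    ODSeries,
    SelectionError,
    analyze_diauxie,
    auto_window,
    colony_area_foldchange,
    detect_shift,
    diauxic_lag,
    fit_growth_rate,
    gen_diauxic_series,
    gen_od_series,
    survival_percent,
    swarming_fraction,
)


def exact_exponential(lam=0.7, od0=0.05, t_max=3.0, n=7):
    t = np.linspace(0.0, t_max, n)
    return ODSeries(times=t, od600=od0 * np.exp(lam * t))


class TestODSeriesValidation:
    def test_rejects_bad_series(self):
        with pytest.raises(DataError):
            ODSeries(times=[0, 1], od600=[0.1, -0.2])
        with pytest.raises(DataError):
            ODSeries(times=[0, 0], od600=[0.1, 0.2])
        with pytest.raises(DataError):
            ODSeries(times=[0.0], od600=[0.1])


class TestFitGrowthRate:
    def test_exact_exponential_recovered(self):
        fit = fit_growth_rate(exact_exponential(lam=0.7))
        assert fit.growth_rate == pytest.approx(0.7, abs=1e-12)
        assert fit.doubling_time == pytest.approx(math.log(2) / 0.7)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.doubling_time * fit.growth_rate == pytest.approx(math.log(2))

    def test_constant_od_gives_zero_rate(self):
        series = ODSeries(times=np.arange(5.0), od600=np.full(5, 0.3))
        fit = fit_growth_rate(series)
        assert fit.growth_rate == 0.0
        assert math.isinf(fit.doubling_time)
        assert fit.r_squared == 1.0  # perfect fit of a flat line

    def test_window_too_small(self):
        with pytest.raises(InsufficientDataError):
            fit_growth_rate(exact_exponential(n=8), window=(0, 3))
        with pytest.raises(DomainError):
            fit_growth_rate(exact_exponential(n=8), window=(5, 3))

    def test_noisy_recovery_is_close(self):
        t = np.linspace(0, 3, 10)
        series = gen_od_series(0.7, 0.05, t, noise_cv=0.02, seed=17)
        fit = fit_growth_rate(series)
        assert fit.growth_rate == pytest.approx(0.7, rel=0.05)


class TestAutoWindow:
    def test_pure_exponential_uses_full_range(self):
        series = exact_exponential(n=9)
        assert auto_window(series) == (0, 9)

    def test_plateau_excluded_matches_naive_enumeration(self):
        t = np.linspace(0, 6, 25)
        od = np.where(t <= 3, 0.05 * np.exp(0.7 * t), 0.05 * math.exp(2.1))
        series = ODSeries(times=t, od600=od)
        chosen = auto_window(series, min_points=4, r2_min=0.999)
        # independent brute-force enumeration with numpy.polyfit
        best, best_rate = None, -np.inf
        n = len(series)
        for start in range(n - 3):
            for stop in range(start + 4, n + 1):
                slope, intercept = np.polyfit(t[start:stop], np.log(od[start:stop]), 1)
                pred = slope * t[start:stop] + intercept
                resid = np.log(od[start:stop]) - pred
                ss_tot = np.sum((np.log(od[start:stop]) - np.log(od[start:stop]).mean()) ** 2)
                r2 = 1 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
                if r2 >= 0.999 and slope > best_rate + 1e-9:
                    best, best_rate = (start, stop), slope
                elif (
                    r2 >= 0.999
                    and abs(slope - best_rate) <= 1e-9
                    and (stop - start) > (best[1] - best[0])
                ):
                    best = (start, stop)
        assert chosen == best
        # the plateau is excluded: windows end by the break point
        assert chosen[1] <= np.searchsorted(t, 3.0, side="right") + 1
        assert fit_growth_rate(series, chosen).growth_rate == pytest.approx(0.7, rel=1e-6)

    def test_no_qualifying_window(self):
        rng = np.random.default_rng(2)
        series = ODSeries(times=np.arange(8.0), od600=rng.uniform(0.1, 1.0, 8))
        with pytest.raises(SelectionError):
            auto_window(series, r2_min=0.9999)

    def test_parameter_validation(self):
        with pytest.raises(DomainError):
            auto_window(exact_exponential(), min_points=3)
        with pytest.raises(DomainError):
            auto_window(exact_exponential(), r2_min=1.5)


class TestDetectShift:
    def test_piecewise_break_found_within_one_step(self):
        dt = 0.05
        series = gen_diauxic_series(0.7, 0.5, 4.0, 0.3, np.arange(0, 12 + dt / 2, dt))
        t1 = math.log(0.5 / 0.02) / 0.7
        t_shift = detect_shift(series, lambda1=0.7)
        assert abs(t_shift - t1) <= 2 * dt + 1e-9

    def test_single_exponential_never_shifts(self):
        series = exact_exponential(lam=0.7, n=20)
        with pytest.raises(NoShiftError):
            detect_shift(series, lambda1=0.7)
        with pytest.raises(NoShiftError):
            detect_shift(series, lambda1=0.7, theta=0.99)

    def test_theta_domain(self):
        series = exact_exponential(n=10)
        with pytest.raises(DomainError):
            detect_shift(series, lambda1=0.7, theta=1.5)


class TestDiauxicLag:
    def grid(self, t_max=14.0, dt=0.05):
        return np.arange(0.0, t_max + dt / 2, dt)

    def test_instant_resumption_has_zero_lag(self):
        series = gen_diauxic_series(0.7, 0.5, 0.0, 0.3, self.grid())
        t1 = math.log(0.5 / 0.02) / 0.7
        window = (int(np.searchsorted(series.times, t1)) + 2, len(series))
        result = diauxic_lag(series, t1, window, lambda1=0.7)
        assert result.lag == pytest.approx(0.0, abs=1e-9)

    def test_known_lag_recovered_exactly_given_true_shift_time(self):
        # put the phase-1 break exactly on the grid so the OD at the shift
        # time is an observed (not interpolated) value
        t1 = 4.6
        od0 = 0.5 / math.exp(0.7 * t1)
        series = gen_diauxic_series(0.7, 0.5, 2.0, 0.3, self.grid(), od0=od0)
        start = int(np.searchsorted(series.times, t1 + 2.0)) + 2
        result = diauxic_lag(series, t1, (start, len(series)), lambda1=0.7)
        assert result.lag == pytest.approx(2.0, abs=1e-6)
        assert result.lambda2 == pytest.approx(0.3, abs=1e-9)

    def test_independent_of_second_window_choice(self):
        series = gen_diauxic_series(0.7, 0.5, 1.5, 0.3, self.grid())
        t1 = math.log(0.5 / 0.02) / 0.7
        base = int(np.searchsorted(series.times, t1 + 1.5)) + 2
        lags = [
            diauxic_lag(series, t1, (base + off, base + off + k), lambda1=0.7).lag
            for off, k in [(0, 40), (10, 25), (30, 60)]
        ]
        assert max(lags) - min(lags) < 1e-9

    def test_flat_second_phase_is_no_regrowth(self):
        series = gen_diauxic_series(0.7, 0.5, 1.0, 0.0, self.grid())
        t1 = math.log(0.5 / 0.02) / 0.7
        start = int(np.searchsorted(series.times, t1 + 1.0)) + 2
        with pytest.raises(NoRegrowthError):
            diauxic_lag(series, t1, (start, len(series)), lambda1=0.7)

    def test_window_must_follow_shift(self):
        series = gen_diauxic_series(0.7, 0.5, 1.0, 0.3, self.grid())
        with pytest.raises(DomainError):
            diauxic_lag(series, 6.0, (0, 10), lambda1=0.7)


class TestAnalyzeDiauxie:
    @pytest.mark.parametrize("lag_true", [0.0, 1.0, 2.0, 4.0])
    def test_pipeline_recovers_lag_within_one_grid_step(self, lag_true):
        dt = 0.05
        t1 = 4.6  # ln(od_shift/od0)/λ1 lands on the grid
        od0 = 0.5 / math.exp(0.7 * t1)
        series = gen_diauxic_series(
            0.7, 0.5, lag_true, 0.3, np.arange(0, 14 + dt / 2, dt), od0=od0
        )
        result = analyze_diauxie(series)
        assert result.lag == pytest.approx(lag_true, abs=dt + 1e-9)
        assert result.lambda1 == pytest.approx(0.7, abs=1e-6)
        assert result.lambda2 == pytest.approx(0.3, abs=1e-3)

    def test_no_shift_in_single_exponential(self):
        t = np.linspace(0, 3, 40)
        series = gen_od_series(0.7, 0.05, t)
        with pytest.raises(NoShiftError):
            analyze_diauxie(series)


class TestSurvival:
    def test_hand_computed_worked_example(self):
        initial = CFUObservation(200, 1e5, 0.1)  # 2.0e8 CFU/mL
        final = CFUObservation(40, 2e4, 0.1)  # 8.0e6 CFU/mL
        assert survival_percent(initial, final) == pytest.approx(4.0)

    def test_identity_and_extinction(self):
        obs = CFUObservation(150, 1e5, 0.1)
        assert survival_percent(obs, obs) == pytest.approx(100.0)
        assert survival_percent(obs, CFUObservation(0, 1e5, 0.1)) == 0.0

    def test_dilution_invariance(self):
        initial = CFUObservation(200, 1e5, 0.1)
        final_a = CFUObservation(40, 2e4, 0.1)
        final_b = CFUObservation(80, 1e4, 0.1)  # same density, other dilution
        assert survival_percent(initial, final_a) == pytest.approx(
            survival_percent(initial, final_b)
        )

    def test_replicates_averaged_as_densities(self):
        initial = [CFUObservation(190, 1e5, 0.1), CFUObservation(210, 1e5, 0.1)]
        final = [CFUObservation(10, 1e5, 0.1), CFUObservation(30, 1e5, 0.1)]
        assert survival_percent(initial, final) == pytest.approx(10.0)

    def test_zero_initial_density_rejected(self):
        with pytest.raises(DomainError):
            survival_percent(CFUObservation(0, 1e5, 0.1), CFUObservation(5, 1e5, 0.1))

    def test_observation_validation(self):
        with pytest.raises(DomainError):
            CFUObservation(-1, 1e5, 0.1)
        with pytest.raises(DomainError):
            CFUObservation(10, 0.5, 0.1)
        with pytest.raises(DomainError):
            CFUObservation(10, 1e5, 0.0)


class TestMotilityMetrics:
    def test_fold_changes(self):
        mean, sd = colony_area_foldchange([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (mean, sd) == (pytest.approx(1.0), pytest.approx(0.0))
        mean, sd = colony_area_foldchange([1.0, 1.0], [2.0, 4.0])
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(math.sqrt(2.0))

    def test_fold_change_validation(self):
        with pytest.raises(DataError):
            colony_area_foldchange([1.0, 2.0], [1.0])
        with pytest.raises(DataError):
            colony_area_foldchange([1.0, 0.0], [1.0, 2.0])

    @pytest.mark.parametrize(
        "areas,threshold,expected",
        [([1.0] * 24, 5.0, 0.0), ([1.0] * 12 + [9.0] * 12, 5.0, 0.5), ([9.0] * 6, 5.0, 1.0)],
    )
    def test_swarming_fraction_by_threshold(self, areas, threshold, expected):
        assert swarming_fraction(areas, threshold) == pytest.approx(expected)

    def test_swarming_fraction_from_flags_and_empty(self):
        assert swarming_fraction([True, False, True, False]) == 0.5
        with pytest.raises(DomainError):
            swarming_fraction([])
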