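"""Synthetic-data generator: schedules, ground-truth dynamics, missingness."""

import numpy as np
import pandas as pd
import pytest

from affectinertia.design import (
    ModerationEffect,
    StudyDesign,
    TruthParams,
    negative_affect_truth,
    signed_power,
)
from affectinertia.preprocess import construct_lags
from affectinertia.schedule import ScheduleError, build_beep_schedule, schedule_wake_times
from affectinertia.simulate import (
    EmaSimulator,
    NA_ITEMS,
    apply_missingness,
    simulate_affect,
    simulate_covariates,
)


class TestBeepSchedule:
    def test_first_beep_at_least_55_min_after_waking(self):
        design = StudyDesign()
        rng = np.random.default_rng(0)
        times = build_beep_schedule(design, 6.0, rng, n_days=50)
        assert (times[:, 0] >= 6.0 + 55 / 60 - 1e-12).all()
        # strictly increasing within day, respecting the 2-3 h range
        gaps = np.diff(times, axis=1)
        assert (gaps >= 2.0).all() and (gaps <= 3.0).all()

    def test_degenerate_gap_range_gives_constant_gaps(self):
        design = StudyDesign(beep_gap_range=(2.6, 2.6))
        rng = np.random.default_rng(0)
        times = build_beep_schedule(design, 7.0, rng, n_days=5)
        assert np.allclose(np.diff(times, axis=1), 2.6)

    def test_mean_gaps_match_design_targets(self):
        # Monte-Carlo check against direct averaging of the generated gaps
        design = StudyDesign()
        rng = np.random.default_rng(1)
        wakes = schedule_wake_times(design)
        within, overnight = [], []
        for wake in wakes:
            times = build_beep_schedule(design, wake, rng, n_days=450)
            within.append(np.diff(times, axis=1).ravel())
            overnight.append(24.0 + times[1:, 0] - times[:-1, -1])
        within = np.concatenate(within)
        overnight = np.concatenate(overnight)
        assert 2.5 <= within.mean() <= 2.7
        assert 10.0 <= overnight.min() and overnight.max() <= 17.0
        assert abs(overnight.mean() - 13.7) < 0.3

    def test_wake_time_outside_range_raises(self):
        with pytest.raises(ScheduleError):
            build_beep_schedule(StudyDesign(), 3.0, np.random.default_rng(0))

    def test_seven_schedules_quantise_wake_range(self):
        wakes = schedule_wake_times(StudyDesign())
        assert len(wakes) == 7
        assert wakes[0] == 5.0 and wakes[-1] == 11.0


class TestSimulateAffect:
    def test_pure_fixed_effects_are_deterministic(self):
        # no heterogeneity, no noise, no lag terms: every beep equals
        # gamma00 + gamma10 * overnight
        truth = TruthParams(
            gamma10=0.5, gamma20=0.0, gamma30=0.0,
            sd_u0=0, sd_u1=0, sd_u2=0, sd_u3=0, sd_wave=0, sd_day=0, sd_resid=0,
        )
        design = StudyDesign(n_persons=3, n_waves=1, n_days_per_wave=4, compliance=1.0)
        data = simulate_affect(design, truth, seed=0)
        beeps = data.beeps
        first_of_day = beeps["beep"] == 1
        overnight = first_of_day & (beeps["day"] > 1)
        assert np.allclose(beeps.loc[overnight, "na"], truth.gamma00 + 0.5)
        assert np.allclose(beeps.loc[~overnight & ~((beeps.day == 1) & first_of_day), "na"],
                           truth.gamma00)

    def test_seeded_determinism(self):
        design = StudyDesign(n_persons=5, n_waves=2, n_days_per_wave=3)
        truth = negative_affect_truth()
        a = EmaSimulator(design, truth).simulate(seed=42)
        b = EmaSimulator(design, truth).simulate(seed=42)
        pd.testing.assert_frame_equal(a.beeps, b.beeps)
        pd.testing.assert_frame_equal(a.mornings, b.mornings)
        pd.testing.assert_frame_equal(a.persons, b.persons)

    def test_stop_regime_kills_overnight_autocorrelation(self):
        truth = negative_affect_truth(
            regime="stop", sd_u0=0, sd_u1=0, sd_u2=0, sd_u3=0, sd_wave=0, sd_day=0
        )
        design = StudyDesign(n_persons=300, n_waves=1, n_days_per_wave=10, compliance=1.0)
        lagged = construct_lags(simulate_affect(design, truth, seed=3).beeps)
        on = lagged[(lagged.overnight == 1) & lagged.eligible]
        r = np.corrcoef(on["na_lag"], on["na"])[0, 1]
        # ~2700 pairs: a true zero correlation stays within 3 MC standard errors
        assert abs(r) < 0.06

    @pytest.mark.parametrize("regime,gamma20", [("continue", 0.7), ("pause", 0.7)])
    def test_regime_implied_overnight_slope(self, regime, gamma20):
        # with no person heterogeneity the pooled overnight OLS slope must
        # match the regime-implied extrapolation of the within-day AR
        design = StudyDesign(n_persons=200, n_waves=1, n_days_per_wave=10, compliance=1.0)
        truth = negative_affect_truth(
            gamma00=3.0, gamma20=gamma20, regime=regime,
            sd_u0=0, sd_u1=0, sd_u2=0, sd_u3=0, sd_wave=0, sd_day=0,
        )
        implied = truth.implied_gamma30(design)
        lagged = construct_lags(simulate_affect(design, truth, seed=4).beeps)
        on = lagged[(lagged.overnight == 1) & lagged.eligible]
        slope = np.polyfit(on["na_lag"], on["na"], 1)[0]
        assert abs(slope - implied) < 0.03

    def test_within_day_slope_recovers_generating_coefficient(self):
        # within-person least squares on the generated data: the pooled
        # within-day lag-1 slope approaches gamma20 (small downward
        # Nickell-type bias from person demeaning)
        design = StudyDesign(n_persons=200, n_waves=1, n_days_per_wave=14, compliance=1.0)
        # wave/day intercept deviations off: a plain least-squares oracle
        # has no terms for them, and their presence in both the lag and
        # the outcome would otherwise inflate the slope
        truth = negative_affect_truth(sd_wave=0.0, sd_day=0.0)
        lagged = construct_lags(simulate_affect(design, truth, seed=5).beeps)
        d = lagged[lagged.eligible & (lagged.withinday == 1)]
        pids, pidx = np.unique(d.person_id, return_inverse=True)
        P = np.zeros((len(d), len(pids)))
        P[np.arange(len(d)), pidx] = 1
        X = np.column_stack([P, d.na_lag])
        slope = np.linalg.lstsq(X, d.na.to_numpy(), rcond=None)[0][-1]
        assert 0.22 <= slope <= 0.32

    def test_stationary_mean_of_long_run(self):
        # single person, one very long day: running mean converges to the
        # AR(1) stationary mean implied by the intercept
        design = StudyDesign(
            n_persons=1, n_waves=1, n_days_per_wave=1, beeps_per_day=5000,
            latest_beep_after_wake=1e9, compliance=1.0,
        )
        truth = TruthParams(
            gamma00=2.0, gamma20=0.5, gamma30=0.0,
            sd_u0=0, sd_u1=0, sd_u2=0, sd_u3=0, sd_wave=0, sd_day=0, sd_resid=1.0,
        )
        beeps = simulate_affect(design, truth, seed=6).beeps
        assert abs(beeps["na"].mean() - 2.0 / (1 - 0.5)) < 0.15

    def test_item_composite_round_trip(self):
        truth = negative_affect_truth(gamma00=4.0, sd_u0=0.3, sd_resid=0.5,
                                      item_error_sd=0.0)
        design = StudyDesign(n_persons=10, n_waves=1, n_days_per_wave=5, compliance=1.0)
        beeps = simulate_affect(design, truth, seed=7).beeps
        inside = beeps[(beeps.na >= 0) & (beeps.na <= 10)]
        recovered = inside[NA_ITEMS].mean(axis=1) / 10.0
        assert np.allclose(recovered, inside["na"])

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            TruthParams(sd_u0=-1)
        bad = np.array([[1, 2, 0, 0], [2, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]])
        with pytest.raises(ValueError):
            TruthParams(re_correlations=bad)
        with pytest.raises(ValueError):
            TruthParams(regime="hibernate")
        with pytest.raises(ValueError):
            StudyDesign(compliance=0.0)

    def test_regime_stop_forces_zero_overnight_coefficient(self):
        truth = negative_affect_truth(regime="stop")
        assert truth.implied_gamma30(StudyDesign()) == 0.0
        cont = negative_affect_truth(regime="continue")
        ratio = 13.7 / 2.6
        assert cont.implied_gamma30(StudyDesign()) == pytest.approx(
            signed_power(cont.gamma20, ratio)
        )


class TestMissingness:
    def test_full_compliance_is_identity(self, na_truth):
        design = StudyDesign(n_persons=5, n_waves=1, n_days_per_wave=4)
        data = simulate_affect(design, na_truth, seed=8)
        out = apply_missingness(data, 1.0, 0)
        pd.testing.assert_frame_equal(out.beeps, data.beeps)

    def test_retained_fraction_matches_compliance(self, na_truth):
        design = StudyDesign(n_persons=150, n_waves=3, n_days_per_wave=14)
        data = simulate_affect(design, na_truth, seed=9)
        out = apply_missingness(data, 0.8, 1)
        frac = len(out.beeps) / len(data.beeps)
        assert abs(frac - 0.8) < 0.01

    def test_seeded_missingness_is_deterministic(self, na_truth):
        design = StudyDesign(n_persons=10, n_waves=1, n_days_per_wave=5)
        data = simulate_affect(design, na_truth, seed=10)
        a = apply_missingness(data, 0.8, 123)
        b = apply_missingness(data, 0.8, 123)
        pd.testing.assert_frame_equal(a.beeps, b.beeps)

    def test_invalid_compliance_raises(self, na_truth):
        design = StudyDesign(n_persons=2, n_waves=1, n_days_per_wave=2)
        data = simulate_affect(design, na_truth, seed=0)
        with pytest.raises(ValueError):
            apply_missingness(data, 1.5, 0)


class TestSimulateCovariates:
    def test_null_moderation_matches_plain_generation(self, na_truth):
        design = StudyDesign(n_persons=8, n_waves=1, n_days_per_wave=5)
        plain = simulate_affect(design, na_truth, seed=12)
        null = simulate_covariates(
            design, negative_affect_truth(moderation_effects={}), seed=12
        )
        pd.testing.assert_frame_equal(plain.beeps, null.beeps)

    def test_unknown_covariate_name_raises(self):
        truth = negative_affect_truth(
            moderation_effects={"caffeine": ModerationEffect(on_within_ar=0.1)}
        )
        with pytest.raises(ValueError, match="caffeine"):
            simulate_covariates(StudyDesign(n_persons=2), truth, seed=0)

    def test_stressor_rate_matches_target(self, na_truth):
        design = StudyDesign(n_persons=300, n_waves=1, n_days_per_wave=14)
        beeps = simulate_affect(design, na_truth, seed=13).beeps
        assert abs(beeps["stressor"].mean() - 0.16) < 0.02
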