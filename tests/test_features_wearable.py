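import math

import numpy as np
import pandas as pd
import pytest

from moodstab.features import (
    fit_cosinor,
    heart_rate_features,
    nightly_cosinor_fits,
    segment_nights,
    sleep_features,
    step_features,
)
from moodstab.features.wearable import CosinorFit

from conftest import T, sleep_night_minutes, wristband_stream

PERIOD = (T("2024-03-04"), T("2024-03-18"))


class TestSegmentNights:
    def test_continuous_night(self):
        minutes = sleep_night_minutes("2024-03-05 23:00", 480)
        nights = segment_nights(wristband_stream(minutes), PERIOD)
        assert len(nights) == 1
        n = nights[0]
        assert n.total_min == 480
        assert n.valid
        assert n.onset == T("2024-03-05 23:00")
        assert n.wake == T("2024-03-06 07:00")
        assert n.date == T("2024-03-05")

    def test_bridge_merges_short_gap(self):
        minutes = (sleep_night_minutes("2024-03-05 23:00", 180)
                   + sleep_night_minutes("2024-03-06 02:30", 270))
        nights = segment_nights(wristband_stream(minutes), PERIOD, bridge_min=60)
        assert len(nights) == 1
        assert nights[0].total_min == 450  # bridged gap minutes are not sleep

    def test_long_gap_splits(self):
        minutes = (sleep_night_minutes("2024-03-05 22:00", 200)
                   + sleep_night_minutes("2024-03-06 03:00", 240))
        nights = segment_nights(wristband_stream(minutes), PERIOD, bridge_min=60)
        assert len(nights) == 2

    def test_short_nap_invalid(self):
        minutes = sleep_night_minutes("2024-03-05 14:00", 90)
        nights = segment_nights(wristband_stream(minutes), PERIOD)
        assert len(nights) == 1
        assert not nights[0].valid
        feats = sleep_features(nights)
        assert feats["sleep.n_nights"] == 0
        assert math.isnan(feats["sleep.total_min_mean"])

    def test_light_deep_conservation(self):
        minutes = sleep_night_minutes("2024-03-05 23:00", 480, deep_every=3)
        nights = segment_nights(wristband_stream(minutes), PERIOD)
        n = nights[0]
        assert n.light_min + n.deep_min == n.total_min == 480
        assert n.deep_min == 160


class TestSleepFeatures:
    def _nights(self, specs):
        minutes = []
        for start, light, deep in specs:
            minutes += sleep_night_minutes(start, light + deep, n_deep=deep)
        return segment_nights(wristband_stream(minutes), PERIOD)

    def test_constant_nights(self):
        specs = [(f"2024-03-{d:02d} 23:00", 300, 180) for d in (5, 6, 7)]
        feats = sleep_features(self._nights(specs))
        assert feats["sleep.deep_ratio"] == pytest.approx(0.375)
        assert feats["sleep.light_ratio"] == pytest.approx(0.625)
        assert feats["sleep.total_min_sd"] == pytest.approx(0.0)
        assert feats["sleep.total_min_mean"] == pytest.approx(480.0)

    def test_single_night_sd_nan(self):
        feats = sleep_features(self._nights([("2024-03-05 23:00", 300, 0)]))
        assert math.isnan(feats["sleep.total_min_sd"])
        assert feats["sleep.total_min_mean"] == pytest.approx(300.0)

    def test_onset_circular_mean_across_midnight(self):
        nights = self._nights([("2024-03-05 23:30", 300, 0),
                               ("2024-03-07 00:30", 300, 0)])
        feats = sleep_features(nights)
        assert feats["sleep.onset_circmean"] == pytest.approx(0.0, abs=1e-6)


class TestStepFeatures:
    def test_constant_days(self):
        minutes = []
        for d in (5, 6, 7):
            day = f"2024-03-{d:02d}"
            for m in range(100):
                minutes.append((T(f"{day} 09:00") + pd.Timedelta(minutes=m),
                                "activity", 10, None))
        out = step_features(wristband_stream(minutes), PERIOD)
        assert out["steps.daily_mean"] == pytest.approx(1000.0)
        assert out["steps.daily_sd"] == pytest.approx(0.0)
        assert out["steps.total"] == pytest.approx(3000.0)

    def test_steps_in_single_bin(self):
        minutes = [(T("2024-03-05 09:30") + pd.Timedelta(minutes=m), "activity", 5, None)
                   for m in range(60)]
        out = step_features(wristband_stream(minutes), PERIOD)
        assert out["steps.bin3_daily_mean"] == pytest.approx(300.0)  # [9,12)
        for k in (0, 1, 2, 4, 5, 6, 7):
            assert out[f"steps.bin{k}_daily_mean"] == pytest.approx(0.0)

    def test_empty_period(self):
        out = step_features(wristband_stream([]), PERIOD)
        assert out["steps.total"] == 0.0
        assert math.isnan(out["steps.daily_mean"])

    def test_not_worn_steps_excluded(self):
        minutes = [("2024-03-05 10:00", "activity", 7, None),
                   ("2024-03-05 10:01", "not_worn", 0, None)]
        out = step_features(wristband_stream(minutes), PERIOD)
        assert out["steps.total"] == pytest.approx(7.0)


def _cosinor_signal(hours, mesor, amp, acro):
    return mesor + amp * np.cos(2 * np.pi * (np.asarray(hours) - acro) / 24.0)


class TestCosinor:
    def test_noiseless_recovery(self):
        hours = np.linspace(23.0, 31.0, 480) % 24.0
        y = _cosinor_signal(hours, 60.0, 10.0, 4.0)
        fit = fit_cosinor(hours, y)
        assert fit.mesor == pytest.approx(60.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(10.0, abs=1e-6)
        assert fit.acrophase == pytest.approx(4.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_flat_signal_conventions(self):
        hours = np.linspace(0, 8, 100)
        fit = fit_cosinor(hours, np.full(100, 55.0))
        assert fit.mesor == pytest.approx(55.0)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert fit.acrophase == 0.0
        assert fit.r2 == 0.0

    def test_too_few_points(self):
        assert fit_cosinor([1, 2, 3], [60, 61, 62]) is None

    def test_noisy_amplitude_within_monte_carlo_tolerance(self):
        """Mean amplitude estimate over 100 replicates lies within 3 standard
        errors of the truth; SE derives from the linear-model variance
        Var(amp_hat) ~ 2*sigma^2/n for a full-cycle design."""
        rng = np.random.default_rng(2024)
        sigma, n, reps, amp_true = 2.0, 400, 100, 10.0
        estimates = []
        for _ in range(reps):
            hours = rng.uniform(0, 24, size=n)
            y = _cosinor_signal(hours, 60.0, amp_true, 4.0) + rng.normal(0, sigma, n)
            estimates.append(fit_cosinor(hours, y).amplitude)
        se_single = sigma * math.sqrt(2.0 / n)
        se_mean = se_single / math.sqrt(reps)
        assert abs(np.mean(estimates) - amp_true) < 3 * se_mean

    def test_linearized_sse_beats_grid_oracle(self):
        """The closed-form least-squares fit is at least as good as a
        brute-force (mesor, amplitude, acrophase) grid search."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(20, 60))
            hours = rng.uniform(0, 24, size=n)
            truth = (rng.uniform(50, 70), rng.uniform(2, 12), rng.uniform(0, 24))
            y = _cosinor_signal(hours, *truth) + rng.normal(0, 1.5, n)
            fit = fit_cosinor(hours, y)
            w = 2 * np.pi / 24.0

            def sse(m, a, phi):
                pred = m + a * np.cos(w * (hours - phi))
                return float(((y - pred) ** 2).sum())

            fit_sse = sse(fit.mesor, fit.amplitude, fit.acrophase)
            grid_best = min(
                sse(m, a, phi)
                for m in np.linspace(y.min(), y.max(), 25)
                for a in np.linspace(0, (y.max() - y.min()), 20)
                for phi in np.linspace(0, 24, 49)
            )
            assert fit_sse <= grid_best + 1e-6

    def test_bias_vanishes_with_noise(self):
        """Estimator bias goes to zero as sigma -> 0 over simulated nights."""
        rng = np.random.default_rng(5)
        hours = rng.uniform(22, 30, size=300) % 24
        truth = (62.0, 8.0, 3.5)
        biases = []
        for sigma in (4.0, 1.0, 0.1, 0.0):
            amps = []
            for _ in range(20):
                y = _cosinor_signal(hours, *truth) + rng.normal(0, sigma, 300)
                amps.append(fit_cosinor(hours, y).amplitude)
            biases.append(abs(np.mean(amps) - truth[1]))
        assert biases[-1] < 1e-9
        assert biases[-1] <= biases[0] + 1e-9

    def test_invalid_fit_fields_rejected(self):
        with pytest.raises(ValueError):
            CosinorFit(mesor=60, amplitude=-1, acrophase=0, r2=0.5, n_points=10)
        with pytest.raises(ValueError):
            CosinorFit(mesor=60, amplitude=1, acrophase=0, r2=1.5, n_points=10)


class TestHeartRateFeatures:
    def test_identical_fits_sd_zero(self):
        fits = [CosinorFit(60, 8, 4, 0.9, 100)] * 3
        out = heart_rate_features(fits)
        assert out["hr.mesor_sd"] == pytest.approx(0.0)
        assert out["hr.amplitude_mean"] == pytest.approx(8.0)
        assert out["hr.acrophase_circsd"] == pytest.approx(0.0, abs=1e-6)

    def test_acrophase_circular_mean(self):
        fits = [CosinorFit(60, 8, 23.0, 0.9, 100), CosinorFit(60, 8, 1.0, 0.9, 100)]
        out = heart_rate_features(fits)
        assert out["hr.acrophase_circmean"] == pytest.approx(0.0, abs=1e-9)

    def test_single_night_sd_nan(self):
        out = heart_rate_features([CosinorFit(60, 8, 4, 0.9, 100)])
        assert math.isnan(out["hr.mesor_sd"])
        assert math.isnan(out["hr.acrophase_circsd"])

    def test_no_fits_nan(self):
        out = heart_rate_features([])
        assert out["hr.n_fits"] == 0
        assert math.isnan(out["hr.mesor_mean"])

    def test_nightly_fits_from_minutes(self):
        minutes = sleep_night_minutes(
            "2024-03-05 23:00", 480,
            hr_fn=lambda h: 60 + 10 * math.cos(2 * math.pi * (h - 4) / 24))
        nights = segment_nights(wristband_stream(minutes), PERIOD)
        fits = nightly_cosinor_fits(nights)
        assert len(fits) == 1
        assert fits[0].amplitude == pytest.approx(10.0, abs=1e-6)
        assert fits[0].acrophase == pytest.approx(4.0, abs=1e-6)
        assert fits[0].r2 == pytest.approx(1.0, abs=1e-9)
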