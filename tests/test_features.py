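"""Feature-extraction oracles and invariants."""

import numpy as np
import pandas as pd
import pytest

from relapsekit import features as feat
from relapsekit.preprocess import CleanDayRecord

#: hand-computed oracle for NN = [800, 810, 790, 805, 795] (n-1 divisor):
#: mean 800; var = 250/4 = 62.5 -> SDNN 7.9057; squared diffs
#: {100, 400, 225, 100} -> mean 206.25 -> RMSSD 14.3614;
#: SD1 = RMSSD/sqrt(2) = 10.1551; SD2 = sqrt(2*62.5 - SD1^2) = 4.6771
TOY_NN = np.array([800.0, 810.0, 790.0, 805.0, 795.0])
TOY = {"mean": 800.0, "sdnn": 7.9057, "rmssd": 14.3614,
       "sd1": 10.1551, "sd2": 4.6771}


class TestTimeDomain:
    def test_printed_toy_series(self):
        """The frozen hand computation on the 5-beat toy series."""
        mean = TOY_NN.mean()
        sdnn = TOY_NN.std(ddof=1)
        rmssd = np.sqrt(np.mean(np.diff(TOY_NN) ** 2))
        assert mean == pytest.approx(TOY["mean"])
        assert sdnn == pytest.approx(TOY["sdnn"], abs=1e-4)
        assert rmssd == pytest.approx(TOY["rmssd"], abs=1e-4)
        sd1 = rmssd / np.sqrt(2)
        sd2 = np.sqrt(2 * sdnn ** 2 - sd1 ** 2)
        assert sd1 == pytest.approx(TOY["sd1"], abs=1e-4)
        assert sd2 == pytest.approx(TOY["sd2"], abs=1e-4)

    def test_hrv_time_matches_hand_computation_on_padded_series(self):
        nn = np.concatenate([TOY_NN, TOY_NN])  # >= 10 values
        mean, sdnn, rmssd, ok = feat.hrv_time(nn)
        assert ok
        assert mean == pytest.approx(nn.mean())
        assert sdnn == pytest.approx(nn.std(ddof=1))
        assert rmssd == pytest.approx(np.sqrt(np.mean(np.diff(nn) ** 2)))

    def test_constant_series_zero_dispersion(self):
        _, sdnn, rmssd, ok = feat.hrv_time(np.full(20, 800.0))
        assert ok and sdnn == 0 and rmssd == 0
        sd1, sd2, _ = feat.poincare(np.full(20, 800.0))
        assert sd1 == 0 and sd2 == 0

    def test_alternating_series_rmssd_10(self):
        nn = np.tile([800.0, 810.0], 10)
        _, _, rmssd, _ = feat.hrv_time(nn)
        assert rmssd == pytest.approx(10.0)

    def test_below_minimum_count_invalid(self):
        assert feat.hrv_time(np.full(9, 800.0))[-1] is False

    def test_sd_identity_on_random_series(self, rng):
        for _ in range(100):
            nn = 800 + 50 * rng.standard_normal(rng.integers(10, 300))
            _, sdnn, rmssd, _ = feat.hrv_time(nn)
            sd1, sd2, _ = feat.poincare(nn)
            assert sd1 == pytest.approx(rmssd / np.sqrt(2), rel=1e-9)
            assert sd1 ** 2 + sd2 ** 2 == pytest.approx(2 * sdnn ** 2, rel=1e-6)

    def test_shuffle_sensitivity(self, rng):
        nn = 800 + 50 * rng.standard_normal(64)
        base = feat.hrv_time(nn)
        shuffled = feat.hrv_time(rng.permutation(nn))
        assert shuffled[0] == pytest.approx(base[0])  # mean order-free
        assert shuffled[1] == pytest.approx(base[1])  # sdnn order-free
        assert shuffled[2] != pytest.approx(base[2])  # rmssd order-sensitive


class TestSimpleFeatures:
    def test_three_four_five_norm(self):
        lin = np.tile([3.0, 4.0, 0.0], (60, 1))
        ang = np.zeros((60, 3))
        f1, f2, ok = feat.accel_features(lin, ang)
        assert ok and f1 == pytest.approx(5.0) and f2 == 0.0

    def test_hr_features_mean_max_min(self):
        f3, f4, f5, ok = feat.hr_features(np.array([60.0, 80.0, 70.0]))
        assert ok and (f3, f4, f5) == (70.0, 80.0, 60.0)

    def test_hr_features_empty_invalid(self):
        assert feat.hr_features(np.array([]))[-1] is False


class TestSpectral:
    def _tachogram(self, freq, amp, fs=4.0, seconds=300):
        t = np.arange(int(seconds * fs)) / fs
        return 800 + amp * np.sin(2 * np.pi * freq * t)

    def test_hf_sinusoid_lands_in_hf_band(self):
        lf, hf, ok = feat.hrv_freq(self._tachogram(0.25, 30))
        assert ok and hf / (lf + hf) >= 0.95

    def test_lf_sinusoid_lands_in_lf_band(self):
        lf, hf, ok = feat.hrv_freq(self._tachogram(0.10, 30))
        assert ok and lf / (lf + hf) >= 0.95

    def test_sinusoid_power_matches_parseval(self):
        amp = 40.0
        _, hf, ok = feat.hrv_freq(self._tachogram(0.25, amp))
        assert ok
        assert hf == pytest.approx(amp ** 2 / 2, rel=0.10)

    def test_too_short_invalid(self):
        assert feat.hrv_freq(self._tachogram(0.25, 30, seconds=60))[-1] is False


def _synthetic_clean_day(rng, fs_hr=1.0, fs_accel=2.0):
    n_hr = int(86400 * fs_hr)
    n_ac = int(86400 * fs_accel)
    return CleanDayRecord(
        patient_id="x", day_index=0,
        accel_lin=rng.uniform(0, 2, (n_ac, 3)),
        accel_ang=rng.uniform(0, 1, (n_ac, 3)),
        hr=rng.uniform(50, 110, n_hr),
        nn=rng.uniform(600, 1000, n_hr),
        sleep_epochs=[(0.0, 6 * 3600.0)],
        relapse_label=0, fs_accel=fs_accel, fs_hr=fs_hr,
        discard_intervals=[],
    )


class TestFeaturizeDay:
    def test_full_day_has_288_valid_slots(self, rng):
        df = feat.featurize_day(_synthetic_clean_day(rng))
        assert len(df) == 288
        assert df.valid.all()
        assert (np.diff(df.interval_start) == 300).all()

    def test_discarded_span_invalidates_48_slots(self, rng):
        clean = _synthetic_clean_day(rng)
        # 4 h discarded span; the missing run sits strictly inside it so the
        # tachogram-resampling guard band stays within the flagged slots
        clean.discard_intervals = [(8 * 3600.0, 12 * 3600.0)]
        lo = int(8 * 3600 * clean.fs_hr) + 1
        hi = int(12 * 3600 * clean.fs_hr) - 1
        clean.hr[lo:hi] = np.nan
        clean.nn[lo:hi] = np.nan
        df = feat.featurize_day(clean)
        assert (~df.valid).sum() == 48

    def test_sleep_flag_follows_slot_midpoint(self, rng):
        df = feat.featurize_day(_synthetic_clean_day(rng))
        assert (df.loc[df.interval_start < 6 * 3600, "sleep_flag"] == "sleep").all()
        assert (df.loc[df.interval_start >= 6 * 3600, "sleep_flag"] == "awake").all()

    def test_agrees_with_per_slot_brute_force(self, rng):
        """Vectorized extraction equals direct per-slot formula evaluation."""
        clean = _synthetic_clean_day(rng)
        df = feat.featurize_day(clean)
        per_hr = int(300 * clean.fs_hr)
        per_ac = int(300 * clean.fs_accel)
        slots = rng.choice(288, size=100, replace=False)
        for i in slots:
            row = df.iloc[int(i)]
            nn = clean.nn[i * per_hr:(i + 1) * per_hr]
            hr = clean.hr[i * per_hr:(i + 1) * per_hr]
            lin = clean.accel_lin[i * per_ac:(i + 1) * per_ac]
            ang = clean.accel_ang[i * per_ac:(i + 1) * per_ac]
            f1, f2, _ = feat.accel_features(lin, ang)
            f3, f4, f5, _ = feat.hr_features(hr)
            f6, f7, f8, _ = feat.hrv_time(nn)
            sd1, sd2, _ = feat.poincare(nn)
            got = row[feat.FEATURE_COLUMNS].to_numpy(dtype=float)
            want = [f1, f2, f3, f4, f5, f6, f7, f8, row.lf_power, row.hf_power,
                    sd1, sd2]
            np.testing.assert_allclose(got, want, atol=1e-8)

    def test_min_le_mean_le_max_on_valid_rows(self, small_study):
        df = small_study["features"]
        ok = df[df.valid]
        assert (ok.hr_min <= ok.hr_mean + 1e-12).all()
        assert (ok.hr_mean <= ok.hr_max + 1e-12).all()
        disp = ok[["sdnn", "rmssd", "sd1", "sd2", "lf_power", "hf_power"]]
        assert (disp >= 0).all().all()
        np.testing.assert_allclose(ok.sd1 ** 2 + ok.sd2 ** 2, 2 * ok.sdnn ** 2,
                                   rtol=1e-6)
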