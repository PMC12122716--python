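"""Generator contracts: determinism, label structure, corruption ledgers."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from relapsekit import synthio
from relapsekit.synthio import (PatientSpec, StateParams, generate_cohort,
                                inject_artifacts, inject_missingness,
                                relapse_events)

from conftest import fast_spec

#: per-patient day counts of the ten-patient reference cohort
REFERENCE_DAY_COUNTS = [303, 316, 230, 228, 210, 297, 243, 455, 92, 325]


class TestLabels:
    def test_reference_cohort_totals_2699_days(self):
        specs = [fast_spec(f"u{i:02d}", n_days=n, relapse_rate=0.2, seed=i)
                 for i, n in enumerate(REFERENCE_DAY_COUNTS)]
        cohort = generate_cohort(specs, seed=0)  # labels are materialized lazily
        assert cohort.n_days_total == 2699
        per = cohort.labels.groupby("patient_id").size()
        assert sorted(per) == sorted(REFERENCE_DAY_COUNTS)

    def test_zero_relapse_rate_gives_no_relapse_days(self):
        cohort = generate_cohort([fast_spec(n_days=1, relapse_rate=0.0)], seed=1)
        assert cohort.labels.relapse.sum() == 0
        assert len(cohort.labels) == 1

    def test_relapse_days_form_contiguous_events_with_plausible_mean_length(self):
        spec = fast_spec(n_days=600, relapse_rate=0.3, relapse_event_mean_len=4.0)
        cohort = generate_cohort([spec], seed=2)
        labs = cohort.labels.relapse.to_numpy()
        events = relapse_events(labs)
        assert events, "expected at least one event at rate 0.3 over 600 days"
        lengths = [e - s for s, e in events]
        # every relapse day is inside exactly one recovered event
        assert sum(lengths) == labs.sum()
        assert 2.0 < np.mean(lengths) < 7.0  # geometric with mean 4

    def test_invalid_specs_rejected(self):
        with pytest.raises(synthio.ConfigurationError):
            fast_spec(n_days=0)
        with pytest.raises(synthio.ConfigurationError):
            fast_spec(relapse_rate=1.5)
        with pytest.raises(synthio.ConfigurationError):
            StateParams(mean_nn=500, sdnn_target=600, accel_mean=0.5, accel_sd=0.1)
        with pytest.raises(synthio.ConfigurationError):
            generate_cohort([], seed=0)


class TestDeterminism:
    def test_same_specs_and_seed_byte_identical(self):
        specs = [fast_spec(n_days=2, gap_rate=0.5, ectopic_rate=0.01,
                           outlier_rate=0.01)]
        a = generate_cohort(specs, seed=9).fingerprint()
        b = generate_cohort([fast_spec(n_days=2, gap_rate=0.5, ectopic_rate=0.01,
                                       outlier_rate=0.01)], seed=9).fingerprint()
        assert a == b

    def test_different_seed_different_streams(self):
        specs = [fast_spec(n_days=1)]
        assert (generate_cohort(specs, seed=1).fingerprint()
                != generate_cohort(specs, seed=2).fingerprint())


class TestGenerateDay:
    def test_stream_shapes_and_rates(self, fast_day):
        assert fast_day.accel_lin.shape == (2 * 86400, 3)
        assert fast_day.hr.shape == (86400,)
        assert fast_day.rr.shape == (86400,)
        assert np.allclose(fast_day.hr, 60000.0 / fast_day.rr)

    def test_sleep_epochs_clipped_and_disjoint(self):
        cohort = generate_cohort([fast_spec(n_days=4)], seed=3)
        for rec in cohort.iter_days():
            for s, e in rec.sleep_epochs:
                assert 0 <= s < e <= 86400
            for (s1, e1), (s2, e2) in zip(rec.sleep_epochs, rec.sleep_epochs[1:]):
                assert e1 <= s2

    def test_zero_noise_limit_gives_exact_means(self):
        quiet = StateParams(mean_nn=800.0, sdnn_target=0.0, accel_mean=0.66,
                            accel_sd=0.0, lf_amp=0.0, hf_amp=0.0,
                            ang_mean=0.3, ang_sd=0.0, accel_within_cv=0.0)
        spec = fast_spec(params={k: quiet for k in synthio.STATE_KEYS})
        rec = generate_cohort([spec], seed=4).day(0, 0)
        assert np.all(rec.rr == 800.0)
        norms = np.linalg.norm(rec.accel_lin.astype(np.float64), axis=1)
        assert np.allclose(norms, 0.66, atol=1e-6)

    def test_label_must_be_binary(self):
        with pytest.raises(synthio.ConfigurationError):
            synthio.generate_day(fast_spec(), 0, 2, seed=0)


class TestStateSeparation:
    def test_identical_awake_accel_distributions_ks_nonsignificant(self):
        """Awake acceleration carries no relapse signal in the presets.

        Daily awake accel-norm means from relapse vs non-relapse days should
        be KS-indistinguishable in at least 90% of seeded replicates.
        """
        nonsig = 0
        reps = 20
        for rep in range(reps):
            spec = fast_spec(n_days=30, relapse_rate=0.5,
                             relapse_event_mean_len=4.0,
                             params=synthio.USER01_LIKE, seed=rep)
            cohort = generate_cohort([spec], seed=700 + rep)
            means = {0: [], 1: []}
            for rec in cohort.iter_days():
                awake = np.ones(rec.accel_lin.shape[0], dtype=bool)
                for s, e in rec.sleep_epochs:
                    awake[int(s * rec.fs_accel):int(e * rec.fs_accel)] = False
                norm = np.linalg.norm(rec.accel_lin.astype(np.float64), axis=1)
                means[rec.relapse_label].append(norm[awake].mean())
            if len(means[0]) >= 3 and len(means[1]) >= 3:
                p = ks_2samp(means[0], means[1]).pvalue
                nonsig += p > 0.05
            else:
                reps -= 1
        assert nonsig / reps >= 0.9


class TestCorruption:
    def test_zero_rates_leave_record_unchanged(self, fast_day):
        gapped = inject_missingness(fast_day, gap_rate=0.0, seed=1)
        assert np.array_equal(gapped.rr, fast_day.rr)
        art = inject_artifacts(fast_day, 0.0, 0.0, seed=1)
        assert np.array_equal(art.hr, fast_day.hr)

    def test_gaps_blank_all_streams_simultaneously_and_are_logged(self, fast_day):
        gapped = inject_missingness(fast_day, gap_rate=3.0, seed=2)
        gaps = gapped.injected["gaps"]
        assert gaps, "expected at least one gap at rate 3"
        for s, e in gaps:
            i0, i1 = int(np.ceil(s * gapped.fs_hr)), int(e * gapped.fs_hr)
            assert np.isnan(gapped.rr[i0:i1]).all()
            assert np.isnan(gapped.hr[i0:i1]).all()
            a0, a1 = int(np.ceil(s * gapped.fs_accel)), int(e * gapped.fs_accel)
            assert np.isnan(gapped.accel_lin[a0:a1]).all()
        # clean copies retained as oracles
        assert np.array_equal(gapped.clean["rr"], fast_day.rr)

    def test_gap_longer_than_day_rejected(self, fast_day):
        with pytest.raises(synthio.ConfigurationError):
            inject_missingness(fast_day, 1.0,
                               gap_len_dist={"long": (90000.0, 100000.0)}, seed=0)

    def test_ectopics_are_isolated_and_scaled_by_0_6(self, fast_day):
        art = inject_artifacts(fast_day, ectopic_rate=0.001, outlier_rate=0.0,
                               seed=3)
        idx = np.array(art.injected["ectopic_idx"])
        assert idx.size > 0
        assert np.all(np.diff(idx) >= 25)
        assert np.allclose(art.rr[idx], 0.6 * fast_day.rr[idx])

    def test_outliers_leave_valid_range_and_are_counted(self, fast_day):
        art = inject_artifacts(fast_day, 0.0, outlier_rate=0.001, seed=4)
        hr_pos = art.injected["outliers"]["hr"]
        assert len(hr_pos) == round(0.001 * fast_day.hr.size)
        assert np.all((art.hr[hr_pos] < 30) | (art.hr[hr_pos] > 220))
        rr_pos = art.injected["outliers"]["rr"]
        assert np.all((art.rr[rr_pos] < 250) | (art.rr[rr_pos] > 2000))


class TestDiskLayout:
    def test_cohort_round_trip(self, tmp_path):
        spec = fast_spec(n_days=1, gap_rate=1.0, seed=8)
        cohort = generate_cohort([spec], seed=13)
        out = synthio.write_cohort(cohort, tmp_path / "cohort")
        assert (out / "manifest.json").exists()
        assert (out / "labels.csv").exists()
        rec = cohort.day(0, 0)
        back = synthio.read_day(out, rec.patient_id, 0)
        np.testing.assert_allclose(back.rr, rec.rr, rtol=1e-12)
        np.testing.assert_allclose(back.accel_lin, rec.accel_lin, rtol=1e-6)
        assert back.relapse_label == rec.relapse_label
        assert back.sleep_epochs == pytest.approx(
            [tuple(map(float, ep)) for ep in rec.sleep_epochs])
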