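"""Shared fixtures: small synthetic cohorts and prepared pipeline stages."""

import numpy as np
import pandas as pd
import pytest

from relapsekit import experiments, synthio


def fast_spec(patient_id="t0", n_days=2, **kwargs):
    """A reduced-sample-rate patient for structural tests.

    The 2 Hz motion / 1 Hz heart streams exercise every code path at a
    fraction of the device-rate cost; rate-dependent statistics are tested
    elsewhere at the true 20 Hz / 5 Hz.
    """
    defaults = dict(params=synthio.USER00_LIKE, n_days=n_days,
                    relapse_rate=0.0, fs_accel=2.0, fs_hr=1.0, seed=3)
    defaults.update(kwargs)
    return synthio.PatientSpec(patient_id=patient_id, **defaults)


@pytest.fixture(scope="session")
def fast_day():
    """One clean reduced-rate day."""
    cohort = synthio.generate_cohort([fast_spec()], seed=11)
    return cohort.day(0, 0)


@pytest.fixture(scope="session")
def small_study():
    """Two device-rate patients (one per phenotype preset), fully prepared.

    Session-scoped because featurizing 42 device-rate days dominates the
    cost; tests must not mutate the returned objects.
    """
    specs = synthio.default_study_specs(n_patients=2, n_days=21)
    cohort = synthio.generate_cohort(specs, seed=5)
    features_df = experiments.featurize_cohort(cohort)
    plan = experiments.split_dataset(cohort.labels, seed=5)
    bundles = experiments.prepare_bundles(features_df, plan)
    return {"specs": specs, "cohort": cohort, "features": features_df,
            "plan": plan, "bundles": bundles}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
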