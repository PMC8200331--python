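"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

import optoconn as oc


@pytest.fixture(scope="session")
def tiny_montage():
    return oc.make_montage(4, distances_mm=[25.0, 30.0, 35.0, 28.0])


@pytest.fixture(scope="session")
def small_spec():
    """Two-group, 16-channel, short-record cohort used by integration tests."""
    return oc.CohortSpec(
        n_groups=2,
        n_per_group=(6, 6),
        n_channels=16,
        n_samples=1800,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return oc.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_subjects(small_cohort):
    recs, _ = small_cohort
    return [oc.preprocess_recording(r, n_samples=1500) for r in recs]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
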