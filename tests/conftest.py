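"""Shared fixtures.

The expensive artifact — the full end-to-end study on a 200-patient
synthetic cohort — is session-scoped; the cohort-level fixtures are views
into it, so the whole suite simulates and models the cohort exactly once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from icpforecast.config import RunConfig
from icpforecast.simcohort import SimConfig
from icpforecast.study import run_study

COHORT_SEED = 42
COHORT_N = 200


def small_sim_config(**kw) -> SimConfig:
    """A cheap simulator configuration for unit-level tests."""
    defaults = dict(n_patients=12, seed=5)
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(sim=SimConfig(n_patients=COHORT_N, seed=COHORT_SEED), seed=COHORT_SEED)


@pytest.fixture(scope="session")
def study_bundle(run_config):
    """Full study bundle (features, labels, models, CV, importances) for the
    default 200-patient synthetic cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(run_config)


@pytest.fixture(scope="session")
def cohort200(study_bundle):
    """(feature_table, ground_truths, excluded) view into the study bundle;
    the table carries OutcomeLabels in attrs['labels']."""
    return (
        study_bundle["feature_table"],
        study_bundle["ground_truths"],
        study_bundle["excluded"],
    )


@pytest.fixture(scope="session")
def feature_table(cohort200):
    return cohort200[0]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
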