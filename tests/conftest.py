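"""Shared fixtures: small synthetic cohorts generated once per session."""

import numpy as np
import pytest

from reachvigor import cohort, design


@pytest.fixture(scope="session")
def learned_schedules():
    return design.build_experiment_schedule(mode="learned", seed=11)


@pytest.fixture(scope="session")
def small_learned_cohort():
    """8 learned-mode subjects with default generator settings."""
    records, _ = cohort.simulate_cohort(n_subjects=8, mode="learned", seed=21)
    return records


@pytest.fixture(scope="session")
def small_instructed_cohort():
    """8 instructed-mode subjects (velocity driven by announced E[R])."""
    records, _ = cohort.simulate_cohort(n_subjects=8, mode="instructed", seed=22)
    return records


@pytest.fixture(scope="session")
def noise_free_kin():
    return cohort.KinematicGenParams(gamma_shape=np.inf, rt_gamma_shape=np.inf,
                                     rt_subject_sd=0.0, pv_subject_sd=0.0)
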