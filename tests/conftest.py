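import numpy as np
import pytest

from astraj.clustering import Trajectory, trajectories_from_frame
from astraj.cohorts import (
    ScreeningGeneratorConfig,
    TrajectoryGeneratorConfig,
    generate_screening_cohort,
    generate_trajectory_cohort,
)


@pytest.fixture(scope="session")
def screening_cohort():
    """Moderate-size screening cohort with the default structure."""
    return generate_screening_cohort(
        ScreeningGeneratorConfig(n_subjects=4000, seed=101))


@pytest.fixture(scope="session")
def trajectory_cohort():
    """Small default-structure trajectory cohort."""
    return generate_trajectory_cohort(
        TrajectoryGeneratorConfig(n_subjects=300, seed=202))


@pytest.fixture(scope="session")
def trajectories(trajectory_cohort):
    return trajectories_from_frame(trajectory_cohort.scores)


@pytest.fixture(scope="session")
def separated_cohort():
    """Low-noise cohort with clearly separated trajectory classes."""
    return generate_trajectory_cohort(TrajectoryGeneratorConfig(
        n_subjects=250, observation_noise_sd=0.03,
        subject_random_intercept_sd=0.02, seed=303))


def make_constant_trajectories(levels, n_per_level=10, n_obs=5, seed=0):
    """Noiseless constant trajectories at the given levels."""
    rng = np.random.default_rng(seed)
    out = []
    sid = 0
    for lev in levels:
        for _ in range(n_per_level):
            sid += 1
            times = np.sort(rng.uniform(0, 10, size=n_obs))
            out.append(Trajectory(sid, times, np.full(n_obs, lev)))
    return out


@pytest.fixture
def two_level_trajectories():
    """Two noiseless groups at constant levels 0.3 and 0.8."""
    return make_constant_trajectories([0.3, 0.8], n_per_level=12, seed=7)
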