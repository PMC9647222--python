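from __future__ import annotations

import numpy as np
import pytest

import radkinetics as rk


@pytest.fixture(scope="session")
def small_trajectory_cohort() -> rk.SyntheticCohort:
    """80 patients, 15 fractions, 30 features, one strong informative
    feature — used by selection/model tests that only need signal."""
    cfg = rk.SyntheticConfig(
        n_patients=80, n_fractions=15, n_features=30,
        prevalence={"6m": 0.46}, informative_features=[(0, 1.5)], seed=11,
    )
    return rk.generate_trajectory_cohort(cfg)


@pytest.fixture(scope="session")
def small_image_cohort() -> rk.SyntheticCohort:
    """4 patients, 8 fractions, noiseless textured phantoms."""
    cfg = rk.SyntheticConfig(
        n_patients=4, n_fractions=8, prevalence={"6m": 0.5},
        noise_sd=0.0, seed=21,
    )
    return rk.generate_image_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
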