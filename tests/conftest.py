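"""Shared fixtures: small seeded cohorts generated once per session."""

import numpy as np
import pytest

from restvs.synthetic import CohortConfig, make_cohort

# desk-scale cohort for unit tests: 15 subjects, 18 ROIs (2 per network)
SMALL_CONFIG = CohortConfig(
    n_per_cohort=(5, 5, 5),
    n_roi=18,
    rest_acq=((2.5, 100), (2.0, 110), (2.7, 90)),
    n_nonzero_edges=1,       # only one within-network pair exists at 2 ROIs/network
    n_cross_per_network=2,
)


@pytest.fixture(scope="session")
def small_cohort():
    return make_cohort(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def small_cohort_clean():
    """Same shape, but noise-free targets and task."""
    cfg = CohortConfig(**{**SMALL_CONFIG.__dict__,
                          "noise_sd_target": 0.0, "task_noise_sd": 0.0})
    return make_cohort(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
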