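"""Shared fixtures: small seeded simulations reused across test modules."""

import numpy as np
import pytest

from icplnc import PipelineConfig, simulate_immune_panel, simulate_tumor_cohort
from icplnc.simulate import SimConfig


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig(rng_seed=0, n_survival_perms=100, mi_null_perms=100)


@pytest.fixture(scope="session")
def small_sim():
    return SimConfig(seed=0, samples_per_cell_type=20, samples_per_cohort=150)


@pytest.fixture(scope="session")
def panel(small_sim):
    return simulate_immune_panel(small_sim)


@pytest.fixture(scope="session")
def tumor(small_sim):
    return simulate_tumor_cohort(small_sim, "C1")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
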