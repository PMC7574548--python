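"""Shared fixtures: a small synthetic study reused across test modules.

The small study keeps the generator's default effect sizes and noise levels
and only scales down the number of planted sites, so per-site properties
match the full-scale study conditions while the suite stays fast.
"""

import numpy as np
import pytest

from pombeori.simulate import SimulationConfig, simulate_genome
from pombeori.workflow import prepare_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=202, n_om=40, n_o=10, n_background=300)


@pytest.fixture(scope="session")
def small_study(small_config):
    return prepare_study(small_config, site_source="truth")


@pytest.fixture(scope="session")
def small_sim(small_study):
    return small_study.sim


@pytest.fixture(scope="session")
def tiny_sim():
    """A very small genome for IO/pipeline round-trips."""
    return simulate_genome(
        SimulationConfig(seed=77, n_chroms=1, n_om=8, n_o=2, n_background=40)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
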