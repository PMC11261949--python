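"""Shared fixtures: a small seeded toy reference and cohort.

Session-scoped because reference construction (sequence synthesis plus site
indexing) dominates test runtime; tests must not mutate these objects.
"""

import warnings

import pytest

from hrdkit.simulate import SimulationConfig, make_reference, simulate_cohort

_MB = 1_000_000


@pytest.fixture(scope="session")
def toy_config() -> SimulationConfig:
    return SimulationConfig(
        n_hrd=8,
        n_hrp=8,
        genome=(("1", 60 * _MB), ("2", 60 * _MB)),
        seq_window=200_000,
    )


@pytest.fixture(scope="session")
def toy_reference(toy_config):
    return make_reference(toy_config, seed=7)


@pytest.fixture(scope="session")
def small_cohort(toy_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(toy_config, seed=7)


@pytest.fixture(scope="session")
def enrichment_cohort():
    """Default study conditions (50 samples per arm) for the enrichment
    screen properties."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(SimulationConfig(n_hrd=50, n_hrp=50), seed=202)
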