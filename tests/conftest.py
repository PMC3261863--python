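import numpy as np
import pytest

from gergm.networks import RestrictedNetwork
from gergm.statistics import STATISTIC_NAMES, StatisticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def full_spec():
    return StatisticSpec(STATISTIC_NAMES)


@pytest.fixture
def random_restricted(rng):
    """Factory: a random restricted network of a given size."""

    def make(n: int, seed: int | None = None) -> RestrictedNetwork:
        local = np.random.default_rng(seed) if seed is not None else rng
        values = local.uniform(0.05, 0.95, size=(n, n))
        np.fill_diagonal(values, 0.0)
        return RestrictedNetwork(values)

    return make
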