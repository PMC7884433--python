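import numpy as np
import pytest

from hybridzone import SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240115)


@pytest.fixture
def small_params():
    """Desk-scale scenario: small population, short run."""
    return SimulationParams(carrying_capacity_per_species=200,
                            n_generations=30, seed=7)
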