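import numpy as np
import pytest

from optidose import UtilityConfig, UtilityMatrix, default_grid, generate_dataset, scenario_spec
from optidose.simulate import split_table


@pytest.fixture(scope="session")
def s1_spec():
    return scenario_spec("S1")


@pytest.fixture(scope="session")
def grid21():
    return default_grid(21)


@pytest.fixture(scope="session")
def s1_data_400(s1_spec):
    """One scenario-1 training table (n=400) shared across model tests."""
    table, _ = generate_dataset(s1_spec, 400, np.random.default_rng(2024))
    return table


@pytest.fixture(scope="session")
def s1_design_400(s1_data_400):
    return split_table(s1_data_400)


@pytest.fixture
def u1_cfg():
    return UtilityConfig(matrix=UtilityMatrix.from_omegas(0.3, 0.5))


@pytest.fixture
def u2_cfg():
    return UtilityConfig(matrix=UtilityMatrix.from_omegas(0.5, 0.5))


def random_joint(rng, shape=()):
    """Dirichlet-random valid joint cell probabilities."""
    return rng.dirichlet(np.ones(4), size=shape)
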