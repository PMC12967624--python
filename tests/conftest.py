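import numpy as np
import pytest

from thorson.synthetic_world import gen_chla_fields, gen_env_grid, gen_world


@pytest.fixture(scope="session")
def world():
    """One default synthetic study system shared across read-only tests."""
    return gen_world(3)


@pytest.fixture(scope="session")
def grid():
    return gen_env_grid(1)


@pytest.fixture(scope="session")
def chla_fields(grid):
    return gen_chla_fields(2, grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
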