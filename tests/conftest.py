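import numpy as np
import pytest

import traitscan as ts


@pytest.fixture(scope="session")
def grid8():
    return ts.make_alpha_grid(8)


@pytest.fixture(scope="session")
def table8(grid8):
    # modest draw count keeps the suite fast; determinism is what matters here
    return ts.get_tc_table(grid8, n_draws=20_000)


@pytest.fixture(scope="session")
def grid5():
    return ts.make_alpha_grid(5)


@pytest.fixture(scope="session")
def table5(grid5):
    return ts.get_tc_table(grid5, n_draws=20_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240105)
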