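import numpy as np
import pandas as pd
import pytest

from bnepi import DataTable, fixture_networks


@pytest.fixture(scope="session")
def nets():
    return fixture_networks()


@pytest.fixture(scope="session")
def exposure6(nets):
    return nets["exposure6"]


@pytest.fixture(scope="session")
def bladder11(nets):
    return nets["bladder11"]


@pytest.fixture
def tiny_table():
    """Three complete records over two binary variables."""
    return DataTable(pd.DataFrame({"A": ["1", "1", "0"], "B": ["0", "1", "1"]}))


def independent_binary(rng: np.random.Generator, n: int, p_x=0.5, p_y=0.5):
    """Two independent binary columns (helper used by several suites)."""
    return DataTable(
        pd.DataFrame(
            {
                "X": (rng.random(n) < p_x).astype(int).astype(str),
                "Y": (rng.random(n) < p_y).astype(int).astype(str),
            }
        )
    )
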