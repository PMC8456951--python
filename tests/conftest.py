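import numpy as np
import pandas as pd
import pytest

from oligocoda.balances import mvco_sbp
from oligocoda.geometry import CompositionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def sbp():
    return mvco_sbp()


def random_composition_matrix(rng, n=20, D=6, labels=None, dates=None):
    """Dirichlet draws with seasonal spread of dates across one year."""
    vals = rng.dirichlet(np.ones(D) * 2.0, n)
    labels = labels or [f"O{j + 1}" for j in range(D)]
    ids = [f"S{i:03d}" for i in range(n)]
    if dates is None:
        dates = pd.date_range("2015-01-10", periods=n, freq="18D")
    df = pd.DataFrame(vals, index=ids, columns=labels)
    return CompositionMatrix(df, pd.Series(dates, index=ids))


@pytest.fixture
def comp_matrix(rng):
    return random_composition_matrix(rng)
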