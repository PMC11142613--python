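import matplotlib

matplotlib.use("Agg", force=True)

import matplotlib.pyplot as plt
import numpy as np
import pytest

from madfc import synthetic_data


@pytest.fixture(autouse=True)
def _close_figures():
    yield
    plt.close("all")


@pytest.fixture(scope="session")
def fc_grid():
    """Dense log-spaced fold-change grid over [2^-10, 2^10]."""
    return np.exp2(np.linspace(-10, 10, 10_000))


@pytest.fixture(scope="session")
def de_table():
    """Small seeded differential-results table."""
    return synthetic_data.gen_de_results(n_genes=400, seed=11)
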