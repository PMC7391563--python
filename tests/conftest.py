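import numpy as np
import pandas as pd
import pytest

from sandsift import simcross


@pytest.fixture(scope="session")
def small_cross():
    """A 3-chromosome, 113-individual simulated cross with its true map."""
    smap = simcross.simulate_map(3, 50.0, 6, seed=11)
    codes = simcross.simulate_f2(smap, 113, seed=12)
    return smap, codes


@pytest.fixture(scope="session")
def base_shape():
    """An irregular but non-degenerate 13-landmark reference configuration."""
    rng = np.random.default_rng(42)
    return np.cumsum(np.ones((13, 2)), axis=0) + rng.normal(0, 0.8, size=(13, 2))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
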