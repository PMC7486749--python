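import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_matrix(rng):
    """5 samples × 8 features, generic positive data."""
    data = np.exp(rng.normal(0, 1, size=(5, 8)))
    return pd.DataFrame(data,
                        index=[f"s{i}" for i in range(5)],
                        columns=[f"f{j}" for j in range(8)])
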