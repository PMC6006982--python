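import numpy as np
import pandas as pd
import pytest

from entroflow import FeatureSpec, RawDataMatrix


@pytest.fixture
def two_block_values():
    """20 values in two tight blocks separated by a 99-unit hole."""
    rng = np.random.default_rng(0)
    return np.concatenate([rng.uniform(0, 1, 10), rng.uniform(100, 101, 10)])


@pytest.fixture
def mixed_raw_matrix():
    """A small raw matrix with continuous, binary and categorical columns."""
    rng = np.random.default_rng(42)
    n = 40
    cont = rng.normal(50, 10, n)
    binary = (cont > 50).astype(int)
    cat = np.where(cont < 45, "low", np.where(cont < 55, "mid", "high"))
    frame = pd.DataFrame(
        {"cont": cont, "flag": binary, "level": cat},
        index=[f"s{i}" for i in range(n)],
    )
    specs = [
        FeatureSpec("cont", "continuous", "covariate"),
        FeatureSpec("flag", "binary", "covariate"),
        FeatureSpec("level", "categorical", "covariate"),
    ]
    return RawDataMatrix(frame, specs)
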