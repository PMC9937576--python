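import numpy as np
import pytest

from coopevo import ModelParams


@pytest.fixture
def baseline_params() -> ModelParams:
    """Two groups of four, e = c_c = c_h = 1, b_CG = 2, b_PG = 3, mu = 1e-4."""
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
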