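import numpy as np
import pytest

from ffltune import FFLParameters


@pytest.fixture
def base_params() -> FFLParameters:
    """Reference parameterization: R=2, c=1, unit GAT1, A=1, X=0.4."""
    return FFLParameters(a=1.0, x=0.4, r=2.0, c=1.0, gat1=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180405)
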