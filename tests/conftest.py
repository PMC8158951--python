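import numpy as np
import pytest

from t2dwi import AcquisitionScheme, ComponentBasis


@pytest.fixture
def scheme() -> AcquisitionScheme:
    return AcquisitionScheme()


@pytest.fixture
def basis() -> ComponentBasis:
    return ComponentBasis()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
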