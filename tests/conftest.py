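import numpy as np
import pytest

from actionpath import MolecularSystem


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def system_1d():
    return MolecularSystem.uniform(1, 1.0, dim=1)


@pytest.fixture
def system_2d():
    return MolecularSystem.uniform(1, 1.0, dim=2)
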