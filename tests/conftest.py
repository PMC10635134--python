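import numpy as np
import pytest

from noedock.restraints import CalibrationTable
from noedock.synthetic import (ToyComplexSpec, fabricated_restraints,
                               make_toy_complex)


@pytest.fixture(scope="session")
def toy():
    """A deterministic zero-noise toy complex."""
    return make_toy_complex(ToyComplexSpec(seed=3))


@pytest.fixture(scope="session")
def toy_restraints(toy):
    return fabricated_restraints(toy)


@pytest.fixture(scope="session")
def calibration():
    return CalibrationTable()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
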