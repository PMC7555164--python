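import numpy as np
import pytest

from agediff import DiffusionParams


@pytest.fixture(scope="session")
def fast_params():
    """Typical fast-task parameters (odd-even-discrimination scale)."""
    return DiffusionParams(v=3.95, a=1.20, t0=0.43, st0=0.06)


@pytest.fixture(scope="session")
def slow_params():
    """Typical slow-task parameters (maze-like scale)."""
    return DiffusionParams(v=0.94, a=3.75, t0=1.29, st0=0.19)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
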