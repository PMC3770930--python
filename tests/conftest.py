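import numpy as np
import pytest

from depspec.cm_model import DielectricParams
from depspec.dualcycle import CycleSpec, default_kinetics


@pytest.fixture
def pstar() -> DielectricParams:
    """Latex nanosphere in dilute KCl: 26 mS/m particle, 2 mS/m medium."""
    return DielectricParams(sigma_p=26e-3, sigma_m=2e-3, eps_p=2.55, eps_m=78.0)


@pytest.fixture
def protocol() -> CycleSpec:
    """15 s on / 10 s off per cycle, 1 MHz control, 2 MHz probe."""
    return CycleSpec(15.0, 10.0, 15.0, 10.0, f1=1e6, f2=2e6)


@pytest.fixture
def full_release() -> CycleSpec:
    """Protocol with off-phases long enough for complete release (>> max tau)."""
    return CycleSpec(15.0, 400.0, 15.0, 400.0, f1=1e6, f2=2e6)


@pytest.fixture
def kinetics():
    return default_kinetics()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
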