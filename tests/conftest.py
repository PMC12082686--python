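import numpy as np
import pytest

from masjump import RotorSpec, Rank2Tensor, zcw_orientations


@pytest.fixture(scope="session")
def rotor20():
    """20 kHz MAS rotor."""
    return RotorSpec(nu_r=20000.0)


@pytest.fixture(scope="session")
def powder_small():
    """Tiny two-angle powder for fast unit checks."""
    return zcw_orientations(30)


@pytest.fixture(scope="session")
def powder_medium():
    """Reduced-fidelity powder used by sequence-level checks."""
    return zcw_orientations(80, three_angle=True)


@pytest.fixture(scope="session")
def dip5k():
    """5 kHz dipolar-coupling tensor (rad/s anisotropy inside)."""
    return Rank2Tensor.from_hz(5000.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240611)
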