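import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from spheroidox.geometry import Shape, SpheroidGeometry
from spheroidox.oxygen import OxygenModelParams

UM = 1e-6


@pytest.fixture(scope="session")
def params():
    """Reference simulation parameters: 500 um spheroid, a = 20 mmHg/s,
    p_o = 100 mmHg, D = 2e-9 m^2/s."""
    return OxygenModelParams(p_o=100.0, D=2e-9, a=20.0)


@pytest.fixture(scope="session")
def dld_geometry():
    """Printed ellipse-fit geometry of the eccentric DLD-1 section:
    r_o = 488.5 um, r_n = 400.15 um, f = 318.89 um."""
    return SpheroidGeometry(Shape.PROLATE, 488.5 * UM, 400.15 * UM, 318.89 * UM)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180256)
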