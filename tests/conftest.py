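import numpy as np
import pytest

from tofprofile.geometry import DetectorGeometry, Panel, UBMatrix
from tofprofile.moderator import default_table
from tofprofile.synthetic import default_instrument


@pytest.fixture(scope="session")
def instrument():
    """The synthetic diffractometer: (UBMatrix, DetectorGeometry)."""
    return default_instrument()


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def single_panel_geom():
    """One flat 256x256 panel straight down the +x axis, 0.5 m away."""
    geom = DetectorGeometry(l_default=30.5)
    geom.panels.append(
        Panel.tangent("p0", two_theta=np.pi / 2, phi_az=0.0, distance=0.5,
                      n_rows=256, n_cols=256, pitch=0.001, l1=30.0)
    )
    return geom
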