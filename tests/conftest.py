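import numpy as np
import pytest

from tpmscaffold import Cylinder, DesignTarget, fit_porosity_line


@pytest.fixture(scope="session")
def gyroid_fit():
    """Default gyroid porosity calibration (fixed package seed)."""
    return fit_porosity_line("G")


@pytest.fixture(scope="session")
def diamond_fit():
    return fit_porosity_line("D")


@pytest.fixture(scope="session")
def wide_gyroid_fit():
    """Calibration over c in [-0.8, 0.8], wide enough to reach 30% porosity."""
    return fit_porosity_line("G", c_values=np.linspace(-0.8, 0.8, 9))


@pytest.fixture(scope="session")
def wide_diamond_fit():
    return fit_porosity_line("D", c_values=np.linspace(-0.8, 0.8, 9))


@pytest.fixture(scope="session")
def paper_target():
    """The reference design: 10 mm cylinder, 1 mm pores, 40 % porosity, gyroid."""
    return DesignTarget(
        family="G",
        porosity=0.40,
        pore_radius=1.0,
        envelope=Cylinder(height=10.0, diameter=10.0),
    )
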