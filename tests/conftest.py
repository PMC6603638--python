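import numpy as np
import pytest

from nodulemap.phantom import (
    HEALTHY_TISSUE,
    TUMOR_TISSUE,
    Phantom,
    make_reference_phantom,
)
from nodulemap.scan_sim import AcquisitionConfig


@pytest.fixture(scope="session")
def noiseless_config() -> AcquisitionConfig:
    return AcquisitionConfig().without_noise()


@pytest.fixture(scope="session")
def homogeneous_healthy() -> Phantom:
    return Phantom()


@pytest.fixture(scope="session")
def homogeneous_tumor() -> Phantom:
    return Phantom(matrix_material=TUMOR_TISSUE)


@pytest.fixture(scope="session")
def fixed_phantom() -> Phantom:
    """Reference phantom with the deterministic fixed inclusion layout."""
    return make_reference_phantom(seed=0, randomize_positions=False)


@pytest.fixture(scope="session")
def small_probe_grid(fixed_phantom):
    """A small grid: every inclusion center plus a handful of matrix points."""
    pts = [(inc.center_mm[0], inc.center_mm[1]) for inc in fixed_phantom.inclusions]
    pts += [(5.0, 5.0), (50.0, 30.0), (95.0, 55.0), (5.0, 55.0), (50.0, 5.0)]
    return np.array(pts)
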