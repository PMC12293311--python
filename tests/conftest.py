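import numpy as np
import pytest
from hypothesis import settings

from voxdose import synthetic
from voxdose.materials import CoefficientTable

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return synthetic.default_registry()


@pytest.fixture(scope="session")
def coeff_table():
    return CoefficientTable.default()


@pytest.fixture(scope="session")
def body():
    """Default synthetic 30-organ body, (64, 64, 160) voxels at 0.4 cm."""
    return synthetic.generate_body()


@pytest.fixture(scope="session")
def small_body():
    """Coarse body for cheap smoke checks."""
    return synthetic.generate_body(dims=(32, 32, 80), pitch=0.8)


@pytest.fixture(scope="session")
def tissue_slab(registry):
    """Muscle / cortical bone / muscle sandwich, 4+2+4 cm along x."""
    return synthetic.generate_slab_phantom(
        [(24, 4.0), (23, 2.0), (24, 4.0)], registry, pitch=0.5, lateral=(4, 4)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
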