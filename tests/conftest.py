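import numpy as np
import pytest

from memperm.synthetic import BilayerSpec, build_bilayer


@pytest.fixture(scope="session")
def flat_bilayer():
    """10+10 lipid bead bilayer, zero tilt, one frame."""
    spec = BilayerSpec(n_lipids_per_leaflet=10, n_chol_per_leaflet=4,
                       n_waters=60, box=(25.0, 25.0, 60.0), head_z=18.0,
                       tilt_deg=0.0, seed=11)
    return build_bilayer(spec)


@pytest.fixture(scope="session")
def tilted_bilayer():
    """Bilayer with every chain tilted 30 degrees from the normal."""
    spec = BilayerSpec(n_lipids_per_leaflet=9, n_waters=40,
                       box=(24.0, 24.0, 60.0), head_z=18.0,
                       tilt_deg=30.0, seed=5)
    return build_bilayer(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
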