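import numpy as np
import pytest

from sparsect.phantoms import PhantomSpec, random_ellipses, shepp_logan
from sparsect.projection import Geometry, radon_forward


@pytest.fixture(scope="session")
def shepp64():
    return shepp_logan(64)


@pytest.fixture(scope="session")
def geom_full():
    """Desk-scale full-view geometry: 90 views over 360 degrees, 64 detectors."""
    return Geometry(n_views=90, n_detectors=64)


@pytest.fixture(scope="session")
def geom_dense():
    """Paper-style dense geometry: one view per degree."""
    return Geometry(n_views=360, n_detectors=64)


@pytest.fixture(scope="session")
def shepp_sino_dense(shepp64, geom_dense):
    return radon_forward(shepp64, geom_dense)


@pytest.fixture(scope="session")
def ellipse_phantom():
    return random_ellipses(PhantomSpec(size=64, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
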