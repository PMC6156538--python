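import numpy as np
import pytest

from myofe import phantoms


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def axial_phantom():
    """Small noiseless axial-fibre DWI phantom with ground truth."""
    return phantoms.make_dwi_phantom(shape=(8, 8, 10))


@pytest.fixture(scope="session")
def cylinder_mesh():
    """Mid-resolution structured cylinder mesh (r=6 mm, L=12 mm)."""
    return phantoms.make_cylinder_mesh(radius=6.0, length=12.0, target_edge=2.0)


@pytest.fixture(scope="session")
def box_mesh():
    """2x2x2-cell unit box split into Kuhn tets."""
    return phantoms.make_box_mesh(2, 2, 2)
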