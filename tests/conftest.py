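import numpy as np
import pytest

from cardioflow.mesh_core import SurfaceMesh
from cardioflow.primitives import box, icosphere, open_cylinder, open_hemisphere
from cardioflow.synthetic_phantom import PhantomSpec, generate_phantom_cycle


@pytest.fixture(scope="session")
def unit_cube() -> SurfaceMesh:
    return box((1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def sphere10() -> SurfaceMesh:
    """Icosphere r = 10 mm, 4 subdivisions (volume within 0.5% of a ball)."""
    return icosphere(10.0, 4)


@pytest.fixture(scope="session")
def hemisphere10() -> SurfaceMesh:
    return open_hemisphere(10.0, 24, 72)


@pytest.fixture(scope="session")
def cylinder() -> SurfaceMesh:
    return open_cylinder(radius=5.0, height=20.0, n_phi=96, n_z=6)


@pytest.fixture(scope="session")
def coarse_phantom():
    """Coarse default-dynamics phantom for registration-level tests (fast to
    generate; too coarse for flow-metric accuracy)."""
    return generate_phantom_cycle(PhantomSpec(mesh_resolution=7.0,
                                              laa_resolution=3.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
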