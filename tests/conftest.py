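import numpy as np
import pytest

from myoline import centroid, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def unit_cube():
    return synthetic.make_primitive("cube", edge=1.0)


@pytest.fixture(scope="session")
def icosphere3():
    return synthetic.make_primitive("icosphere", radius=1.0, subdivisions=3)


@pytest.fixture(scope="session")
def straight_cylinder():
    """Capped straight cylinder r=1, h=2 along +z with cap ground truth."""
    spec = synthetic.straight_cylinder_spec(1.0, 2.0, n_rings=8, n_sides=64)
    return synthetic.make_tube(spec)


@pytest.fixture(scope="session")
def quarter_tube():
    """Quarter-circle-arc tube, arc radius 10, tube radius 1, 64 sides."""
    spec = synthetic.quarter_torus_spec(10.0, 1.0, n_rings=64, n_sides=64)
    return synthetic.make_tube(spec)


@pytest.fixture(scope="session")
def cylinder_attachments(straight_cylinder):
    mesh, _ = straight_cylinder
    return (
        centroid.attachment_centroid(mesh.select_group("origin")),
        centroid.attachment_centroid(mesh.select_group("insertion")),
    )


def random_rigid_transform(rng):
    """A uniformly random rotation matrix and a translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-10, 10, 3)
    return R, t
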