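import numpy as np
import pytest

from uvfield.fixtures import generate_fixture_mesh, save_mesh_stl


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def unit_cube_mesh():
    return generate_fixture_mesh("box", extents=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def icosphere_mesh():
    return generate_fixture_mesh("icosphere", radius=0.03, subdivisions=3)


@pytest.fixture
def cube_stl_ascii(tmp_path, unit_cube_mesh):
    path = tmp_path / "cube_ascii.stl"
    save_mesh_stl(unit_cube_mesh, path, ascii_format=True)
    return path


@pytest.fixture
def cube_stl_binary(tmp_path, unit_cube_mesh):
    path = tmp_path / "cube_binary.stl"
    save_mesh_stl(unit_cube_mesh, path, ascii_format=False)
    return path


def random_pose(rng):
    from scipy.spatial.transform import Rotation
    from uvfield.geometry import Pose
    return Pose.from_rotation_translation(Rotation.random(random_state=rng).as_matrix(),
                                          rng.normal(size=3))
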