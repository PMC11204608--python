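import numpy as np
import pytest
import trimesh

from footprintmorph.synthetic import make_synthetic_bone


@pytest.fixture(scope="session")
def generic_bone():
    """Small phantom bone (sphere head + cylindrical shaft), meshed at 0.7 mm."""
    bone = make_synthetic_bone(
        "generic", {"head_radius": 12.0, "shaft_radius": 6.0, "length": 60.0}, mesh_pitch=0.7
    )
    bone.mesh  # build once for the whole session
    return bone


@pytest.fixture(scope="session")
def femur_bone():
    """Full-size phantom femur (25 mm head, 405 mm mechanical axis)."""
    bone = make_synthetic_bone("femur", mesh_pitch=1.0)
    bone.mesh
    return bone


@pytest.fixture(scope="session")
def icosphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=20.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def planar_grid_mesh(nx=20, ny=20, lx=1.0, ly=1.0, z=0.0):
    """Rectangular planar triangulated patch in the z-plane."""
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z)])
    faces = []
    for i in range(nx):
        for j in range(ny):
            a = i * (ny + 1) + j
            b = (i + 1) * (ny + 1) + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
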