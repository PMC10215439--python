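import numpy as np
import pytest

from thrombomap.mesh import SurfaceMesh
from thrombomap.synthetic import SyntheticSpec, make_aneurysm_mesh
from thrombomap.wss import WSSField


def flat_patch_mesh(n_side: int = 4, spacing: float = 1.0) -> SurfaceMesh:
    """Planar triangulated grid in z = 0 with +z normals.

    WSS vectors in the xy-plane are exactly tangent, so analytic index
    values are not polluted by tangent-plane projection.
    """
    ii, jj = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
    verts = np.column_stack([
        ii.ravel() * spacing, jj.ravel() * spacing, np.zeros(n_side**2)
    ])
    faces = []
    for i in range(n_side - 1):
        for j in range(n_side - 1):
            a = i * n_side + j
            b = a + n_side
            faces.append([a, b, b + 1])
            faces.append([a, b + 1, a + 1])
    normals = np.tile([0.0, 0.0, 1.0], (len(verts), 1))
    return SurfaceMesh(vertices=verts, faces=np.array(faces), normals=normals)


def harmonic_field(
    mesh: SurfaceMesh,
    coeffs_x: np.ndarray,
    coeffs_y: np.ndarray,
    n_times: int = 64,
    period: float = 1.0,
) -> WSSField:
    """Band-limited per-vertex field in the plane of ``flat_patch_mesh``.

    ``coeffs_x``/``coeffs_y`` have shape (N, 2H+1): mean, then cos/sin
    pairs per harmonic, giving the x and y vector components.
    """
    t = np.linspace(0.0, period, n_times, endpoint=False)
    h = (coeffs_x.shape[1] - 1) // 2

    def series(c):
        out = np.tile(c[:, 0], (n_times, 1))
        for k in range(1, h + 1):
            w = 2 * np.pi * k * t / period
            out += np.outer(np.cos(w), c[:, 2 * k - 1])
            out += np.outer(np.sin(w), c[:, 2 * k])
        return out

    vectors = np.zeros((n_times, mesh.n_vertices, 3))
    vectors[:, :, 0] = series(coeffs_x)
    vectors[:, :, 1] = series(coeffs_y)
    return WSSField(mesh=mesh, times=t, period=period, vectors=vectors)


def random_harmonic_field(rng, mesh, n_harmonics=3, n_times=48, scale=1.0):
    shape = (mesh.n_vertices, 2 * n_harmonics + 1)
    cx = rng.normal(scale=scale, size=shape)
    cy = rng.normal(scale=scale, size=shape)
    return harmonic_field(mesh, cx, cy, n_times=n_times)


@pytest.fixture
def patch():
    return flat_patch_mesh(4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_theta=24, n_z=32)


@pytest.fixture(scope="session")
def small_aneurysm(small_spec):
    return make_aneurysm_mesh(small_spec)
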