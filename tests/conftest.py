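import numpy as np
import pytest

from eegfwd.geometry import (LabeledTetMesh, MeshDensity, SphereModelSpec,
                             build_sphere_mesh, extract_interfaces,
                             three_layer_model)

COARSE3 = MeshDensity(n_surface=220, inner_layers=5, outer_layers=(1, 1))


@pytest.fixture(scope="session")
def spec3():
    return three_layer_model()


@pytest.fixture(scope="session")
def mesh3_coarse(spec3):
    return build_sphere_mesh(spec3, density=COARSE3, seed=3)


@pytest.fixture(scope="session")
def surfaces3_coarse(mesh3_coarse):
    return extract_interfaces(mesh3_coarse)


@pytest.fixture(scope="session")
def spec1():
    """Homogeneous single-shell head (radius 9.2 cm)."""
    return SphereModelSpec(
        radii_cm=(9.2,), conductivity_intervals=((0.33, 0.33),),
        layer_names=("head",))


@pytest.fixture(scope="session")
def mesh1_coarse(spec1):
    return build_sphere_mesh(
        spec1, density=MeshDensity(n_surface=450, inner_layers=7), seed=2)


@pytest.fixture(scope="session")
def cube_mesh():
    """Unit cube split into 6 tets (Kuhn decomposition); 12 boundary faces."""
    corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                        for z in (0, 1)], float)
    # vertices indexed by binary (x y z): path permutations 000 -> 111
    def vid(x, y, z):
        return 4 * x + 2 * y + z
    perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
    tets = []
    for perm in perms:
        path = [np.zeros(3, int)]
        for axis in perm:
            nxt = path[-1].copy()
            nxt[axis] = 1
            path.append(nxt)
        tets.append([vid(*p) for p in path])
    mesh = LabeledTetMesh(nodes=corners, tets=np.array(tets),
                          region_label=np.ones(6, int))
    mesh.orient_positive()
    return mesh


def rdm_of(a, b):
    a = a - a.mean()
    b = b - b.mean()
    return float(np.linalg.norm(a / np.linalg.norm(a) - b / np.linalg.norm(b)))


def mag_of(a, b):
    return float(np.linalg.norm(b - b.mean()) / np.linalg.norm(a - a.mean()))


def closed_form_homogeneous_radial(R, sigma, b, M, pts):
    """Scalp potential of a radial dipole in a homogeneous sphere (closed
    form from the summed Legendre series; independent of the package)."""
    r = np.linalg.norm(pts, axis=1)
    t = np.clip(pts[:, 2] / r, -1.0, 1.0)
    x = b / R
    if x == 0:
        return M / (4 * np.pi * sigma * R**2) * 3 * t
    s = np.sqrt(1.0 - 2.0 * x * t + x * x)
    return M / (4 * np.pi * sigma * R**2) * (
        2.0 * (t - x) / s**3 + (1.0 / s - 1.0) / x)


def series_homogeneous_tangential(R, sigma, b, M, pts, N=2000):
    """Scalp potential of an x-oriented dipole at (0,0,b): direct series."""
    r = np.linalg.norm(pts, axis=1)
    t = np.clip(pts[:, 2] / r, -1.0, 1.0)
    rho = np.sqrt(pts[:, 0]**2 + pts[:, 1]**2)
    cphi = np.where(rho > 0, pts[:, 0] / np.where(rho > 0, rho, 1.0), 0.0)
    s = np.sqrt(np.clip(1 - t * t, 0, None))
    x = b / R
    tot = np.zeros(len(pts))
    pm1 = np.zeros_like(t)
    p = s.copy()
    for n in range(1, N + 1):
        tot += (2 * n + 1) / n * x**(n - 1) * p
        pm1, p = p, ((2 * n + 1) * t * p - (n + 1) * pm1) / n
    return M / (4 * np.pi * sigma * R * R) * tot * cphi
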