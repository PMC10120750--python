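import numpy as np
import pytest
import trimesh

from surfmap.mesh import SurfaceMesh, VolumeImage


@pytest.fixture(scope="session")
def icosphere():
    ico = trimesh.creation.icosphere(subdivisions=3)
    return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def icosphere4():
    ico = trimesh.creation.icosphere(subdivisions=4)
    return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def torus_mesh():
    tor = trimesh.creation.torus(major_radius=3, minor_radius=1,
                                 major_sections=48, minor_sections=24)
    return SurfaceMesh(np.asarray(tor.vertices), np.asarray(tor.faces))


@pytest.fixture(scope="session")
def ball_binary():
    """Solid ball radius 20 voxels in a 64^3 grid."""
    idx = np.indices((64, 64, 64)).reshape(3, -1).T
    b = (np.linalg.norm(idx - 31.5, axis=1) < 20).reshape(64, 64, 64)
    return VolumeImage(b.astype(np.uint8))


@pytest.fixture(scope="session")
def bumpy_phantom():
    """Seeded 5-bleb phantom at test scale (~2.5k vertices)."""
    from surfmap.phantoms import default_bleb_spec, make_cell_mesh

    spec = default_bleb_spec(n_blebs=5, base_radius=20, seed=3,
                             subdivisions=4, height=6, width=0.4)
    mesh, labels = make_cell_mesh(spec)
    return mesh, labels


@pytest.fixture(scope="session")
def bumpy_sphere_param(bumpy_phantom):
    """Conformal spherical parameterization of the bumpy phantom (shared
    across tests because the flow dominates runtime)."""
    from surfmap.sphere import conformal_sphere_map

    mesh, _ = bumpy_phantom
    return conformal_sphere_map(mesh)


@pytest.fixture(scope="session")
def bump_scene():
    """Synthetic topographic scene: floor at d=8 with 5 hemispherical bumps
    (r=6) at known (u, v) positions, with an identity lookup space."""
    from surfmap.topography import TopographicSpace, topographic_mesh

    D, R, C = 24, 64, 128
    b = np.zeros((D, R, C), dtype=bool)
    b[:8] = True
    centers = [(16, 20), (16, 60), (16, 100), (44, 40), (44, 85)]
    rr, cc = np.mgrid[:R, :C]
    for (r0, c0) in centers:
        dist2 = (rr - r0) ** 2 + (cc - c0) ** 2
        for k in range(8, 15):
            rad2 = 6.0**2 - (k - 8) ** 2
            if rad2 > 0:
                b[k][dist2 <= rad2] = True
    lookup = np.stack(np.meshgrid(
        np.arange(D, dtype=float), np.arange(R, dtype=float),
        np.arange(C, dtype=float), indexing="ij"), axis=-1)
    ts = TopographicSpace(lookup=lookup, alpha=1.0, D_in=0, D_out=D - 1)
    tb = VolumeImage(b.astype(np.uint8))
    tm = topographic_mesh(tb, ts, target_fraction=0.5)
    return {"binary": tb, "space": ts, "mesh": tm, "centers": centers,
            "floor": 8, "bump_radius": 6}


def make_sheet(nu=30, nv=40, bump_height=0.0, bump_sigma=4.0):
    """Rectangular (d, u, v) sheet mesh with an optional Gaussian bump."""
    uu, vv = np.meshgrid(np.arange(nu, dtype=float), np.arange(nv, dtype=float),
                         indexing="ij")
    d = bump_height * np.exp(-(((uu - nu / 2) ** 2 + (vv - nv / 2) ** 2)
                               / (2 * bump_sigma**2)))
    verts = np.stack([d.ravel(), uu.ravel(), vv.ravel()], axis=1)
    idx = np.arange(nu * nv).reshape(nu, nv)
    f1 = np.stack([idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(), idx[1:, 1:].ravel()], axis=1)
    f2 = np.stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()], axis=1)
    return SurfaceMesh(verts, np.vstack([f1, f2]))
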