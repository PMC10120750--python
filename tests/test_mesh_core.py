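"""Mesh data model, I/O, discrete operators, curvature, topology, quality."""

import numpy as np
import pytest

from surfmap.mesh import (
    MeshParseError, SurfaceMesh, VolumeImage, build_operators, euler_genus,
    gaussian_curvature, mean_curvature_from_sdf, radius_ratio, read_mesh,
    remesh, voxelize, write_mesh,
)


TETRA = SurfaceMesh(
    np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]),
    np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]]),
)


class TestIO:
    def test_obj_roundtrip_bit_identical(self, tmp_path):
        p = tmp_path / "t.obj"
        write_mesh(TETRA, p)
        back = read_mesh(p)
        assert np.array_equal(back.vertices, TETRA.vertices)
        assert np.array_equal(back.faces, TETRA.faces)

    def test_obj_one_based_indices(self, tmp_path):
        p = tmp_path / "t.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        m = read_mesh(p)
        assert m.faces.tolist() == [[0, 1, 2]]

    def test_ply_vertex_quality_field(self, tmp_path):
        p = tmp_path / "t.ply"
        m = TETRA.copy()
        m.vertex_fields["quality"] = np.array([0.1, 0.2, 0.3, 0.4])
        write_mesh(m, p)
        back = read_mesh(p)
        assert "quality" in back.vertex_fields
        np.testing.assert_allclose(back.vertex_fields["quality"],
                                   [0.1, 0.2, 0.3, 0.4], atol=1e-6)

    def test_malformed_file_names_line(self, tmp_path):
        p = tmp_path / "bad.obj"
        p.write_text("v 0 0 0\nv oops 0 0\n")
        with pytest.raises(MeshParseError, match="line 2"):
            read_mesh(p)


class TestOperators:
    def test_cotangent_weights_equilateral_pair(self):
        # two equilateral unit triangles sharing edge (0, 1):
        # w_ij = 0.5*(cot60 + cot60) = 1/sqrt(3)
        h = np.sqrt(3) / 2
        m = SurfaceMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0.5, h, 0], [0.5, -h, 0]]),
            np.array([[0, 1, 2], [0, 3, 1]]),
        )
        L = build_operators(m).laplacian
        assert L[0, 1] == pytest.approx(1 / np.sqrt(3), rel=1e-12)

    def test_laplacian_annihilates_constants(self, icosphere):
        L = build_operators(icosphere).laplacian
        assert np.abs(L @ np.ones(icosphere.n_vertices)).max() < 1e-10

    def test_mass_trace_equals_area(self, icosphere):
        M = build_operators(icosphere).mass
        assert M.diagonal().sum() == pytest.approx(icosphere.area(), rel=1e-12)

    def test_laplacian_negative_semidefinite_direction(self, icosphere):
        L = build_operators(icosphere).laplacian
        x = icosphere.vertices[:, 0]
        assert x @ (L @ x) <= 0

    def test_robust_variant_selectable(self, icosphere):
        ops = build_operators(icosphere, "robust")
        assert ops.kind == "robust"
        assert np.abs(ops.laplacian @ np.ones(icosphere.n_vertices)).max() < 1e-8


class TestCurvatureTopology:
    def test_gauss_bonnet_sphere(self, icosphere):
        assert gaussian_curvature(icosphere).sum() == pytest.approx(4 * np.pi, abs=1e-6)

    def test_gauss_bonnet_torus(self, torus_mesh):
        assert gaussian_curvature(torus_mesh).sum() == pytest.approx(0.0, abs=1e-6)

    def test_cube_corner_deficit(self):
        # vertex 0 with three mutually orthogonal right-angle triangles
        m = SurfaceMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]),
            np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1]]),
        )
        K = gaussian_curvature(m)
        # the fan closes around vertex 0 (interior): deficit 2*pi - 3*pi/2
        assert K[0] == pytest.approx(np.pi / 2, abs=1e-12)

    def test_euler_genus_sphere(self, icosphere):
        chi, g, b, wt = euler_genus(icosphere)
        assert (chi, g, b, wt) == (2, 0, 0, True)

    def test_euler_genus_torus(self, torus_mesh):
        chi, g, b, wt = euler_genus(torus_mesh)
        assert (chi, g) == (0, 1) and wt

    def test_open_tetrahedron_one_boundary(self):
        m = SurfaceMesh(TETRA.vertices, TETRA.faces[:-1])
        chi, g, b, wt = euler_genus(m)
        assert (chi, g, b, wt) == (1, 0, 1, False)

    def test_mean_curvature_ball(self, ball_binary):
        H = mean_curvature_from_sdf(ball_binary)
        idx = np.indices(ball_binary.shape).reshape(3, -1).T
        near = np.abs(np.linalg.norm(idx - 31.5, axis=1) - 20) < 1
        val = H.reshape(-1)[near].mean()
        assert val == pytest.approx(1 / 20, rel=0.10)

    def test_mean_curvature_scale_law(self):
        def ball(r):
            idx = np.indices((64, 64, 64)).reshape(3, -1).T
            return VolumeImage(
                (np.linalg.norm(idx - 31.5, axis=1) < r).reshape(64, 64, 64).astype(np.uint8))

        def surf_H(r):
            H = mean_curvature_from_sdf(ball(r))
            idx = np.indices((64, 64, 64)).reshape(3, -1).T
            near = np.abs(np.linalg.norm(idx - 31.5, axis=1) - r) < 1
            return H.reshape(-1)[near].mean()

        assert surf_H(10) / surf_H(20) == pytest.approx(2.0, rel=0.15)

    def test_mean_curvature_flat_slab(self):
        b = np.zeros((40, 40, 40), dtype=np.uint8)
        b[:20] = 1
        H = mean_curvature_from_sdf(VolumeImage(b))
        assert abs(H[19:21, 10:30, 10:30]).max() < 0.02

    def test_empty_binary_errors(self):
        with pytest.raises(ValueError):
            mean_curvature_from_sdf(VolumeImage(np.zeros((8, 8, 8), dtype=np.uint8)))


@pytest.fixture(scope="module")
def sphere_r15():
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=4, radius=15)
    return SurfaceMesh(np.asarray(ico.vertices) + 20, np.asarray(ico.faces))


class TestVoxelizeRemesh:
    def test_ball_volume(self, sphere_r15):
        vol = voxelize(sphere_r15, dilation_radius=3)
        assert vol.data.sum() == pytest.approx(4 / 3 * np.pi * 15**3, rel=0.05)

    def test_dilation_erosion_near_cancellation(self, sphere_r15):
        v0 = voxelize(sphere_r15, dilation_radius=0).data.sum()
        v5 = voxelize(sphere_r15, dilation_radius=5).data.sum()
        assert abs(v5 - v0) / v0 < 0.03

    def test_hole_closed_by_dilation(self, bumpy_phantom):
        from surfmap.phantoms import PhantomSpec, make_cell_mesh

        spec = PhantomSpec(base_radius=15, subdivisions=4,
                           holes=[{"direction": (0, 0, 1), "angular_radius": 0.08}])
        mesh, _ = make_cell_mesh(spec)
        assert not euler_genus(mesh)[3]  # not watertight
        vol = voxelize(mesh, dilation_radius=3)
        out = remesh(vol, 0.5)
        assert euler_genus(out)[1] == 0

    def test_open_sheet_not_closable(self):
        from tests.conftest import make_sheet

        sheet = make_sheet(20, 20)
        with pytest.raises(ValueError, match="non-closable"):
            voxelize(sheet, dilation_radius=0)

    def test_remesh_quality_genus_gauss_bonnet(self, sphere_r15):
        vol = voxelize(sphere_r15, dilation_radius=3)
        m = remesh(vol, 0.5)
        chi, g, b, wt = euler_genus(m)
        assert g == 0 and wt
        assert np.median(radius_ratio(m)) > 0.7
        assert gaussian_curvature(m).sum() == pytest.approx(4 * np.pi, abs=1e-5)

    def test_remesh_deterministic(self, sphere_r15):
        vol = voxelize(sphere_r15, dilation_radius=3)
        m1 = remesh(vol, 0.5)
        m2 = remesh(vol, 0.5)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(m1.faces, m2.faces)

    def test_remesh_volume_conservation(self, bumpy_phantom):
        mesh, _ = bumpy_phantom
        vol = voxelize(mesh, dilation_radius=3)
        m = remesh(vol, 0.5)
        assert m.enclosed_volume() == pytest.approx(float(vol.data.sum()), rel=0.03)

    def test_remesh_bad_fraction(self, sphere_r15):
        vol = voxelize(sphere_r15, dilation_radius=3)
        with pytest.raises(ValueError):
            remesh(vol, 1.5)


class TestRadiusRatio:
    def test_equilateral_is_one(self):
        tri = np.array([[[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]]])
        assert radius_ratio(tri)[0] == pytest.approx(1.0, abs=1e-12)

    def test_right_isoceles_formula(self):
        # legs 1, 1, hypotenuse sqrt(2): r_in = (a + b - c)/2, r_circ = c/2
        tri = np.array([[[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]])
        c = np.sqrt(2)
        expect = 2 * ((2 - c) / 2) / (c / 2)
        assert radius_ratio(tri)[0] == pytest.approx(expect, rel=1e-12)

    def test_sliver_near_zero(self):
        tri = np.array([[[0, 0, 0], [1, 0, 0], [0.5, 1e-4, 0]]])
        assert radius_ratio(tri)[0] < 0.05

    def test_degenerate_is_zero(self):
        tri = np.array([[[0, 0, 0], [1, 0, 0], [2, 0, 0.0]]])
        assert radius_ratio(tri)[0] == 0.0
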