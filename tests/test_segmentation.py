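"""Topography-guided protrusion segmentation, refinement and decomposition."""

import numpy as np
import pytest
import trimesh
from scipy.spatial import Delaunay

from surfmap.mesh import SurfaceMesh, VolumeImage, boundary_loops, euler_genus
from surfmap.segmentation import (
    AffinityConfig, als_baseline_1d, als_reference_surface,
    approximate_height_image, binary_protrusions, cap_boundary_loop,
    cartesian_decompose, combined_affinity, decompose_volume, extract_submesh,
    instance_protrusions, label_spreading, mesh_components, refine_blebs,
    unwrap_submesh_to_square,
)
from surfmap.topography import TopographicSpace, topographic_mesh

SMALL_CFG = AffinityConfig(min_area_pre=20, min_area_post=50, n_iter=5)


class TestHeightImage:
    def test_solid_slab(self):
        b = np.zeros((20, 8, 9), dtype=bool)
        b[:10] = True
        assert np.unique(approximate_height_image(b)).tolist() == [10.0]

    def test_longest_run_wins(self):
        col = np.zeros((20, 1, 1), dtype=bool)
        col[0:3] = True
        col[5:10] = True
        assert approximate_height_image(col)[0, 0] == 5.0

    def test_empty_column_zero(self):
        b = np.zeros((5, 2, 2), dtype=bool)
        assert (approximate_height_image(b) == 0).all()

    def test_bump_phantom_height(self, bump_scene):
        hi = approximate_height_image(bump_scene["binary"].data.astype(bool))
        r0, c0 = bump_scene["centers"][0]
        assert hi[r0, c0] >= bump_scene["floor"] + 4  # floor + bump top


class TestALS:
    def test_flat_is_fixed_point(self):
        flat = np.full((40, 60), 5.0)
        rf = als_reference_surface(flat, downsample=2)
        np.testing.assert_allclose(rf.d_ref, 5.0, atol=1e-9)

    def test_spike_suppressed(self):
        img = np.full((40, 60), 5.0)
        img[18:22, 28:32] = 30.0
        rf = als_reference_surface(img, downsample=2)
        assert rf.d_ref[18:22, 28:32].mean() < 12.0  # far below the spike
        assert rf.d_ref[18:22, 28:32].mean() >= 5.0  # above the flat level

    def test_2d_matches_1d_oracle_on_separable_profile(self):
        y = np.full(64, 3.0)
        y[30:34] = 20.0
        z1 = als_baseline_1d(y)
        rf = als_reference_surface(np.tile(y, (64, 1)), downsample=1)
        mid = rf.d_ref[32]
        assert np.corrcoef(z1, mid)[0, 1] > 0.999
        np.testing.assert_allclose(mid, z1, atol=0.05)

    def test_two_level_terrain_tracks_envelope(self):
        img = np.full((40, 60), 3.0)
        img[:, 30:] = 12.0
        rf = als_reference_surface(img, downsample=2)
        assert abs(rf.d_ref[:, :15].mean() - 3.0) < 0.5
        assert abs(rf.d_ref[:, 48:].mean() - 12.0) < 0.5


class TestLabelSpreading:
    def test_never_creates_labels(self, icosphere):
        A = combined_affinity(icosphere)
        seeds = np.zeros(icosphere.n_vertices, dtype=np.int64)
        seeds[:5] = 2
        seeds[10:15] = 7
        out = label_spreading(A, seeds, n_iter=10)
        assert set(np.unique(out)) <= {0, 2, 7}

    def test_unlabeled_background_lets_labels_expand(self, icosphere):
        A = combined_affinity(icosphere)
        seeds = np.zeros(icosphere.n_vertices, dtype=np.int64)
        seeds[0] = 1
        out = label_spreading(A, seeds, n_iter=10, clamp=0.99,
                              background_is_class=False)
        assert out[0] == 1
        assert (out == 1).sum() > 1  # label spread beyond the seed

    def test_two_class_background_competes(self, icosphere):
        A = combined_affinity(icosphere)
        seeds = np.zeros(icosphere.n_vertices, dtype=np.int64)
        seeds[icosphere.vertices[:, 2] > 0.9] = 1
        out = label_spreading(A, seeds, n_iter=10, clamp=0.99)
        # background class holds the far hemisphere
        assert (out[icosphere.vertices[:, 2] < 0] == 0).all()


class TestBinarySegmentation:
    def test_bumps_found_plane_background(self, bump_scene):
        hi = approximate_height_image(bump_scene["binary"].data.astype(bool))
        rf = als_reference_surface(hi, downsample=4)
        fg = binary_protrusions(bump_scene["mesh"], rf, SMALL_CFG)
        ncomp, _ = mesh_components(bump_scene["mesh"].mesh, fg)
        assert ncomp == 5
        assert 0.05 < fg.mean() < 0.5

    def test_flat_plane_is_empty(self):
        D, R, C = 12, 32, 48
        b = np.zeros((D, R, C), dtype=bool)
        b[:6] = True
        lookup = np.stack(np.meshgrid(
            np.arange(D, dtype=float), np.arange(R, dtype=float),
            np.arange(C, dtype=float), indexing="ij"), axis=-1)
        ts = TopographicSpace(lookup=lookup, alpha=1.0, D_in=0, D_out=D - 1)
        tm = topographic_mesh(VolumeImage(b.astype(np.uint8)), ts, 0.5)
        hi = approximate_height_image(b)
        rf = als_reference_surface(hi, downsample=2)
        with pytest.warns(UserWarning, match="empty"):
            fg = binary_protrusions(tm, rf, SMALL_CFG)
        assert not fg.any()

    def test_flat_reference_undersegments_on_curved_cortex(self):
        """Flat (d_ref = 0) reference merges protrusions when the cortex
        itself undulates; the ALS reference separates them."""
        D, R, C = 28, 48, 96
        b = np.zeros((D, R, C), dtype=bool)
        rr, cc = np.mgrid[:R, :C]
        floor = 8 + 6 * np.sin(2 * np.pi * cc / C)  # undulating cortex
        dd = np.arange(D)[:, None, None]
        b |= dd < floor[None]
        centers = [(24, 20), (24, 50), (24, 80)]
        for r0, c0 in centers:
            dist2 = (rr - r0) ** 2 + (cc - c0) ** 2
            base = floor[r0, c0]
            for k in range(int(base), int(base) + 6):
                rad2 = 5.0**2 - (k - base) ** 2
                if rad2 > 0:
                    b[k][dist2 <= rad2] = True
        lookup = np.stack(np.meshgrid(
            np.arange(D, dtype=float), np.arange(R, dtype=float),
            np.arange(C, dtype=float), indexing="ij"), axis=-1)
        ts = TopographicSpace(lookup=lookup, alpha=1.0, D_in=0, D_out=D - 1)
        tm = topographic_mesh(VolumeImage(b.astype(np.uint8)), ts, 0.5)
        hi = approximate_height_image(b)
        rf = als_reference_surface(hi, downsample=4)
        fg_als = binary_protrusions(tm, rf, SMALL_CFG)
        fg_flat = binary_protrusions(tm, None, SMALL_CFG)
        n_als, _ = mesh_components(tm.mesh, fg_als)
        n_flat, _ = mesh_components(tm.mesh, fg_flat)
        assert n_als >= 3
        assert n_flat < n_als  # under-segmentation with the flat reference


class TestInstanceSegmentation:
    def test_five_bumps_five_instances(self, bump_scene):
        hi = approximate_height_image(bump_scene["binary"].data.astype(bool))
        rf = als_reference_surface(hi, downsample=4)
        vlab, _ = instance_protrusions(
            bump_scene["binary"], bump_scene["mesh"], rf,
            min_voxels=30, min_area=20, affinity_cfg=SMALL_CFG,
            diffusion_iters=5)
        assert vlab.max() == 5

    def test_deterministic(self, bump_scene):
        hi = approximate_height_image(bump_scene["binary"].data.astype(bool))
        rf = als_reference_surface(hi, downsample=4)
        args = dict(min_voxels=30, min_area=20, affinity_cfg=SMALL_CFG,
                    diffusion_iters=5)
        a, _ = instance_protrusions(bump_scene["binary"], bump_scene["mesh"], rf, **args)
        b, _ = instance_protrusions(bump_scene["binary"], bump_scene["mesh"], rf, **args)
        assert np.array_equal(a, b)

    def test_labels_respect_height_reference(self, bump_scene):
        """Labeled vertices sit above the reference surface (internal
        structures below d_ref can never be labeled)."""
        from scipy import ndimage as ndi

        hi = approximate_height_image(bump_scene["binary"].data.astype(bool))
        rf = als_reference_surface(hi, downsample=4)
        vlab, _ = instance_protrusions(
            bump_scene["binary"], bump_scene["mesh"], rf,
            min_voxels=30, min_area=20, affinity_cfg=SMALL_CFG, diffusion_iters=5)
        m = bump_scene["mesh"].mesh
        dref_at = ndi.map_coordinates(rf.d_ref, m.vertices[:, 1:].T, order=1)
        h = m.vertices[:, 0] - dref_at
        assert h[vlab > 0].mean() > h[vlab == 0].mean()


class TestSubmeshUnwrap:
    def test_flat_disk_near_identity(self):
        ang = np.linspace(0, 2 * np.pi, 33)[:-1]
        pts = np.array([(0.0, 0.0)] + [
            (np.cos(a) * r, np.sin(a) * r) for r in (0.33, 0.66, 1.0) for a in ang])
        tri = Delaunay(pts)
        sub = SurfaceMesh(np.c_[pts, np.zeros(len(pts))],
                          tri.simplices.astype(np.int64))
        sq = unwrap_submesh_to_square(sub, N=64)
        assert sq.n_flipped() == 0
        # near-isometric: 2D areas proportional to 3D areas
        from surfmap.segmentation import _tri_area_2d

        a2 = _tri_area_2d(sq.disk_xy, sub.faces)
        a3 = sub.face_areas()
        lam = (a3 / a3.sum()) / (a2 / a2.sum())
        assert abs(np.mean(lam) - 1) < 0.1

    def test_hemisphere_cap_bijective(self, icosphere):
        cap, _ = extract_submesh(icosphere, icosphere.vertices[:, 2] > 0.05)
        sq = unwrap_submesh_to_square(cap, N=64)
        assert sq.n_flipped() == 0

    def test_relaxation_improves_area_distortion(self, icosphere):
        from surfmap.segmentation import _tri_area_2d, harmonic_disk_map

        cap, _ = extract_submesh(icosphere, icosphere.vertices[:, 2] > -0.5)
        xy0 = harmonic_disk_map(cap)
        sq = unwrap_submesh_to_square(cap, N=64)
        a3 = cap.face_areas()
        f3 = a3 / a3.sum()

        def obj(xy):
            a2 = _tri_area_2d(xy, cap.faces)
            lam = f3 / (a2 / a2.sum())
            return np.abs(np.log(lam)).mean()

        assert obj(sq.disk_xy) < obj(xy0)

    def test_multi_boundary_rejected(self, icosphere):
        ring, _ = extract_submesh(
            icosphere, np.abs(icosphere.vertices[:, 2]) < 0.4)
        with pytest.raises(ValueError):
            unwrap_submesh_to_square(ring)


@pytest.fixture(scope="module")
def fused_blebs():
    """Two fused hemispheres on a sphere under a single label."""
    from surfmap.phantoms import PhantomSpec, Protrusion, make_cell_mesh

    d1 = np.array([0.0, 0.0, 1.0])
    d2 = np.array([0.0, np.sin(0.5), np.cos(0.5)])
    spec = PhantomSpec(base_radius=20, subdivisions=4, protrusions=[
        Protrusion("bleb", tuple(d1), 7.0, 0.26),
        Protrusion("bleb", tuple(d2), 7.0, 0.26)], allow_overlap=True)
    mesh, labels = make_cell_mesh(spec)
    fused = (labels > 0).astype(np.int64)
    return mesh, fused


class TestRefinement:
    def test_fused_pair_split(self, fused_blebs):
        mesh, fused = fused_blebs
        out = refine_blebs(mesh, fused, N=96, min_area=5, diffusion_iters=5)
        assert len([c for c in np.unique(out) if c > 0]) == 2

    def test_single_clean_bleb_unchanged(self, bumpy_phantom):
        mesh, labels = bumpy_phantom
        single = (labels == 1).astype(np.int64)
        out = refine_blebs(mesh, single, N=96, min_area=5, diffusion_iters=5)
        assert len([c for c in np.unique(out) if c > 0]) == 1

    def test_total_labeled_area_conserved(self, fused_blebs):
        mesh, fused = fused_blebs
        out = refine_blebs(mesh, fused, N=96, min_area=5, diffusion_iters=5)
        va = mesh.vertex_areas()
        before = va[fused > 0].sum()
        after = va[out > 0].sum()
        assert abs(after - before) / before < 0.15


class TestDecomposition:
    def test_volume_partition_conservation(self, bump_scene):
        hi = approximate_height_image(bump_scene["binary"].data.astype(bool))
        rf = als_reference_surface(hi, downsample=4)
        vlab, _ = instance_protrusions(
            bump_scene["binary"], bump_scene["mesh"], rf,
            min_voxels=30, min_area=20, affinity_cfg=SMALL_CFG, diffusion_iters=5)
        dec = decompose_volume(bump_scene["space"], bump_scene["binary"],
                               bump_scene["mesh"], vlab)
        total = float(bump_scene["binary"].data.sum())
        got = dec["cortex_volume"].data.sum() + sum(dec["protrusion_volumes"].values())
        assert abs(got - total) / total < 0.02

    def test_hemisphere_volume_analytic(self, bump_scene):
        hi = approximate_height_image(bump_scene["binary"].data.astype(bool))
        rf = als_reference_surface(hi, downsample=4)
        vlab, _ = instance_protrusions(
            bump_scene["binary"], bump_scene["mesh"], rf,
            min_voxels=30, min_area=20, affinity_cfg=SMALL_CFG, diffusion_iters=5)
        dec = decompose_volume(bump_scene["space"], bump_scene["binary"],
                               bump_scene["mesh"], vlab)
        r = bump_scene["bump_radius"]
        expect = 2 / 3 * np.pi * r**3
        vols = sorted(dec["protrusion_volumes"].values())
        # median protrusion volume close to the analytic hemisphere
        assert np.median(vols) == pytest.approx(expect, rel=0.30)

    def test_cortex_smooth_under_removed_bump(self, bump_scene):
        hi = approximate_height_image(bump_scene["binary"].data.astype(bool))
        rf = als_reference_surface(hi, downsample=4)
        vlab, _ = instance_protrusions(
            bump_scene["binary"], bump_scene["mesh"], rf,
            min_voxels=30, min_area=20, affinity_cfg=SMALL_CFG, diffusion_iters=5)
        dec = decompose_volume(bump_scene["space"], bump_scene["binary"],
                               bump_scene["mesh"], vlab)
        d_img = dec["d_ref_image"]
        r0, c0 = bump_scene["centers"][0]
        under = d_img[r0 - 4:r0 + 5, c0 - 4:c0 + 5]
        # inpainted cortex height stays near the floor, no spike
        assert abs(under.mean() - bump_scene["floor"]) < 2.5
        assert under.max() - under.min() < 4.0


class TestCartesianDecompose:
    def test_planar_loop_flat_cap(self):
        ang = np.linspace(0, 2 * np.pi, 33)[:-1]
        pts = np.vstack([[(np.cos(a) * r, np.sin(a) * r) for a in ang]
                         for r in (1.0, 0.6)])
        tri = Delaunay(pts)
        ann = SurfaceMesh(np.c_[pts, np.zeros(len(pts))],
                          tri.simplices.astype(np.int64))
        loop = np.asarray(boundary_loops(ann)[0])
        cap = cap_boundary_loop(ann, loop, subdivisions=2)
        assert np.abs(cap.vertices[:, 2]).max() < 1e-9

    def test_hemisphere_cap_area_bound(self, icosphere):
        sub, _ = extract_submesh(icosphere, icosphere.vertices[:, 2] > 0.0)
        loop = np.asarray(boundary_loops(sub)[0])
        cap = cap_boundary_loop(sub, loop, subdivisions=2)
        rim_r = np.linalg.norm(icosphere.vertices[loop][:, :2], axis=1).mean()
        assert cap.area() >= 0.95 * np.pi * rim_r**2

    def test_closed_protrusions_and_agreement(self, bumpy_phantom):
        mesh, labels = bumpy_phantom
        prot, cortex = cartesian_decompose(mesh, labels)
        assert len(prot) == 5
        for m in prot.values():
            chi, g, b, wt = euler_genus(m)
            assert b == 0
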