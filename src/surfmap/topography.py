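"""Topographic (d, u, v) coordinate space construction and resampling.

The (u, v)-parameterized reference surface is propagated through Cartesian
space along the steepest gradient of the signed distance function of the
reference in equidistant steps of ``alpha`` voxels — outward (d > 0) far
enough to encapsulate the full cell surface, and inward (d < 0) a chosen
number of steps.  The resulting (D x rows x cols) lookup table of Cartesian
coordinates defines a bijection (d, u, v) <-> (x, y, z): volumes are pulled
into topographic space by trilinear interpolation at the lookup coordinates
and topographic meshes are pushed back by interpolating the lookup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh, VolumeImage, remesh, marching_cubes_mesh


@dataclass
class TopographicSpace:
    lookup: np.ndarray          # (D, rows, cols, 3) Cartesian coordinates
    alpha: float
    D_in: int
    D_out: int
    n_flagged: int = 0          # pixels with non-monotone propagation

    @property
    def d_zero_index(self) -> int:
        return self.D_in

    @property
    def shape(self):
        return self.lookup.shape[:3]

    def d_of_index(self, index):
        return (np.asarray(index, dtype=float) - self.D_in) * self.alpha


@dataclass
class TopographicMesh:
    mesh: SurfaceMesh            # vertices in (d-index, row, col) grid coords
    cartesian_twin: np.ndarray   # matched (n, 3) Cartesian coordinates

    def twin_mesh(self) -> SurfaceMesh:
        return SurfaceMesh(self.cartesian_twin.copy(), self.mesh.faces.copy())


def _smooth_sheet(sheet, mode: str = "box5"):
    """Per-iteration smoothing of a propagated (rows, cols, 3) sheet.

    ``box5``: separable uniform filter, window 5 (periodic in u); ``robust``:
    heavier Gaussian smoothing (sigma derived from factor 50 on the larger
    grid dimension) for noisy propagation."""
    if mode is None or mode == "none":
        return sheet
    out = np.empty_like(sheet)
    for k in range(3):
        if mode == "box5":
            out[..., k] = ndi.uniform_filter(sheet[..., k], size=5, mode="nearest")
        elif mode == "robust":
            out[..., k] = ndi.gaussian_filter(sheet[..., k], sigma=2.0, mode="nearest")
        else:
            raise ValueError(f"unknown smoothing mode {mode!r}")
    return out


def signed_distance_outside_positive(binary: np.ndarray) -> np.ndarray:
    b = binary.astype(bool)
    return ndi.distance_transform_edt(~b) - ndi.distance_transform_edt(b)


def build_topographic_space(
    ref_uv_lookup: np.ndarray,
    ref_binary: VolumeImage,
    alpha: float = 0.5,
    D_in: int | None = None,
    D_out: int | None = None,
    cell_binary: VolumeImage | None = None,
    smoothing: str = "box5",
) -> TopographicSpace:
    """Propagate the reference surface's UV lookup along grad(Phi).

    Phi is the signed distance of the voxelized reference surface (negative
    inside, so +d is outward).  ``D_out`` defaults to the number of steps
    needed to encapsulate ``cell_binary`` (or 1.5x the base radius estimate);
    ``D_in`` defaults to half the maximum internal distance.  Non-monotone
    trajectories (self-crossing) are flagged and smoothed.
    """
    sheet0 = np.asarray(ref_uv_lookup, dtype=float) + ref_binary.origin_offset
    phi = signed_distance_outside_positive(ref_binary.data)
    phi_s = ndi.gaussian_filter(phi, 1.0)
    g = np.stack(np.gradient(phi_s), axis=0)
    gn = np.linalg.norm(g, axis=0)
    gn[gn == 0] = 1.0
    g = g / gn
    shape = np.array(ref_binary.data.shape, dtype=float)

    def sample(vol, pts):
        return ndi.map_coordinates(vol, pts.reshape(-1, 3).T, order=1, mode="nearest").reshape(pts.shape[:-1])

    def step(sheet, sign):
        vel = np.stack([sample(g[k], sheet) for k in range(3)], axis=-1)
        return sheet + sign * alpha * vel

    if D_out is None:
        if cell_binary is not None:
            # distance of the farthest cell voxel outside the reference
            cell = cell_binary.data.astype(bool)
            dmax = float(phi[cell].max()) if cell.any() else 0.0
            D_out = int(np.ceil(max(dmax, alpha) / alpha)) + 2
        else:
            D_out = int(np.ceil(0.5 * min(shape) / alpha))
    if D_in is None:
        dt_in = ndi.distance_transform_edt(ref_binary.data.astype(bool))
        D_in = int(np.ceil(0.5 * dt_in.max() / alpha))

    outward = [sheet0]
    s = sheet0
    for _ in range(D_out):
        s = _smooth_sheet(step(s, +1.0), smoothing)
        s = np.clip(s, 0, shape - 1)
        outward.append(s)
    inward = []
    s = sheet0
    for _ in range(D_in):
        s = _smooth_sheet(step(s, -1.0), smoothing)
        s = np.clip(s, 0, shape - 1)
        inward.append(s)
    lookup = np.stack(inward[::-1] + outward, axis=0)
    # monotonicity audit along d of Phi at the lookup coordinates
    phi_along = np.stack([sample(phi, lookup[k]) for k in range(len(lookup))], axis=0)
    viol = (np.diff(phi_along, axis=0) < -1e-3).any(axis=0)
    n_flagged = int(viol.sum())
    if n_flagged:
        warnings.warn(f"{n_flagged} (u,v) trajectories are non-monotone in Phi; smoothed")
    lookup = lookup - ref_binary.origin_offset
    return TopographicSpace(lookup=lookup, alpha=alpha, D_in=D_in, D_out=D_out,
                            n_flagged=n_flagged)


def resample_volume(topo_space: TopographicSpace, volume: VolumeImage):
    """Pull a Cartesian volume into (d, u, v) by trilinear interpolation at
    the lookup coordinates; out-of-grid voxels become 0 (count reported)."""
    pts = (topo_space.lookup + volume.origin_offset).reshape(-1, 3)
    shape = np.array(volume.data.shape)
    oob = ((pts < 0) | (pts > shape - 1)).any(axis=1)
    vals = ndi.map_coordinates(volume.data.astype(float), pts.T, order=1, mode="constant", cval=0.0)
    out = vals.reshape(topo_space.shape)
    return VolumeImage(out), int(oob.sum())


def topographic_mesh(topo_binary: VolumeImage, topo_space: TopographicSpace,
                     target_fraction: float = 0.5, seed: int = 0) -> TopographicMesh:
    """Marching cubes (isovalue 0.5 after Gaussian sigma=1) + clustering
    remesh of the topographic binary; the Cartesian twin interpolates the
    lookup table at the (d, u, v) vertex coordinates."""
    if topo_binary.data.sum() == 0:
        raise ValueError("empty topographic binary")
    try:
        m = remesh(topo_binary, target_fraction, smooth_sigma=1.0, seed=seed)
    except ValueError:
        m = marching_cubes_mesh(topo_binary, smooth_sigma=1.0)
    twin = topo_to_cartesian(m.vertices, topo_space)
    return TopographicMesh(mesh=m, cartesian_twin=twin)


def topo_to_cartesian(points_duv: np.ndarray, topo_space: TopographicSpace) -> np.ndarray:
    """Forward map by trilinear interpolation of the lookup at (d-index, row,
    col) coordinates."""
    pts = np.asarray(points_duv, dtype=float).T
    return np.stack(
        [ndi.map_coordinates(topo_space.lookup[..., k], pts, order=1, mode="nearest")
         for k in range(3)],
        axis=1,
    )


def cartesian_to_topo(points_xyz: np.ndarray, topo_space: TopographicSpace,
                      refine_iters: int = 8):
    """Inverse map: nearest lookup node (KD-tree) + local Gauss-Newton
    refinement of the trilinear cell.  Returns (points_duv, out_of_extent)."""
    pts = np.asarray(points_xyz, dtype=float)
    D, R, C = topo_space.shape
    flat = topo_space.lookup.reshape(-1, 3)
    tree = cKDTree(flat)
    dist, idx = tree.query(pts)
    duv = np.stack(np.unravel_index(idx, (D, R, C)), axis=1).astype(float)
    # local refinement: gradient of the lookup wrt (d, r, c)
    grads = np.stack(np.gradient(topo_space.lookup, axis=(0, 1, 2)), axis=0)  # (3, D, R, C, 3)
    for _ in range(refine_iters):
        cur = topo_to_cartesian(duv, topo_space)
        resid = pts - cur
        J = np.stack(
            [np.stack(
                [ndi.map_coordinates(grads[a, ..., k], duv.T, order=1, mode="nearest")
                 for k in range(3)], axis=1)
             for a in range(3)], axis=2,
        )  # (n, 3 xyz, 3 duv)
        # least-squares step per point
        JT = np.einsum("nij->nji", J)
        A = np.einsum("nij,njk->nik", JT, J) + 1e-9 * np.eye(3)
        b = np.einsum("nij,nj->ni", JT, resid)
        try:
            stepv = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        duv = duv + np.clip(stepv, -1.0, 1.0)
        duv[:, 0] = np.clip(duv[:, 0], 0, D - 1)
        duv[:, 1] = np.clip(duv[:, 1], 0, R - 1)
        duv[:, 2] = np.clip(duv[:, 2], 0, C - 1)
    final = topo_to_cartesian(duv, topo_space)
    err = np.linalg.norm(final - pts, axis=1)
    spacing = max(topo_space.alpha, 1.0)
    out_of_extent = err > 2.0 * spacing
    return duv, out_of_extent
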