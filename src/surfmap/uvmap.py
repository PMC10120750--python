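"""Equirectangular (u, v) unwrapping of the spherical parameterization.

The unit sphere is sampled on an equirectangular grid — u (columns) spans
the azimuth over 2*pi, v (rows) the pole-to-pole arc over pi, rows:cols =
1:2 so the equatorial circumference / polar arc length ratio is preserved.
Each pixel direction is matched to a spherical triangle and stored as
barycentric weights, through which the vertices (or any vertex field) of
any mesh bijective to the sphere can be pulled back to the pixel grid.

A weighted PCA of the sphere vertices chooses the unwrapping (north-south)
axis: the smallest-variance eigenvector becomes the pole axis, so that
heavily weighted features land near the equator where equirectangular
distortion is least.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh


@dataclass
class RotationFrame:
    R: np.ndarray  # columns e1, e2, e3; proper rotation
    eigenvalues: np.ndarray  # descending

    def __post_init__(self):
        assert abs(np.linalg.det(self.R) - 1.0) < 1e-6


@dataclass
class UVGrid:
    """Rectangular grid of barycentric correspondence with a spherical mesh."""

    face_index: np.ndarray       # (rows, cols) int
    bary: np.ndarray             # (rows, cols, 3) weights, sum 1
    directions: np.ndarray       # (rows, cols, 3) unit pixel directions
    xyz_lookup: np.ndarray       # (rows, cols, 3) pulled-back partner coords
    rotation: RotationFrame | None = None
    duplicate_seam: bool = False
    n_fallback: int = 0
    fields: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.face_index.shape


def optimal_axis(sphere_vertices: np.ndarray, weights: np.ndarray) -> RotationFrame:
    """Unwrapping axis by weighted PCA of sphere vertex coordinates.

    The pole axis e3 is the smallest-eigenvalue eigenvector of the weighted
    second-moment (covariance) matrix; sign fixes on e1, e2 and e3 = e1 x e2
    make the frame a proper rotation.  Near-isotropic weight distributions
    fall back to the identity frame with a warning.
    """
    v = np.asarray(sphere_vertices, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    # second moment about the origin (sphere centre), not the weighted mean:
    # for a weight patch at direction n the small-variance axes are then
    # perpendicular to n, so the patch rotates to the equator
    A = (w[:, None, None] * np.einsum("ij,ik->ijk", v, v)).sum(axis=0) / w.sum()
    evals, evecs = np.linalg.eigh(A)  # ascending
    evals = evals[::-1]
    evecs = evecs[:, ::-1]  # columns now descending: e1, e2, e3
    spread = (evals[0] - evals[2]) / max(evals[0], 1e-300)
    if spread < 1e-6:
        warnings.warn("degenerate/isotropic weight covariance; using identity rotation")
        return RotationFrame(np.eye(3), evals)
    e1 = evecs[:, 0] * np.sign(evecs[0, 0] or 1.0)
    e2 = evecs[:, 1] * np.sign(evecs[1, 1] or 1.0)
    e3 = np.cross(e1, e2)
    R = np.stack([e1, e2, e3], axis=1)
    return RotationFrame(R, evals)


def _pixel_directions(N: int, duplicate_seam: bool):
    """Unit directions of the equirectangular grid (pole axis = +z).

    v=0 is the north pole (+e3); u=0 lies at the azimuth of +e1.  Rows use
    pixel centres; in seam-duplicating mode columns include both u=0 and
    u=2*pi endpoints (first and last column identical).
    """
    rows = N
    vv = (np.arange(rows) + 0.5) * np.pi / rows
    if duplicate_seam:
        cols = 2 * N + 1
        uu = np.arange(cols) * 2.0 * np.pi / (cols - 1)
    else:
        cols = 2 * N
        uu = (np.arange(cols) + 0.5) * 2.0 * np.pi / cols
    V, U = np.meshgrid(vv, uu, indexing="ij")
    d = np.stack(
        [np.sin(V) * np.cos(U), np.sin(V) * np.sin(U), np.cos(V)], axis=-1
    )
    return d


def _match_directions(dirs_flat, sphere_vertices, faces, k_candidates=12):
    """Match each unit direction to the spherical triangle its ray crosses.

    Candidate faces come from a KD-tree over face centroid directions; the
    barycentric coordinates of the central-ray / triangle-plane intersection
    decide membership.  Unmatched directions (numerical gaps) fall back to
    the nearest candidate face, counted and reported; candidate ties are
    broken by smallest face index (the KD-tree returns sorted distances and
    we scan in order).
    """
    tri = sphere_vertices[faces]
    cent = tri.mean(axis=1)
    cent /= np.linalg.norm(cent, axis=1, keepdims=True)
    tree = cKDTree(cent)
    k = min(k_candidates, len(faces))
    _, cand = tree.query(dirs_flat, k=k)
    if k == 1:
        cand = cand[:, None]
    npix = len(dirs_flat)
    a = tri[:, 0]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    face_out = np.full(npix, -1, dtype=np.int64)
    bary_out = np.zeros((npix, 3))
    remaining = np.arange(npix)
    for j in range(k):
        if not len(remaining):
            break
        f = cand[remaining, j]
        # Moller-Trumbore for ray o=0, dir d against triangle f
        d = dirs_flat[remaining]
        pv = np.cross(d, e2[f])
        det = np.einsum("ij,ij->i", e1[f], pv)
        ok = np.abs(det) > 1e-14
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tv = -a[f]
        u = np.einsum("ij,ij->i", tv, pv) * inv
        qv = np.cross(tv, e1[f])
        vpar = np.einsum("ij,ij->i", d, qv) * inv
        tpar = np.einsum("ij,ij->i", e2[f], qv) * inv
        hit = ok & (u >= -1e-9) & (vpar >= -1e-9) & (u + vpar <= 1 + 1e-9) & (tpar > 0)
        idx = remaining[hit]
        face_out[idx] = f[hit]
        bary_out[idx, 0] = 1.0 - u[hit] - vpar[hit]
        bary_out[idx, 1] = u[hit]
        bary_out[idx, 2] = vpar[hit]
        remaining = remaining[~hit]
    n_fallback = len(remaining)
    if n_fallback:
        f = cand[remaining, 0]
        face_out[remaining] = f
        # project onto the plane of the nearest face and clip
        d = dirs_flat[remaining]
        n = np.cross(e1[f], e2[f])
        denom = np.einsum("ij,ij->i", d, n)
        denom[denom == 0] = 1e-300
        t = np.einsum("ij,ij->i", a[f], n) / denom
        p = d * t[:, None]
        # barycentric by least squares on the two edge vectors
        w = p - a[f]
        d11 = np.einsum("ij,ij->i", e1[f], e1[f])
        d12 = np.einsum("ij,ij->i", e1[f], e2[f])
        d22 = np.einsum("ij,ij->i", e2[f], e2[f])
        w1 = np.einsum("ij,ij->i", w, e1[f])
        w2 = np.einsum("ij,ij->i", w, e2[f])
        det = d11 * d22 - d12 * d12
        det[det == 0] = 1e-300
        u = (d22 * w1 - d12 * w2) / det
        vv = (d11 * w2 - d12 * w1) / det
        b = np.stack([1 - u - vv, u, vv], axis=1)
        b = np.clip(b, 0, None)
        b /= b.sum(axis=1, keepdims=True)
        bary_out[remaining] = b
    bary_out = np.clip(bary_out, 0.0, None)
    bary_out /= bary_out.sum(axis=1, keepdims=True)
    return face_out, bary_out, n_fallback


def uv_map(
    sphere_param,
    N: int,
    rotation: RotationFrame | None = None,
    duplicate_seam: bool = False,
    partner: SurfaceMesh | None = None,
) -> UVGrid:
    """Equirectangular UV grid of a spherical parameterization.

    ``partner`` (default: the parameterization's source mesh) supplies the
    3D coordinates pulled back per pixel; any bijective partner works.
    """
    if N < 32:
        raise ValueError("N must be >= 32")
    sphere_vertices = sphere_param.sphere_vertices
    faces = sphere_param.source.faces
    dirs = _pixel_directions(N, duplicate_seam)
    if rotation is not None:
        dirs_world = dirs @ rotation.R.T  # map pole frame to world: d = R d'
    else:
        dirs_world = dirs
    flat = dirs_world.reshape(-1, 3)
    face_idx, bary, n_fb = _match_directions(flat, sphere_vertices, faces)
    shape = dirs.shape[:2]
    grid = UVGrid(
        face_index=face_idx.reshape(shape),
        bary=bary.reshape(shape + (3,)),
        directions=dirs_world.reshape(shape + (3,)),
        xyz_lookup=np.zeros(shape + (3,)),
        rotation=rotation,
        duplicate_seam=duplicate_seam,
        n_fallback=n_fb,
    )
    part = partner if partner is not None else sphere_param.source
    grid.xyz_lookup = pullback_field(grid, part.vertices, faces)
    return grid


def pullback_field(uv_grid: UVGrid, vertex_values: np.ndarray, faces: np.ndarray):
    """Interpolate per-vertex values (n,) or (n, k) onto the pixel grid with
    the stored barycentric weights."""
    vals = np.asarray(vertex_values)
    if len(vals) <= faces.max():
        raise ValueError("vertex count does not match the parameterization")
    fv = vals[faces[uv_grid.face_index]]  # (rows, cols, 3[, k])
    w = uv_grid.bary
    if fv.ndim == 4:
        return np.einsum("rcj,rcjk->rck", w, fv)
    return np.einsum("rcj,rcj->rc", w, fv)


def uv_to_xyz(uv_grid: UVGrid, points_uv: np.ndarray) -> np.ndarray:
    """Bilinear lookup of 3D coordinates at fractional (row, col) positions."""
    from scipy import ndimage as ndi

    pts = np.asarray(points_uv, dtype=float).T
    return np.stack(
        [ndi.map_coordinates(uv_grid.xyz_lookup[..., k], pts, order=1, mode="nearest")
         for k in range(3)],
        axis=1,
    )


def xyz_to_uv(uv_grid: UVGrid, points_xyz: np.ndarray) -> np.ndarray:
    """Nearest-pixel inverse of the UV lookup (sub-pixel via local refinement)."""
    look = uv_grid.xyz_lookup.reshape(-1, 3)
    tree = cKDTree(look)
    _, idx = tree.query(np.asarray(points_xyz, dtype=float))
    rows, cols = uv_grid.shape
    return np.stack(np.unravel_index(idx, (rows, cols)), axis=1).astype(float)
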