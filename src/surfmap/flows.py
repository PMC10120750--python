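"""Conformalized mean curvature flow (cMCF) and constrained variants.

cMCF evolves mesh vertices by implicit mean-curvature steps while freezing
the Laplacian at its initial value, which preserves local face aspect ratios
(the flow is conformal in the limit) and avoids pinch singularities.  Face
connectivity is never touched, so every iterate is bijective to the input by
construction.  The active-contour variant adds an external force term (most
usefully the gradient of a signed distance function, giving equal-step normal
displacement); the topographic variant constrains a rectangular-boundary
open sheet so the limit is the flat (u, v) rectangle rather than a point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse.linalg import splu

from .mesh import SurfaceMesh, VolumeImage, build_operators, gaussian_curvature, boundary_loops


class FlowBreakdown(RuntimeError):
    """Raised when the implicit solve fails; carries the last valid iterate."""

    def __init__(self, message, last_valid=None, iteration=None):
        super().__init__(message)
        self.last_valid = last_valid
        self.iteration = iteration


@dataclass
class FlowConfig:
    """cMCF settings: implicit time step, stopping criterion and operators."""

    delta_t: float = 5e-4
    t_min: int = 1
    delta_thresh: float = 1e-5
    max_iters: int = 50
    laplacian_kind: str = "cotangent"
    renormalize: bool = True
    #: elbow reading (default): stop when the decrease |d|K|/dt| falls below
    #: threshold. literal=True instead stops at the first increase above it.
    literal_threshold: bool = False

    def __post_init__(self):
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")
        if self.t_min < 1 or self.max_iters < self.t_min:
            raise ValueError("need t_min >= 1 and max_iters >= t_min")


@dataclass
class FlowResult:
    snapshots: list = field(default_factory=list)
    K_trace: list = field(default_factory=list)
    stop_iteration: int = 0
    broke_down: bool = False

    def mesh_at(self, iteration, faces) -> SurfaceMesh:
        return SurfaceMesh(self.snapshots[iteration].copy(), faces.copy())


def _normalize(verts, faces):
    """Rescale to unit total surface area and recenter the centroid."""
    m = SurfaceMesh(verts, faces)
    area = m.area()
    verts = verts / np.sqrt(area)
    verts = verts - verts.mean(axis=0)
    return verts


def mean_abs_gaussian_curvature(verts, faces) -> float:
    m = SurfaceMesh(_normalize(verts.copy(), faces), faces)
    return float(np.abs(gaussian_curvature(m)).mean())


def auto_stop(K_trace, t_min: int, delta_thresh: float, max_iters: int | None = None,
              literal: bool = False) -> int:
    """Stopping iteration stop_t = max(t_min, t_K).

    ``t_K`` is, by default, the first iteration at which the change in mean
    absolute Gaussian curvature |Delta |K|| drops below ``delta_thresh`` (the
    elbow of the trace).  ``literal=True`` uses the first iteration at which
    the change *exceeds* the threshold instead.
    """
    K_trace = np.asarray(K_trace, dtype=float)
    if len(K_trace) < 2:
        raise ValueError("K_trace must have at least 2 entries")
    if max_iters is None:
        max_iters = len(K_trace) - 1
    deltas = np.abs(np.diff(K_trace))
    hit = (deltas > delta_thresh) if literal else (deltas < delta_thresh)
    idx = np.nonzero(hit)[0]
    t_K = int(idx[0] + 1) if idx.size else int(max_iters)
    return max(int(t_min), t_K)


def cmcf(mesh: SurfaceMesh, config: FlowConfig | None = None) -> FlowResult:
    """Run conformalized MCF: (M_t - dt * L_0) v(t+dt) = M_t v(t).

    ``L_0`` is frozen at t=0; the mass matrix is recomputed each iteration.
    With ``renormalize`` the surface area is normalized to 1 and the centroid
    recentred after every step, and the curvature trace is evaluated on the
    normalized mesh so the stopping criterion is scale-free.
    """
    config = config or FlowConfig()
    faces = mesh.faces
    verts = mesh.vertices.copy()
    if config.renormalize:
        verts = _normalize(verts, faces)
    ops0 = build_operators(SurfaceMesh(verts, faces), config.laplacian_kind)
    L0 = ops0.laplacian
    result = FlowResult()
    result.snapshots.append(verts.copy())
    result.K_trace.append(mean_abs_gaussian_curvature(verts, faces))
    for it in range(1, config.max_iters + 1):
        M = sparse.diags(SurfaceMesh(verts, faces).vertex_areas()).tocsr()
        A = (M - config.delta_t * L0).tocsc()
        try:
            lu = splu(A)
            new = lu.solve(M @ verts)
        except RuntimeError as exc:
            result.broke_down = True
            result.stop_iteration = it - 1
            return result
        if not np.isfinite(new).all():
            result.broke_down = True
            result.stop_iteration = it - 1
            return result
        verts = _normalize(new, faces) if config.renormalize else new
        result.snapshots.append(verts.copy())
        result.K_trace.append(mean_abs_gaussian_curvature(verts, faces))
    result.stop_iteration = auto_stop(
        result.K_trace, config.t_min, config.delta_thresh,
        config.max_iters, literal=config.literal_threshold,
    )
    return result


# ---------------------------------------------------------------------------
# Active-contour cMCF
# ---------------------------------------------------------------------------

def sdf_force_field(binary: VolumeImage, normalize: bool = True):
    """Return a callable sampling grad(Phi) (unit-normalized by default) of the
    signed distance function at arbitrary vertex positions (trilinear).

    Phi is negative inside / positive outside so the gradient points outward.
    """
    b = binary.data.astype(bool)
    phi = ndi.distance_transform_edt(~b) - ndi.distance_transform_edt(b)
    g = np.stack(np.gradient(phi), axis=0)
    if normalize:
        n = np.linalg.norm(g, axis=0)
        n[n == 0] = 1.0
        g = g / n
    shape = np.array(b.shape)
    off = binary.origin_offset

    def force(verts):
        pts = (verts + off).T
        oob = ((pts < 0) | (pts > (shape[:, None] - 1))).any(axis=0)
        out = np.stack(
            [ndi.map_coordinates(g[k], pts, order=1, mode="nearest") for k in range(3)],
            axis=1,
        )
        return out, oob

    return force


def active_contour_cmcf(
    mesh: SurfaceMesh,
    external_force,
    alpha_step: float,
    config: FlowConfig | None = None,
    n_iters: int = 1,
) -> SurfaceMesh:
    """Displace a mesh along an external force under Laplacian regularization:
    (M_t - dt * L_0) v(t+1) = M_t (v(t) + alpha * f(v(t))).

    ``external_force`` is a callable ``verts -> (forces, out_of_bounds_mask)``
    or ``verts -> forces``; with the unit SDF gradient and step ``alpha`` the
    mesh advances in equal alpha-voxel normal steps (positive = outward).
    """
    config = config or FlowConfig()
    faces = mesh.faces
    verts = mesh.vertices.copy()
    L0 = build_operators(mesh, config.laplacian_kind).laplacian
    warned = False
    for _ in range(n_iters):
        res = external_force(verts)
        if isinstance(res, tuple):
            f, oob = res
            if oob.any() and not warned:
                import warnings

                warnings.warn(f"{int(oob.sum())} vertices left the force-field grid; clamped")
                warned = True
        else:
            f = res
        M = sparse.diags(SurfaceMesh(verts, faces).vertex_areas()).tocsr()
        A = (M - config.delta_t * L0).tocsc()
        verts = splu(A).solve(M @ (verts + alpha_step * f))
    out = mesh.copy()
    out.vertices = verts
    return out


# ---------------------------------------------------------------------------
# Topographic cMCF (open rectangular sheets in (d, u, v))
# ---------------------------------------------------------------------------

def _line_operators(n_boundary, loop_positions):
    """1D mass / Laplacian for a closed polyline through the given positions."""
    d = np.linalg.norm(np.roll(loop_positions, -1, axis=0) - loop_positions, axis=1)
    seg_prev = np.roll(d, 1)
    mass = 0.5 * (d + seg_prev)
    n = n_boundary
    w_next = 1.0 / np.maximum(d, 1e-12)
    w_prev = 1.0 / np.maximum(seg_prev, 1e-12)
    rows = np.r_[np.arange(n), np.arange(n), np.arange(n)]
    cols = np.r_[np.arange(n), (np.arange(n) + 1) % n, (np.arange(n) - 1) % n]
    vals = np.r_[-(w_next + w_prev), w_next, w_prev]
    L = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    M = sparse.diags(mass).tocsr()
    return M, L


def topographic_cmcf(topo_mesh: SurfaceMesh, config: FlowConfig | None = None,
                     n_iters: int = 10) -> FlowResult:
    """cMCF for open topographic sheets with a rectangular (u, v) boundary.

    Interior vertices follow standard cMCF.  Boundary vertices keep their
    (u, v) coordinates fixed (no flux tangent to the boundary) while their
    depth coordinate d evolves under a 1D line mass/Laplacian along the
    boundary polyline, so the flow limit is the planar (u, v) rectangle.
    Vertex coordinate order is (d, u, v).
    """
    config = config or FlowConfig(delta_t=5e4, renormalize=False)
    faces = topo_mesh.faces
    verts = topo_mesh.vertices.copy()
    loops = boundary_loops(topo_mesh)
    if len(loops) != 1:
        raise ValueError(f"topographic sheet must have exactly one boundary loop, got {len(loops)}")
    loop = np.asarray(loops[0])
    # rectangular boundary sanity: u,v extremes should bound all vertices
    uv = verts[:, 1:]
    buv = uv[loop]
    if not (
        np.isclose(buv[:, 0].min(), uv[:, 0].min())
        and np.isclose(buv[:, 0].max(), uv[:, 0].max())
        and np.isclose(buv[:, 1].min(), uv[:, 1].min())
        and np.isclose(buv[:, 1].max(), uv[:, 1].max())
    ):
        raise ValueError("boundary is not the rectangular (u, v) outline of the sheet")

    L0 = build_operators(topo_mesh, config.laplacian_kind).laplacian
    is_b = np.zeros(len(verts), dtype=bool)
    is_b[loop] = True
    interior = ~is_b
    result = FlowResult()
    result.snapshots.append(verts.copy())
    for _ in range(n_iters):
        M = sparse.diags(SurfaceMesh(verts, faces).vertex_areas()).tocsr()
        A = M - config.delta_t * L0
        rhs = M @ verts
        # boundary rows: d evolves by the 1D line system; u,v held fixed
        Mb, Lb = _line_operators(len(loop), verts[loop])
        Ab = Mb - config.delta_t * Lb
        full = sparse.lil_matrix(sparse.diags(interior.astype(float)) @ A)
        full[np.ix_(loop, loop)] = Ab.toarray()
        rhs[loop, 0] = Mb @ verts[loop, 0]
        rhs[loop, 1] = Ab @ verts[loop, 1]  # overwritten below; keeps system well-posed
        rhs[loop, 2] = Ab @ verts[loop, 2]
        lu = splu(full.tocsc())
        new = lu.solve(rhs)
        # enforce exact u,v invariance on the boundary (no-flux correction)
        new[loop, 1:] = verts[loop, 1:]
        verts = new
        result.snapshots.append(verts.copy())
    result.stop_iteration = n_iters
    return result
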