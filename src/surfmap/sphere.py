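"""Genus-0 spherical parameterization and bijective area-distortion relaxation.

The spherical map is built in two stages:

1. a quasi-conformal map to the unit sphere — conformalized mean curvature
   flow run to near-spherical convergence, radial projection, and Mobius
   centering so the area centroid sits at the origin (Mobius transforms are
   the conformal automorphisms of the sphere, so centering costs no
   conformal error);
2. iterative area-distortion relaxation — the per-face area-distortion
   factor ``lambda`` is diffused by advecting vertices tangentially along
   ``-grad(log lambda)`` with an implicit Laplacian-regularized step
   (active-contour style), reprojecting to the sphere each iteration.

Four stopping criteria (equiareal, MIPS, area-preserving MIPS, isometric)
can be evaluated on the cached trajectory post hoc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .mesh import SurfaceMesh, build_operators, grad_operator
from .metrics import face_singular_values, face_conformal_error, face_area_distortion
from .flows import FlowConfig, cmcf


@dataclass
class SphereParam:
    """Unit-sphere vertex positions in 1-1 correspondence with a source mesh."""

    sphere_vertices: np.ndarray
    source: SurfaceMesh
    relax_trace: list = field(default_factory=list)
    collapsed: bool = False
    stop_iteration: int = 0
    snapshots: list | None = None

    def sphere_mesh(self) -> SurfaceMesh:
        return SurfaceMesh(self.sphere_vertices.copy(), self.source.faces.copy())

    def n_flipped_faces(self) -> int:
        return count_flipped_faces(self.sphere_vertices, self.source.faces)


@dataclass
class RelaxConfig:
    epsilon: float = 1.0
    max_iters: int = 100
    stiffness: float = 0.1
    retry_stiffness: float = 5e-3
    criterion: str = "equiareal"
    theta: float = 0.5
    equiareal_tol: float = 1e-2
    laplacian_kind: str = "cotangent"

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if self.criterion not in (
            "equiareal", "conformal_mips", "isometric", "area_preserving_mips"
        ):
            raise ValueError(f"unknown criterion {self.criterion!r}")


def count_flipped_faces(sphere_vertices, faces) -> int:
    """Spherical triangles whose outward orientation is inconsistent
    (normal anti-parallel to the face centroid direction)."""
    a = sphere_vertices[faces[:, 0]]
    b = sphere_vertices[faces[:, 1]]
    c = sphere_vertices[faces[:, 2]]
    n = np.cross(b - a, c - a)
    centroid = (a + b + c) / 3.0
    return int((np.einsum("ij,ij->i", n, centroid) <= 0).sum())


def _mobius_center(verts, faces, max_iter: int = 100, tol: float = 1e-6):
    """Mobius-center a spherical mesh so the face-area-weighted centroid is at
    the origin (conformal, removes the inversive degree of freedom)."""
    v = verts.copy()
    for _ in range(max_iter):
        m = SurfaceMesh(v, faces)
        a = m.face_areas()
        cent = m.vertices[faces].mean(axis=1)
        mu = (a[:, None] * cent).sum(axis=0) / a.sum()
        if np.linalg.norm(mu) < tol:
            break
        c = -0.5 * mu  # damped inversion step
        vc = v + c
        nrm2 = np.einsum("ij,ij->i", vc, vc)
        v = (1.0 - np.dot(c, c)) * vc / nrm2[:, None] + c
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def conformal_sphere_map(
    mesh: SurfaceMesh,
    flow_config: FlowConfig | None = None,
    sphericity_tol: float = 2e-3,
    max_flow_iters: int = 400,
) -> SphereParam:
    """Quasi-conformal map of a closed genus-0 mesh onto the unit sphere.

    cMCF (which converges conformally to the sphere for genus-0 input) is run
    until the vertex radius spread falls below ``sphericity_tol``; the result
    is radially projected and Mobius-centered.
    """
    from .mesh import euler_genus

    chi, g, b, _ = euler_genus(mesh)
    if g != 0 or b != 0:
        raise ValueError(
            f"spherical parameterization requires a closed genus-0 mesh (genus={g}, boundaries={b})"
        )
    cfg = flow_config or FlowConfig(delta_t=5e-4, max_iters=max_flow_iters, t_min=1)
    faces = mesh.faces
    verts = mesh.vertices.copy()
    # run the flow in chunks, checking sphericity between chunks
    L0 = build_operators(mesh, cfg.laplacian_kind).laplacian
    from .flows import _normalize

    verts = _normalize(verts, faces)
    it = 0
    while it < cfg.max_iters:
        M = sparse.diags(SurfaceMesh(verts, faces).vertex_areas()).tocsr()
        A = (M - cfg.delta_t * L0).tocsc()
        new = splu(A).solve(M @ verts)
        if not np.isfinite(new).all():
            warnings.warn("flow breakdown during spherical mapping; using last iterate")
            break
        verts = _normalize(new, faces)
        it += 1
        if it % 5 == 0 or it == cfg.max_iters:
            r = np.linalg.norm(verts - verts.mean(axis=0), axis=1)
            if r.std() / r.mean() < sphericity_tol:
                break
    center = verts.mean(axis=0)
    sph = verts - center
    sph /= np.linalg.norm(sph, axis=1, keepdims=True)
    sph = _mobius_center(sph, faces)
    return SphereParam(sphere_vertices=sph, source=mesh.copy())


# ---------------------------------------------------------------------------
# Area-distortion relaxation
# ---------------------------------------------------------------------------

def _face_lambda(source: SurfaceMesh, sphere_verts, faces):
    a_ref = source.face_areas()
    sm = SurfaceMesh(sphere_verts, faces)
    a_sph = sm.face_areas()
    f_ref = a_ref / a_ref.sum()
    f_sph = a_sph / np.maximum(a_sph.sum(), 1e-300)
    with np.errstate(divide="ignore"):
        lam = f_ref / np.maximum(f_sph, 1e-300)
    return lam, sm


def _face_to_vertex(faces, n_vertices, values):
    """Incidence-count average of per-face values onto vertices."""
    out = np.zeros((n_vertices,) + values.shape[1:])
    cnt = np.zeros(n_vertices)
    for k in range(3):
        np.add.at(out, faces[:, k], values)
        np.add.at(cnt, faces[:, k], 1.0)
    cnt[cnt == 0] = 1.0
    return out / cnt.reshape(-1, *([1] * (values.ndim - 1)))


def _min_interior_angle(verts, faces):
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    angs = []
    for p, q, r in ((a, b, c), (b, c, a), (c, a, b)):
        u, v = q - p, r - p
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cosang = np.einsum("ij,ij->i", u, v) / np.maximum(nu * nv, 1e-300)
        angs.append(np.arccos(np.clip(cosang, -1, 1)))
    return float(np.min(angs))


def relax_area_distortion(
    sphere_param: SphereParam, config: RelaxConfig | None = None
) -> SphereParam:
    """Iteratively advect sphere vertices along -grad(log lambda) to diffuse
    area distortion, via implicitly regularized (active-contour) steps.

    The full (conformal error, area distortion) trajectory is cached so any
    of the four stopping criteria can be extracted post hoc; the returned
    ``stop_iteration`` and vertices correspond to ``config.criterion``.
    Stops early if a face collapses (interior angle -> 0) or the criterion's
    objective stops improving.
    """
    config = config or RelaxConfig()
    out = _relax_once(sphere_param, config, config.stiffness)
    if config.criterion == "equiareal" and out.relax_trace:
        final_obj = abs(out.relax_trace[out.stop_iteration][1] - 1.0)
        if final_obj > config.equiareal_tol and config.retry_stiffness is not None:
            slow = _relax_once(sphere_param, config, config.retry_stiffness)
            slow_obj = abs(slow.relax_trace[slow.stop_iteration][1] - 1.0)
            if slow_obj < final_obj:
                out = slow
    return out


def _relax_once(sphere_param: SphereParam, config: RelaxConfig, stiffness: float) -> SphereParam:
    source = sphere_param.source
    faces = source.faces
    n = source.n_vertices
    verts = sphere_param.sphere_vertices.copy()
    snapshots = [verts.copy()]
    trace = []
    collapsed = False

    min_angle0 = _min_interior_angle(verts, faces)
    for it in range(config.max_iters + 1):
        lam, sm = _face_lambda(source, verts, faces)
        Q, gQ = face_conformal_error(source, sm)
        glam = float(lam[np.isfinite(lam)].mean())
        trace.append((gQ, glam))
        if it == config.max_iters:
            break
        if config.criterion == "equiareal" and abs(glam - 1.0) < config.equiareal_tol:
            break
        # vector field V = -grad(log lambda) via per-face gradient of the
        # vertex-averaged log-lambda
        log_lam_v = _face_to_vertex(faces, n, np.log(np.maximum(lam, 1e-12)))
        G = grad_operator(SurfaceMesh(verts, faces))
        Vf = -(G @ log_lam_v).reshape(3, -1).T
        norms = np.linalg.norm(Vf, axis=1)
        med = np.median(norms[norms > 0]) if (norms > 0).any() else 0.0
        if med == 0:
            break
        ls = SurfaceMesh(verts, faces).mean_edge_length()
        Vf = Vf * (ls / med)
        Vv = _face_to_vertex(faces, n, Vf)
        # cap the heavy tail of the field at one edge length so no vertex
        # jumps across its one-ring in a single step
        nv = np.linalg.norm(Vv, axis=1, keepdims=True)
        Vv = Vv * np.minimum(1.0, ls / np.maximum(nv, 1e-30))
        # tangential projection with vertex normals (= radial directions here)
        nrm = verts / np.linalg.norm(verts, axis=1, keepdims=True)
        Vt = Vv - np.einsum("ij,ij->i", Vv, nrm)[:, None] * nrm
        # implicit active-contour step
        ops = build_operators(SurfaceMesh(verts, faces), config.laplacian_kind)
        M = ops.mass
        A = (M - stiffness * ops.laplacian).tocsc()
        new = splu(A).solve(M @ (verts + config.epsilon * Vt))
        new /= np.linalg.norm(new, axis=1, keepdims=True)
        if (
            count_flipped_faces(new, faces) > 0
            or _min_interior_angle(new, faces) < 0.05 * min_angle0
        ):
            collapsed = True
            break
        verts = new
        snapshots.append(verts.copy())

    stop = _select_stop(trace, config)
    stop = min(stop, len(snapshots) - 1)
    return SphereParam(
        sphere_vertices=snapshots[stop].copy(),
        source=source,
        relax_trace=trace,
        collapsed=collapsed,
        stop_iteration=stop,
        snapshots=snapshots,
    )


def _select_stop(trace, config: RelaxConfig) -> int:
    gQ = np.array([t[0] for t in trace])
    glam = np.array([t[1] for t in trace])
    if config.criterion == "equiareal":
        return int(np.argmin(np.abs(glam - 1.0)))
    if config.criterion == "conformal_mips":
        return 0
    if config.criterion == "isometric":
        obj = (1 - config.theta) * gQ + config.theta * np.log(np.maximum(glam, 1e-12))
        return int(np.argmin(obj))
    # area_preserving_mips: last iterate before area distortion stops improving
    return int(np.argmin(np.abs(glam - 1.0)))


# ---------------------------------------------------------------------------
# Stopping-criterion objectives
# ---------------------------------------------------------------------------

def evaluate_stopping_criteria(sphere_param: SphereParam, theta: float = 0.5):
    """Global objectives of the four relaxation stopping criteria for the
    current sphere vertices (both meshes normalized to unit total area):

    - ``mips``               = area-weighted mean of s2/s1 + s1/s2 (min 2);
    - ``area_preserving_mips`` = mean of MIPS * (s1 s2 + 1/(s1 s2)) ** theta_ap
      with theta_ap = 1;
    - ``isometric``          = (1-theta) * global_Q + theta * log(global_lambda);
    - ``equiareal_obj``      = |global_lambda - 1|.
    """
    source = sphere_param.source
    faces = source.faces
    srcN = SurfaceMesh(source.vertices / np.sqrt(source.area()), faces)
    sm = SurfaceMesh(sphere_param.sphere_vertices, faces)
    smN = SurfaceMesh(sm.vertices / np.sqrt(sm.area()), faces)
    s1, s2 = face_singular_values(srcN, smN)
    areas = srcN.face_areas()
    ok = np.isfinite(s1) & (s1 > 0)
    n_excluded = int((~ok).sum())
    s1, s2, areas = s1[ok], s2[ok], areas[ok]
    mips_f = s2 / s1 + s1 / s2
    prod = s1 * s2
    ap_f = mips_f * (prod + 1.0 / prod)  # theta_ap = 1
    mips = float((mips_f * areas).sum() / areas.sum())
    ap = float((ap_f * areas).sum() / areas.sum())
    _, gQ = face_conformal_error(srcN, smN)
    _, glam = face_area_distortion(srcN, smN)
    iso = (1 - theta) * gQ + theta * float(np.log(max(glam, 1e-12)))
    return {
        "equiareal_obj": abs(glam - 1.0),
        "mips": mips,
        "area_preserving_mips": ap,
        "isometric": iso,
        "global_Q": gQ,
        "global_lambda": glam,
        "n_excluded": n_excluded,
    }
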