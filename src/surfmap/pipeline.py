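"""End-to-end orchestration: Cartesian input -> reference surface -> sphere
-> (u, v) plane -> topographic space -> topographic mesh, with metrics.

The stages:

1. conformalized mean-curvature smoothing to the curvature elbow, then
   voxelization with morphological hole closing and an isotropic remesh to
   obtain a closed genus-0 reference surface; bijectivity with the input is
   restored by nearest-point matching against the (bijective) flow iterate;
2. quasi-conformal spherical parameterization of the reference;
3. area-distortion relaxation on the sphere;
4. optional weighted-PCA unwrapping axis + equirectangular UV grid;
5. topographic (d, u, v) space by signed-distance propagation, and
   resampling of the cell binary;
6. topographic mesh + Cartesian twin, with distortion/discrepancy reports.

Genus-0 inputs can skip stage 1 (direct unwrapping).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from . import __version__
from .mesh import (
    SurfaceMesh, VolumeImage, euler_genus, voxelize, remesh,
    mean_curvature_from_sdf,
)
from .flows import FlowConfig, cmcf
from .sphere import SphereParam, RelaxConfig, conformal_sphere_map, relax_area_distortion
from .uvmap import uv_map, optimal_axis, pullback_field
from .topography import build_topographic_space, resample_volume, topographic_mesh
from .metrics import distortion_report, compare_meshes


class PipelineFailure(RuntimeError):
    """Structured stage failure (e.g. unclosable reference surface)."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    flow: FlowConfig = field(default_factory=lambda: FlowConfig(
        delta_t=5e-4, max_iters=50, delta_thresh=1e-5))
    relax: RelaxConfig = field(default_factory=lambda: RelaxConfig(max_iters=50))
    dilation_radius: int = 5
    remesh_fraction: float = 0.9
    topo_fraction: float = 0.5
    N: int = 256
    alpha: float = 0.5
    D_in: int | None = None
    optimize_axis: bool = True
    direct_genus0: bool = False
    seed: int = 0
    compute_metrics: bool = True

    def as_dict(self):
        return {
            "version": __version__,
            "flow": asdict(self.flow),
            "relax": asdict(self.relax),
            "dilation_radius": self.dilation_radius,
            "remesh_fraction": self.remesh_fraction,
            "topo_fraction": self.topo_fraction,
            "N": self.N, "alpha": self.alpha, "D_in": self.D_in,
            "optimize_axis": self.optimize_axis,
            "direct_genus0": self.direct_genus0, "seed": self.seed,
        }


def restore_bijectivity(intermediate: SurfaceMesh, remeshed: SurfaceMesh,
                        warn_distance: float = 3.0):
    """Vertex correspondence remeshed -> intermediate by nearest-point
    matching with barycentric weights on the matched face.

    Returns (face_index, bary_weights, distances); compose with the flow's
    per-vertex identity to declare the input<->reference bijection.  Fields
    on the intermediate mesh transfer through ``transfer_field``.
    """
    tm = intermediate.as_trimesh()
    from trimesh.proximity import closest_point
    try:
        pts, dist, fidx = closest_point(tm, remeshed.vertices)
    except BaseException:  # rtree missing: nearest-vertex fallback
        tree = cKDTree(intermediate.vertices)
        dist, vidx = tree.query(remeshed.vertices)
        fidx = np.zeros(len(vidx), dtype=np.int64)
        # pick any face incident to the matched vertex
        v2f = {}
        for i, f in enumerate(intermediate.faces):
            for v in f:
                v2f.setdefault(int(v), i)
        fidx = np.array([v2f[int(v)] for v in vidx])
        pts = intermediate.vertices[vidx]
    tri = intermediate.vertices[intermediate.faces[fidx]]
    from trimesh.triangles import points_to_barycentric
    bary = points_to_barycentric(tri, pts)
    bary = np.clip(bary, 0, None)
    bary /= bary.sum(axis=1, keepdims=True)
    frac_far = float((dist > warn_distance).mean())
    if frac_far > 0.01:
        warnings.warn(
            f"{100 * frac_far:.1f}% of remeshed vertices matched farther than "
            f"{warn_distance} voxels")
    return fidx, bary, dist


def transfer_field(field_values: np.ndarray, faces: np.ndarray, fidx: np.ndarray,
                   bary: np.ndarray) -> np.ndarray:
    vals = np.asarray(field_values)
    fv = vals[faces[fidx]]
    if fv.ndim == 3:
        return np.einsum("nj,njk->nk", bary, fv)
    return np.einsum("nj,nj->n", bary, fv)


@dataclass
class UnwrapResult:
    input_mesh: SurfaceMesh
    reference: SurfaceMesh
    sphere: SphereParam
    uv_grid: object
    topo_space: object
    topo_mesh: object
    correspondence: tuple | None
    flow_result: object
    report: dict = field(default_factory=dict)


def run_unwrap(mesh: SurfaceMesh, cell_binary: VolumeImage | None = None,
               config: PipelineConfig | None = None) -> UnwrapResult:
    """Run the full unwrapping pipeline on a Cartesian input mesh."""
    cfg = config or PipelineConfig()
    report = {"config": cfg.as_dict(), "timings": {}, "stages": {}}
    t_all = time.time()

    chi, g, b, watertight = euler_genus(mesh)
    report["stages"]["input"] = {"chi": chi, "genus": g, "boundaries": b,
                                 "watertight": watertight,
                                 "n_vertices": mesh.n_vertices}
    if cell_binary is None:
        try:
            cell_binary = voxelize(mesh, dilation_radius=cfg.dilation_radius)
        except ValueError as exc:
            raise PipelineFailure("voxelize", str(exc))

    # ---- Step 1: reference surface
    t0 = time.time()
    direct = cfg.direct_genus0 and g == 0 and b == 0
    corr = None
    flow_res = None
    if direct:
        reference = mesh.copy()
    else:
        flow_res = cmcf(mesh, cfg.flow)
        stop = flow_res.stop_iteration
        smooth_v = flow_res.snapshots[stop]
        # restore the input scale/position (flow snapshots are normalized)
        smooth_v = smooth_v * np.sqrt(mesh.area())
        smooth_v = smooth_v - smooth_v.mean(axis=0) + mesh.vertices.mean(axis=0)
        intermediate = SurfaceMesh(smooth_v, mesh.faces)
        try:
            ref_binary = voxelize(intermediate, dilation_radius=cfg.dilation_radius)
        except ValueError as exc:
            raise PipelineFailure(
                "reference", f"holes too large for closing: {exc}")
        reference = remesh(ref_binary, cfg.remesh_fraction, seed=cfg.seed)
        chi2, g2, b2, wt2 = euler_genus(reference)
        if g2 != 0 or not wt2:
            raise PipelineFailure(
                "reference",
                f"voxelization/remeshing failed to produce a closed genus-0 "
                f"reference (genus={g2}, watertight={wt2})")
        corr = restore_bijectivity(intermediate, reference)
        report["stages"]["reference"] = {
            "stop_iteration": stop, "n_vertices": reference.n_vertices,
            "genus": g2}
    report["timings"]["step1"] = time.time() - t0

    # ---- Steps 2-3: sphere + relaxation
    t0 = time.time()
    sp = conformal_sphere_map(reference)
    report["timings"]["step2"] = time.time() - t0
    t0 = time.time()
    rx = relax_area_distortion(sp, cfg.relax)
    report["stages"]["sphere"] = {
        "flipped": rx.n_flipped_faces(),
        "relax_iterations": rx.stop_iteration,
        "collapsed": rx.collapsed,
        "trace_final": rx.relax_trace[rx.stop_iteration] if rx.relax_trace else None,
    }
    report["timings"]["step3"] = time.time() - t0

    # ---- Step 4: axis + UV
    t0 = time.time()
    rotation = None
    if cfg.optimize_axis:
        H = mean_curvature_from_sdf(reference)
        rotation = optimal_axis(rx.sphere_vertices, np.abs(H))
    grid = uv_map(rx, cfg.N, rotation=rotation)
    report["stages"]["uv"] = {"N": cfg.N, "n_fallback": grid.n_fallback}
    report["timings"]["step4"] = time.time() - t0

    # ---- Step 5: topographic space
    t0 = time.time()
    try:
        ref_binary2 = voxelize(reference, dilation_radius=cfg.dilation_radius,
                               grid_shape=cell_binary.data.shape,
                               offset=cell_binary.origin_offset)
    except ValueError as exc:
        raise PipelineFailure("topography", str(exc))
    tspace = build_topographic_space(
        grid.xyz_lookup, ref_binary2, alpha=cfg.alpha, D_in=cfg.D_in,
        cell_binary=cell_binary)
    topo_vol, n_oob = resample_volume(tspace, VolumeImage(
        cell_binary.data.astype(float), origin_offset=cell_binary.origin_offset))
    report["stages"]["topography"] = {
        "shape": list(tspace.shape), "alpha": cfg.alpha,
        "D_in": tspace.D_in, "D_out": tspace.D_out, "oob": n_oob,
        "flagged": tspace.n_flagged}
    report["timings"]["step5"] = time.time() - t0

    # ---- Step 6: topographic mesh
    t0 = time.time()
    tb = VolumeImage((topo_vol.data >= 0.5).astype(np.uint8))
    tmesh = topographic_mesh(tb, tspace, target_fraction=cfg.topo_fraction,
                             seed=cfg.seed)
    report["timings"]["step6"] = time.time() - t0

    # ---- metrics
    if cfg.compute_metrics:
        t0 = time.time()
        rep = distortion_report(reference, rx.sphere_mesh())
        report["distortion"] = {
            "global_Q": rep.global_Q, "global_lambda": rep.global_lambda}
        cmp_ = compare_meshes(tmesh.twin_mesh(), mesh, seed=cfg.seed,
                              compute_volume=False)
        report["comparison"] = {
            "chamfer": cmp_.chamfer, "sliced_wasserstein": cmp_.sliced_wasserstein,
            "delta_area_pct": cmp_.delta_area_pct}
        report["timings"]["metrics"] = time.time() - t0
    report["timings"]["total"] = time.time() - t_all
    return UnwrapResult(
        input_mesh=mesh, reference=reference, sphere=rx, uv_grid=grid,
        topo_space=tspace, topo_mesh=tmesh, correspondence=corr,
        flow_result=flow_res, report=report)


def run_battery(specs, config: PipelineConfig | None = None):
    """Run the pipeline over a battery of phantom specs and report the
    fraction completing all stages (robustness harness)."""
    from .phantoms import make_cell_mesh

    results = []
    for spec in specs:
        mesh, _ = make_cell_mesh(spec)
        try:
            res = run_unwrap(mesh, config=config)
            results.append({"ok": True, "report": res.report})
        except (PipelineFailure, ValueError, RuntimeError) as exc:
            results.append({"ok": False, "error": str(exc)})
    frac = float(np.mean([r["ok"] for r in results])) if results else 0.0
    return {"success_fraction": frac, "results": results}
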