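"""Synthetic cell-surface phantoms with known ground truth.

Phantoms emulate the protrusion morphologies seen on live-cell surfaces —
globular blebs (hemispherical caps), sheet-like lamellipodial ridges
(elongated Gaussian crests) and hair-like filopodial spikes (tall thin
cones) — on a spherical cell body, with optional topological defects
(holes: removed patches; handles: welded tubes) to mimic segmentation and
meshing errors in real microscopy data.  Everything is reproducible
bit-identically from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage as ndi

from .mesh import SurfaceMesh, VolumeImage, voxelize, signed_distance


@dataclass
class Protrusion:
    kind: str  # bleb | ridge | spike
    center_direction: tuple
    height: float
    width: float  # angular radius (radians) of the footprint

    def __post_init__(self):
        if self.kind not in ("bleb", "ridge", "spike"):
            raise ValueError(f"unknown protrusion kind {self.kind!r}")
        d = np.asarray(self.center_direction, dtype=float)
        self.center_direction = tuple(d / np.linalg.norm(d))


@dataclass
class PhantomSpec:
    base_radius: float = 25.0
    protrusions: list = field(default_factory=list)
    holes: list = field(default_factory=list)     # each: dict(direction, angular_radius)
    handles: list = field(default_factory=list)   # each: dict(direction, angular_offset, tube_radius)
    subdivisions: int = 4
    seed: int = 0
    grid_pad: int = 12
    allow_overlap: bool = False


def default_bleb_spec(n_blebs: int = 5, base_radius: float = 25.0, seed: int = 0,
                      subdivisions: int = 4, height: float = 8.0,
                      width: float = 0.45) -> PhantomSpec:
    """Evenly separated hemispherical blebs on a spherical body (the standard
    test condition: non-overlapping, separation >= 3 voxels)."""
    dirs = fibonacci_directions(n_blebs, seed=seed)
    prot = [Protrusion("bleb", tuple(d), height, width) for d in dirs]
    return PhantomSpec(base_radius=base_radius, protrusions=prot,
                       subdivisions=subdivisions, seed=seed)


def fibonacci_directions(n: int, seed: int = 0) -> np.ndarray:
    """n well-separated unit directions (Fibonacci lattice, seeded rotation)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + 5**0.5)
    theta = golden * i
    d = np.stack([np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)
    rng = np.random.default_rng(seed)
    Qm, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Qm) < 0:
        Qm[:, 0] *= -1
    return d @ Qm.T


def _angular_distance(dirs, center):
    return np.arccos(np.clip(dirs @ np.asarray(center), -1.0, 1.0))


def _profile(kind, ang, height, width):
    """Radial displacement profile vs angular distance from the footprint centre."""
    out = np.zeros_like(ang)
    inside = ang < width
    x = np.clip(ang[inside] / width, 0.0, 1.0)
    if kind == "bleb":
        out[inside] = height * np.sqrt(np.maximum(1.0 - x**2, 0.0))
    elif kind == "spike":
        out[inside] = height * (1.0 - x) ** 2
    return out


def _ridge_profile(dirs, center, axis, height, width):
    """Elongated Gaussian crest along the great circle through ``center`` with
    tangent ``axis``; width is the cross-crest angular sigma."""
    c = np.asarray(center)
    t = np.asarray(axis) - np.dot(axis, c) * c
    t /= np.linalg.norm(t)
    b = np.cross(c, t)
    along = np.arctan2(dirs @ t, dirs @ c)
    across = np.arcsin(np.clip(dirs @ b, -1, 1))
    amp = np.exp(-(across**2) / (2 * width**2))
    amp *= np.exp(-(along**2) / (2 * (4 * width) ** 2))
    return height * amp


def make_cell_mesh(spec: PhantomSpec):
    """Build the phantom mesh and per-vertex ground-truth instance labels
    (0 = cortex, i>=1 = protrusion i in spec order)."""
    ico = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
    dirs = np.asarray(ico.vertices)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    r = np.full(len(dirs), float(spec.base_radius))
    labels = np.zeros(len(dirs), dtype=np.int64)
    # overlap check on footprints
    for i, p in enumerate(spec.protrusions if not spec.allow_overlap else []):
        for q in spec.protrusions[i + 1:]:
            sep = _angular_distance(np.asarray([p.center_direction]), q.center_direction)[0]
            if sep < (p.width + q.width):
                raise ValueError("overlapping protrusions in phantom spec")
    rng = np.random.default_rng(spec.seed)
    for i, p in enumerate(spec.protrusions, start=1):
        ang = _angular_distance(dirs, p.center_direction)
        if p.kind == "ridge":
            axis = rng.normal(size=3)
            disp = _ridge_profile(dirs, p.center_direction, axis, p.height, p.width)
        else:
            disp = _profile(p.kind, ang, p.height, p.width)
        r += disp
        labels[disp > 0.2 * p.height] = i
    verts = dirs * r[:, None]
    faces = np.asarray(ico.faces)
    mesh = SurfaceMesh(verts, faces)

    for h in spec.holes:
        mesh, labels = _punch_hole(mesh, labels, h["direction"], h["angular_radius"])
    for h in spec.handles:
        mesh, labels = _add_handle(mesh, labels, h)
    mesh.vertex_fields["gt_label"] = labels
    return mesh, labels


def _punch_hole(mesh, labels, direction, angular_radius):
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    vdir = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    ang = _angular_distance(vdir, d)
    kill = ang < angular_radius
    keep_face = ~kill[mesh.faces].any(axis=1)
    faces = mesh.faces[keep_face]
    used = np.unique(faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(mesh.vertices[used], remap[faces]), labels[used]


def _add_handle(mesh, labels, h):
    """Weld a tube between two surface patches, raising the genus by one."""
    d = np.asarray(h["direction"], dtype=float)
    d /= np.linalg.norm(d)
    off = h.get("angular_offset", 0.5)
    tube_r = h.get("tube_radius", 3.0)
    # second anchor: rotate d by `off` radians about a perpendicular axis
    perp = np.cross(d, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(d, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    d2 = d * np.cos(off) + np.cross(perp, d) * np.sin(off)
    m1, l1 = _punch_hole(mesh, labels, d, 0.18)
    m2, l2 = _punch_hole(m1, l1, d2, 0.18)
    from .mesh import boundary_loops

    loops = boundary_loops(m2)
    if len(loops) != 2:
        raise ValueError("handle construction failed to open two holes")
    la, lb = loops
    n = min(len(la), len(lb))
    la = np.asarray(la[:n])
    lb = np.asarray(lb[:n])
    # order loop b to minimise twist relative to loop a
    ca = m2.vertices[la].mean(axis=0)
    cb = m2.vertices[lb].mean(axis=0)
    axis = cb - ca
    axis /= np.linalg.norm(axis)
    e1 = m2.vertices[la[0]] - ca
    e1 -= np.dot(e1, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    ang_a = np.arctan2((m2.vertices[la] - ca) @ e2, (m2.vertices[la] - ca) @ e1)
    ang_b = np.arctan2((m2.vertices[lb] - cb) @ e2, (m2.vertices[lb] - cb) @ e1)
    la = la[np.argsort(ang_a)]
    lb = lb[np.argsort(ang_b)]
    faces = list(m2.faces)
    for k in range(n):
        a0, a1 = la[k], la[(k + 1) % n]
        b0, b1 = lb[k], lb[(k + 1) % n]
        faces.append([a0, b0, a1])
        faces.append([a1, b0, b1])
    out = trimesh.Trimesh(m2.vertices, np.asarray(faces, dtype=np.int64), process=False)
    trimesh.repair.fix_normals(out)
    return SurfaceMesh(np.asarray(out.vertices), np.asarray(out.faces)), l2


# ---------------------------------------------------------------------------
# Volumes and movies
# ---------------------------------------------------------------------------

def make_volume(spec: PhantomSpec, shell_depth: float = 0.0, shell_width: float = 1.5,
                curvature_coupled: bool = False, mesh=None):
    """Binary cell mask + a membrane-proximal intensity channel.

    The intensity channel is a Gaussian shell at ``shell_depth`` voxels below
    the surface; with ``curvature_coupled`` its amplitude is modulated by
    local mean curvature (emulating curvature-sensing cortical markers).
    """
    if mesh is None:
        mesh, _ = make_cell_mesh(spec)
    binary = voxelize(mesh, dilation_radius=3, pad=spec.grid_pad)
    sdf = signed_distance(binary.data, positive_inside=True)  # >0 inside
    dist_below = sdf - shell_depth
    intensity = np.exp(-(dist_below**2) / (2 * shell_width**2))
    intensity[sdf < -2 * shell_width] = 0.0
    if curvature_coupled:
        from .mesh import mean_curvature_from_sdf

        H = mean_curvature_from_sdf(binary, return_volume=True)
        Hn = (H - H.min()) / max(H.max() - H.min(), 1e-12)
        intensity = intensity * (0.2 + 0.8 * Hn)
    return {
        "binary": binary,
        "intensity": VolumeImage(intensity, origin_offset=binary.origin_offset),
        "mesh": mesh,
    }


def make_bleb_movie(n_blebs: int = 3, n_frames: int = 20, period: int = 10,
                    grid_shape=(128, 256), box_half: int = 12, seed: int = 0):
    """Synthetic 2D (u, v) bleb movie with ground truth.

    Per-frame integer label images and mean-curvature-like images for blob
    blebs whose radii oscillate sinusoidally with per-bleb phase; ground
    truth gives track boxes per frame and event (peak-area) times.
    """
    if period < 4:
        raise ValueError("period must be >= 4 frames")
    rng = np.random.default_rng(seed)
    rows, cols = grid_shape
    centers = np.stack([
        rng.uniform(rows * 0.25, rows * 0.75, n_blebs),
        rng.uniform(cols * 0.1, cols * 0.9, n_blebs),
    ], axis=1)
    # enforce separation
    for _ in range(200):
        d = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        bad = np.argwhere(d < 3.2 * box_half)
        if not len(bad):
            break
        i = bad[0, 0]
        centers[i] = [rng.uniform(rows * 0.25, rows * 0.75), rng.uniform(cols * 0.1, cols * 0.9)]
    phases = rng.uniform(0, 2 * np.pi, n_blebs)
    labels_movie = np.zeros((n_frames,) + grid_shape, dtype=np.int64)
    H_movie = np.zeros((n_frames,) + grid_shape, dtype=float)
    gt_boxes = {}
    rr, cc = np.mgrid[:rows, :cols]
    radii_t = np.zeros((n_frames, n_blebs))
    for t in range(n_frames):
        for i in range(n_blebs):
            radius = box_half * (0.7 + 0.25 * np.sin(2 * np.pi * t / period + phases[i]))
            radii_t[t, i] = radius
            dist = np.hypot(rr - centers[i, 0], cc - centers[i, 1])
            blob = dist <= radius
            labels_movie[t][blob] = i + 1
            H_movie[t] += np.exp(-(dist**2) / (2 * (radius / 1.5) ** 2))
            gt_boxes.setdefault(i + 1, {})[t] = (
                centers[i, 1] - radius, centers[i, 0] - radius,
                centers[i, 1] + radius, centers[i, 0] + radius,
            )
    event_times = {
        i + 1: [t for t in range(1, n_frames - 1)
                if radii_t[t, i] >= radii_t[t - 1, i] and radii_t[t, i] > radii_t[t + 1, i]]
        for i in range(n_blebs)
    }
    return {
        "labels": labels_movie,
        "H": H_movie,
        "gt_boxes": gt_boxes,
        "gt_events": event_times,
        "centers": centers,
        "period": period,
    }
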