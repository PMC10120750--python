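"""Triangle-mesh data model, I/O, discrete operators, curvature and quality.

Conventions
-----------
* Vertex coordinates are in voxel units, ``(z, y, x)`` grid order when a mesh
  is tied to a volume grid; a :class:`VolumeImage` carries the physical voxel
  size for conversion to micrometres.
* The cotangent Laplacian ``L`` is negative semi-definite with zero row sums;
  the mass matrix ``M`` is the barycentric (lumped) diagonal.
* Mean curvature follows the biology sign convention: a sphere sampled with
  outward normals has ``H = +1/r`` (protrusions are positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage as ndi
from scipy import sparse
from scipy.spatial import cKDTree
from skimage import measure
from skimage.morphology import ball


class MeshParseError(ValueError):
    """Raised when a mesh file cannot be parsed; message names the line."""


@dataclass
class SurfaceMesh:
    """A triangle surface mesh with optional named per-vertex/per-face fields."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_fields: dict = field(default_factory=dict)
    face_fields: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("faces index out-of-range vertices")
        for name, v in self.vertex_fields.items():
            if len(v) != len(self.vertices):
                raise ValueError(f"vertex field {name!r} has wrong length")

    # -- basic geometry -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_corners(self):
        v = self.vertices
        f = self.faces
        return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    def face_areas(self) -> np.ndarray:
        a, b, c = self.face_corners()
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def face_normals(self) -> np.ndarray:
        a, b, c = self.face_corners()
        n = np.cross(b - a, c - a)
        nn = np.linalg.norm(n, axis=1)
        nn[nn == 0] = 1.0
        return n / nn[:, None]

    def vertex_normals(self) -> np.ndarray:
        a, b, c = self.face_corners()
        n = np.cross(b - a, c - a)  # area weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], n)
        nn = np.linalg.norm(vn, axis=1)
        nn[nn == 0] = 1.0
        return vn / nn[:, None]

    def area(self) -> float:
        return float(self.face_areas().sum())

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas (one third of incident face area)."""
        fa = self.face_areas()
        va = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(va, self.faces[:, k], fa / 3.0)
        return va

    def edges_unique(self) -> np.ndarray:
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        return np.unique(e, axis=0)

    def mean_edge_length(self) -> float:
        e = self.edges_unique()
        return float(np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1).mean())

    def enclosed_volume(self) -> float:
        """Signed volume via the divergence theorem (needs closed orientable mesh)."""
        a, b, c = self.face_corners()
        return float(np.abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)

    def vertex_adjacency(self) -> sparse.csr_matrix:
        e = self.edges_unique()
        n = self.n_vertices
        A = sparse.coo_matrix(
            (np.ones(2 * len(e)), (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n, n),
        )
        return A.tocsr()

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.faces.copy(),
            {k: np.array(v) for k, v in self.vertex_fields.items()},
            {k: np.array(v) for k, v in self.face_fields.items()},
        )


@dataclass
class VolumeImage:
    """A 3D scalar grid in ``(z, y, x)`` order with physical voxel size (um)."""

    data: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    origin_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be 3D with positive shape")
        self.origin_offset = np.asarray(self.origin_offset, dtype=float)

    @property
    def shape(self):
        return self.data.shape

    def is_binary(self) -> bool:
        return bool(np.isin(np.unique(self.data), (0, 1)).all())


@dataclass
class MeshOperators:
    """Sparse mass matrix M (barycentric, diagonal) and Laplacian L (<=0)."""

    mass: sparse.csr_matrix
    laplacian: sparse.csr_matrix
    kind: str = "cotangent"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Write OBJ (geometry only) or ASCII PLY (with per-vertex scalar fields)."""
    path = str(path)
    if path.lower().endswith(".obj"):
        with open(path, "w") as fh:
            for v in mesh.vertices:
                fh.write("v %.17g %.17g %.17g\n" % (v[0], v[1], v[2]))
            for f in mesh.faces:
                fh.write("f %d %d %d\n" % (f[0] + 1, f[1] + 1, f[2] + 1))
    elif path.lower().endswith(".ply"):
        scalar_fields = {
            k: np.asarray(v, dtype=float)
            for k, v in mesh.vertex_fields.items()
            if np.asarray(v).ndim == 1
        }
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {mesh.n_vertices}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            for name in scalar_fields:
                fh.write(f"property float {name}\n")
            fh.write(f"element face {mesh.n_faces}\n")
            fh.write("property list uchar int vertex_indices\n")
            fh.write("end_header\n")
            cols = [mesh.vertices] + [scalar_fields[k][:, None] for k in scalar_fields]
            data = np.hstack(cols)
            for row in data:
                fh.write(" ".join("%.9g" % x for x in row) + "\n")
            for f in mesh.faces:
                fh.write("3 %d %d %d\n" % tuple(f))
    else:
        raise ValueError("unsupported mesh format (use .obj or .ply)")


def _read_ply_ascii(path) -> SurfaceMesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshParseError(f"{path}: line 1: not a PLY file")
    n_vert = n_face = None
    vert_props = []
    i = 1
    element = None
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        if tok[0] == "format" and tok[1] != "ascii":
            # binary PLY: delegate to trimesh
            tm = trimesh.load(path, process=False)
            return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
        if tok[0] == "element":
            element = tok[1]
            if element == "vertex":
                n_vert = int(tok[2])
            elif element == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and element == "vertex" and tok[1] != "list":
            vert_props.append(tok[-1])
        elif tok[0] == "end_header":
            i += 1
            break
        i += 1
    if n_vert is None or n_face is None:
        raise MeshParseError(f"{path}: header missing vertex/face element")
    try:
        vdata = np.array(
            [lines[i + j].split() for j in range(n_vert)], dtype=float
        )
    except (ValueError, IndexError) as exc:
        raise MeshParseError(f"{path}: vertex block starting line {i + 1}: {exc}")
    i += n_vert
    faces = []
    for j in range(n_face):
        tok = lines[i + j].split()
        try:
            cnt = int(tok[0])
            if cnt != 3:
                raise ValueError("non-triangle face")
            faces.append([int(tok[1]), int(tok[2]), int(tok[3])])
        except (ValueError, IndexError) as exc:
            raise MeshParseError(f"{path}: line {i + j + 1}: {exc}")
    ix = {p: k for k, p in enumerate(vert_props)}
    verts = vdata[:, [ix["x"], ix["y"], ix["z"]]]
    fields = {
        p: vdata[:, ix[p]] for p in vert_props if p not in ("x", "y", "z")
    }
    return SurfaceMesh(verts, np.array(faces, dtype=np.int64), vertex_fields=fields)


def read_mesh(path) -> SurfaceMesh:
    """Read an OBJ or PLY file. OBJ 1-based indices become 0-based."""
    path = str(path)
    if path.lower().endswith(".ply"):
        return _read_ply_ascii(path)
    if path.lower().endswith(".obj"):
        verts, faces = [], []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                tok = line.split()
                if not tok:
                    continue
                try:
                    if tok[0] == "v":
                        verts.append([float(tok[1]), float(tok[2]), float(tok[3])])
                    elif tok[0] == "f":
                        faces.append([int(t.split("/")[0]) - 1 for t in tok[1:4]])
                except (ValueError, IndexError) as exc:
                    raise MeshParseError(f"{path}: line {ln}: {exc}")
        return SurfaceMesh(np.array(verts), np.array(faces, dtype=np.int64))
    raise ValueError("unsupported mesh format (use .obj or .ply)")


# ---------------------------------------------------------------------------
# Discrete operators
# ---------------------------------------------------------------------------

def _cotangents(vertices, faces):
    """Cotangent of the interior angle opposite each face edge, shape (m, 3).

    Column k is the angle at corner k (opposite edge (k+1, k+2)).
    """
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    cots = np.empty((len(faces), 3))
    for k, (p, q, r) in enumerate(((a, b, c), (b, c, a), (c, a, b))):
        u = q - p
        v = r - p
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cross[cross == 0] = np.inf
        cots[:, k] = np.einsum("ij,ij->i", u, v) / cross
    return cots


def _mollify_edge_lengths(l0, l1, l2, delta):
    """Intrinsic mollification: add the smallest eps so that every triangle
    inequality holds with slack ``delta`` (relative to mean edge length)."""
    viol = np.maximum.reduce([
        l0 - l1 - l2, l1 - l0 - l2, l2 - l0 - l1,
    ])
    eps = max(0.0, float(viol.max()) + delta)
    return l0 + eps, l1 + eps, l2 + eps


def _cotangents_from_lengths(l0, l1, l2):
    """Cotangents at corners 0,1,2 from the three edge lengths, where lk is the
    length of the edge *opposite* corner k (law of cosines)."""
    area4 = np.sqrt(np.maximum(
        (l0 + l1 + l2) * (-l0 + l1 + l2) * (l0 - l1 + l2) * (l0 + l1 - l2), 1e-300
    ))
    c0 = (l1**2 + l2**2 - l0**2) / area4
    c1 = (l0**2 + l2**2 - l1**2) / area4
    c2 = (l0**2 + l1**2 - l2**2) / area4
    return np.stack([c0, c1, c2], axis=1)


def is_edge_manifold(mesh: SurfaceMesh) -> bool:
    e = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    return bool((counts <= 2).all())


def build_operators(mesh: SurfaceMesh, laplacian_kind: str = "cotangent") -> MeshOperators:
    """Cotangent (or mollified 'robust') Laplacian + barycentric mass matrix.

    ``L`` has zero row sums; negative cotangent weights are clamped at 0.
    Non-manifold input triggers a warning and the robust variant.
    """
    if laplacian_kind not in ("cotangent", "robust"):
        raise ValueError("laplacian_kind must be 'cotangent' or 'robust'")
    if laplacian_kind == "cotangent" and not is_edge_manifold(mesh):
        warnings.warn("non-manifold edges detected; falling back to robust Laplacian")
        laplacian_kind = "robust"

    f = mesh.faces
    v = mesh.vertices
    if laplacian_kind == "robust":
        # mollified intrinsic lengths for degenerate/sliver robustness
        l0 = np.linalg.norm(v[f[:, 1]] - v[f[:, 2]], axis=1)  # opposite corner 0
        l1 = np.linalg.norm(v[f[:, 2]] - v[f[:, 0]], axis=1)
        l2 = np.linalg.norm(v[f[:, 0]] - v[f[:, 1]], axis=1)
        delta = 1e-6 * float(np.mean(np.r_[l0, l1, l2]))
        l0, l1, l2 = _mollify_edge_lengths(l0, l1, l2, delta)
        cots = _cotangents_from_lengths(l0, l1, l2)
    else:
        cots = _cotangents(v, f)
    # degenerate (non-finite) weights are zeroed; genuine negative cotangents
    # are kept — they carry the conformal structure of obtuse triangles
    cots[~np.isfinite(cots)] = 0.0

    n = mesh.n_vertices
    rows, cols, vals = [], [], []
    # angle at corner k weights edge (k+1, k+2)
    for k in range(3):
        i = f[:, (k + 1) % 3]
        j = f[:, (k + 2) % 3]
        w = 0.5 * cots[:, k]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    W = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    d = np.asarray(W.sum(axis=1)).ravel()
    L = W - sparse.diags(d)
    M = sparse.diags(mesh.vertex_areas())
    return MeshOperators(mass=M.tocsr(), laplacian=L.tocsr(), kind=laplacian_kind)


def grad_operator(mesh: SurfaceMesh) -> sparse.csr_matrix:
    """Per-face gradient operator ``G``: (3m, n) mapping vertex scalars to the
    stacked per-face 3D gradient vectors (rows fx0..fxm, fy..., fz...)."""
    v = mesh.vertices
    f = mesh.faces
    m = len(f)
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    n = np.cross(b - a, c - a)
    dblA = np.linalg.norm(n, axis=1)
    dblA[dblA == 0] = np.inf
    nu = n / dblA[:, None]
    # gradient of hat function at corner k is (n x e_k) / (2A), e_k opposite edge
    g0 = np.cross(nu, c - b) / dblA[:, None]
    g1 = np.cross(nu, a - c) / dblA[:, None]
    g2 = np.cross(nu, b - a) / dblA[:, None]
    rows = np.concatenate([np.tile(np.arange(m) + d * m, 3) for d in range(3)])
    cols = np.concatenate([f[:, 0], f[:, 1], f[:, 2]] * 3)
    vals = np.concatenate([
        g0[:, 0], g1[:, 0], g2[:, 0],
        g0[:, 1], g1[:, 1], g2[:, 1],
        g0[:, 2], g1[:, 2], g2[:, 2],
    ])
    G = sparse.coo_matrix((vals, (rows, cols)), shape=(3 * m, mesh.n_vertices))
    return G.tocsr()


# ---------------------------------------------------------------------------
# Curvature and topology
# ---------------------------------------------------------------------------

def gaussian_curvature(mesh: SurfaceMesh) -> np.ndarray:
    """Discrete Gaussian curvature by angular deficit: K(vi) = 2*pi - sum(theta).

    Boundary vertices use the open deficit pi - sum(theta).
    """
    v, f = mesh.vertices, mesh.faces
    areas = mesh.face_areas()
    good = areas > 1e-14
    angles = np.zeros((len(f), 3))
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    for k, (p, q, r) in enumerate(((a, b, c), (b, c, a), (c, a, b))):
        u1 = q - p
        u2 = r - p
        n1 = np.linalg.norm(u1, axis=1)
        n2 = np.linalg.norm(u2, axis=1)
        n1[n1 == 0] = np.inf
        n2[n2 == 0] = np.inf
        cosang = np.clip(np.einsum("ij,ij->i", u1, u2) / (n1 * n2), -1.0, 1.0)
        angles[:, k] = np.arccos(cosang)
    angsum = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(angsum, f[good, k], angles[good, k])
    K = 2.0 * np.pi - angsum
    bverts = boundary_vertices(mesh)
    if bverts.size:
        K[bverts] = np.pi - angsum[bverts]
    return K


def boundary_edges(mesh: SurfaceMesh) -> np.ndarray:
    e = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return uniq[counts == 1]


def boundary_vertices(mesh: SurfaceMesh) -> np.ndarray:
    be = boundary_edges(mesh)
    return np.unique(be) if be.size else np.array([], dtype=np.int64)


def boundary_loops(mesh: SurfaceMesh) -> list:
    """Ordered vertex loops of each boundary component."""
    be = boundary_edges(mesh)
    if not be.size:
        return []
    nbr = {}
    for i, j in be:
        nbr.setdefault(int(i), []).append(int(j))
        nbr.setdefault(int(j), []).append(int(i))
    seen = set()
    loops = []
    for start in sorted(nbr):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            nxt = [k for k in nbr[cur] if k != prev and k not in seen]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            loop.append(cur)
            seen.add(cur)
        loops.append(loop)
    return loops


def euler_genus(mesh: SurfaceMesh):
    """Return (chi, genus, n_boundaries, watertight).

    chi = V - E + F; closed surfaces use chi = 2 - 2g, open ones 2 - 2g - b.
    """
    V = mesh.n_vertices
    e = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    E = len(uniq)
    F = mesh.n_faces
    chi = V - E + F
    b = len(boundary_loops(mesh))
    watertight = b == 0 and bool((counts == 2).all())
    g = (2 - chi - b) / 2.0
    g = int(round(g)) if abs(g - round(g)) < 1e-9 else g
    return chi, g, b, watertight


# ---------------------------------------------------------------------------
# Voxelization / remeshing
# ---------------------------------------------------------------------------

def voxelize(
    mesh: SurfaceMesh,
    dilation_radius: int = 5,
    smooth_sigma: float = 0.0,
    pad: int = 10,
    grid_shape=None,
    offset=None,
) -> VolumeImage:
    """Binary voxelization: subdivide to sub-voxel edges, stamp barycenters,
    morphologically close holes (ball dilation -> fill -> erosion).

    ``grid_shape``/``offset`` pin the output grid (for co-registered volumes);
    otherwise the grid is the padded bounding box and ``origin_offset`` records
    the shift applied to vertex coordinates.
    """
    verts = mesh.vertices.copy()
    faces = mesh.faces.copy()
    if offset is None:
        lo = verts.min(axis=0)
        offset = -(lo - pad)
    verts = verts + offset
    if grid_shape is None:
        hi = verts.max(axis=0)
        grid_shape = tuple(int(np.ceil(h + pad)) for h in hi)

    # subdivide until mean edge < 1 voxel
    tm = trimesh.Trimesh(verts, faces, process=False)
    for _ in range(12):
        el = tm.edges_unique_length.mean()
        if el < 1.0:
            break
        tm = trimesh.Trimesh(*trimesh.remesh.subdivide(tm.vertices, tm.faces), process=False)
    bary = tm.triangles_center
    B = np.zeros(grid_shape, dtype=bool)
    idx = np.round(bary).astype(int)
    keep = ((idx >= 0) & (idx < np.array(grid_shape))).all(axis=1)
    idx = idx[keep]
    B[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    shell_count = int(B.sum())

    if dilation_radius > 0:
        se = ball(int(dilation_radius))
        Bd = ndi.binary_dilation(B, structure=se)
        Bf = ndi.binary_fill_holes(Bd)
        Bout = ndi.binary_erosion(Bf, structure=se)
    else:
        Bout = ndi.binary_fill_holes(B)
    if int(Bout.sum()) <= int(1.05 * shell_count):
        raise ValueError("non-closable surface: binary fill produced no interior")
    # the stamped shell straddles the surface, so the filled body overshoots by
    # about half a voxel: one face-connected erosion debiases the volume
    Bout = ndi.binary_erosion(Bout)
    if smooth_sigma > 0:
        Bout = ndi.gaussian_filter(Bout.astype(float), smooth_sigma) >= 0.5
    return VolumeImage(Bout.astype(np.uint8), origin_offset=np.asarray(offset, dtype=float))


def marching_cubes_mesh(binary: VolumeImage, smooth_sigma: float = 1.0,
                        level: float = 0.5) -> SurfaceMesh:
    """Marching cubes at the given isovalue after Gaussian smoothing of the
    binary; vertices are returned in the *unpadded* input coordinate frame."""
    vol = binary.data.astype(float)
    if smooth_sigma > 0:
        vol = ndi.gaussian_filter(vol, smooth_sigma)
    verts, faces, _, _ = measure.marching_cubes(vol, level=level)
    verts = verts - binary.origin_offset
    return SurfaceMesh(verts, faces.astype(np.int64))


def _cluster_remesh(mesh: SurfaceMesh, n_clusters: int, n_iter: int = 8,
                    seed: int = 0) -> SurfaceMesh:
    """Deterministic Lloyd-style uniform vertex clustering remesh.

    Cluster centers are seeded by a strided permutation of the vertices,
    relaxed by a few Lloyd iterations (nearest-center assignment + centroid
    update), and the output faces are the cluster-adjacency dual of the input
    faces. This yields near-isotropic, approximately equilateral triangles on
    dense marching-cubes input.
    """
    v = mesh.vertices
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(v))
    centers = v[order[:: max(1, len(v) // n_clusters)]][:n_clusters].copy()
    assign = None
    for _ in range(n_iter):
        tree = cKDTree(centers)
        _, assign = tree.query(v)
        sums = np.zeros_like(centers)
        cnts = np.zeros(len(centers))
        np.add.at(sums, assign, v)
        np.add.at(cnts, assign, 1.0)
        nonempty = cnts > 0
        centers[nonempty] = sums[nonempty] / cnts[nonempty, None]
    nonempty = np.bincount(assign, minlength=len(centers)) > 0
    remap = -np.ones(len(centers), dtype=np.int64)
    remap[nonempty] = np.arange(nonempty.sum())
    centers = centers[nonempty]
    lab = remap[assign]
    fl = lab[mesh.faces]
    distinct = (fl[:, 0] != fl[:, 1]) & (fl[:, 1] != fl[:, 2]) & (fl[:, 0] != fl[:, 2])
    tri = fl[distinct]
    # dedupe by sorted key but keep the original winding of the first instance
    key = np.sort(tri, axis=1)
    _, first = np.unique(key, axis=0, return_index=True)
    tri = tri[np.sort(first)]
    centers, tri = _repair_nonmanifold(centers, tri)
    out = trimesh.Trimesh(centers, tri, process=False)
    trimesh.repair.fix_normals(out)
    # orient outward for closed meshes
    if out.is_winding_consistent and out.is_watertight and out.volume < 0:
        out.invert()
    return SurfaceMesh(np.asarray(out.vertices), np.asarray(out.faces))


def _repair_nonmanifold(vertices, faces, max_rounds: int = 6):
    """Collapse edges shared by >2 faces (merge endpoints), removing the pinch
    configurations a clustering remesh occasionally produces."""
    vertices = np.asarray(vertices)
    faces = np.asarray(faces)
    for _ in range(max_rounds):
        e = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        bad = uniq[counts > 2]
        if not len(bad):
            break
        remap = np.arange(len(vertices))
        for i, j in bad:
            remap[remap == remap[j]] = remap[i]
        faces = remap[faces]
        nondegen = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 0] != faces[:, 2])
        )
        faces = faces[nondegen]
        key = np.sort(faces, axis=1)
        _, first = np.unique(key, axis=0, return_index=True)
        faces = faces[np.sort(first)]
    used = np.unique(faces)
    remap = -np.ones(len(vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return vertices[used], remap[faces]


def remesh(binary_or_mesh, target_fraction: float = 0.5, smooth_sigma: float = 1.0,
           seed: int = 0, keep_largest: bool = True) -> SurfaceMesh:
    """Marching cubes (isovalue 0.5) + uniform clustering remesh to
    ``target_fraction`` of the marching-cubes vertex count."""
    if target_fraction >= 1.0:
        raise ValueError("target_fraction must be < 1")
    if isinstance(binary_or_mesh, VolumeImage):
        mc = marching_cubes_mesh(binary_or_mesh, smooth_sigma=smooth_sigma)
    else:
        mc = binary_or_mesh
    n_target = int(target_fraction * mc.n_vertices)
    if n_target < 100:
        raise ValueError(f"remesh target {n_target} vertices < 100")
    out = _cluster_remesh(mc, n_target, seed=seed)
    if keep_largest:
        tm = out.as_trimesh()
        comps = tm.split(only_watertight=False)
        if len(comps) > 1:
            big = max(comps, key=lambda c: len(c.vertices))
            out = SurfaceMesh(np.asarray(big.vertices), np.asarray(big.faces))
    return out


# ---------------------------------------------------------------------------
# Curvature from the signed distance transform
# ---------------------------------------------------------------------------

def signed_distance(binary: np.ndarray, positive_inside: bool = True) -> np.ndarray:
    """Euclidean signed distance transform of a binary volume."""
    b = binary.astype(bool)
    inside = ndi.distance_transform_edt(b)
    outside = ndi.distance_transform_edt(~b)
    sdf = inside - outside
    return sdf if positive_inside else -sdf


def mean_curvature_from_sdf(mesh_or_binary, smooth_sigma: float = 1.0,
                            return_volume: bool = False):
    """Mean curvature H = -0.5 * div(n_hat) with n_hat the unit gradient of the
    signed distance transform (positive-inside convention: sphere has H>0).

    Accepts a binary VolumeImage (returns per-voxel H, optionally sampled at
    mesh vertices when a SurfaceMesh is given).
    """
    if isinstance(mesh_or_binary, SurfaceMesh):
        binary = voxelize(mesh_or_binary, dilation_radius=2)
        mesh = mesh_or_binary
    else:
        binary = mesh_or_binary
        mesh = None
    if binary.data.sum() == 0:
        raise ValueError("empty binary volume")
    sdf = signed_distance(binary.data, positive_inside=True)
    if smooth_sigma > 0:
        sdf = ndi.gaussian_filter(sdf, smooth_sigma)
    g = np.stack(np.gradient(sdf), axis=0)
    norm = np.linalg.norm(g, axis=0)
    norm[norm == 0] = 1.0
    n_hat = g / norm
    div = sum(np.gradient(n_hat[k], axis=k) for k in range(3))
    H = -0.5 * div
    if mesh is None or return_volume:
        return H
    pts = (mesh.vertices + binary.origin_offset).T
    return ndi.map_coordinates(H, pts, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# Mesh quality
# ---------------------------------------------------------------------------

def radius_ratio(mesh_or_faces) -> np.ndarray:
    """Per-face triangle quality 2*r_in/r_circ in (0, 1]; 1 for equilateral,
    0 for degenerate triangles."""
    if isinstance(mesh_or_faces, SurfaceMesh):
        a, b, c = mesh_or_faces.face_corners()
    else:
        tri = np.asarray(mesh_or_faces, dtype=float)
        a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(c - a, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    s = 0.5 * (la + lb + lc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_in = area / s
        r_circ = la * lb * lc / (4.0 * area)
        q = 2.0 * r_in / r_circ
    q[~np.isfinite(q)] = 0.0
    return np.clip(q, 0.0, 1.0)
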