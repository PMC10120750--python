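"""Topography-guided unsupervised segmentation and decomposition of
cell-surface protrusions.

Working in the topographic (d, u, v) space makes protrusion analysis almost
planar: every protrusion points "up" (+d), its height is simply h = d - d_ref
relative to a reference height field, and lateral watersheds and label
diffusion operate on well-behaved grids.  The reference height field is an
asymmetric-least-squares (Whittaker) baseline of the (u, v)-parameterized
height image: the asymmetry presses the fit underneath upward excursions
(protrusions) while the Laplacian penalty keeps it smooth like a cortex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse.linalg import spsolve, splu
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import expand_labels, watershed
from skimage.transform import resize

from .mesh import SurfaceMesh, VolumeImage, boundary_loops, build_operators, euler_genus
from .topography import TopographicSpace, TopographicMesh, topo_to_cartesian


# ---------------------------------------------------------------------------
# Reference height field (ALS baseline)
# ---------------------------------------------------------------------------

@dataclass
class ReferenceHeightField:
    d_ref: np.ndarray              # (rows, cols) smooth baseline, d-index units
    approx_d: np.ndarray           # the rugged (u, v) height approximation
    als_params: dict = field(default_factory=dict)


def approximate_height_image(topo_binary: np.ndarray) -> np.ndarray:
    """(u, v) height image: per column, the length of the longest contiguous
    foreground run along d (robust to internal voids and floaters)."""
    b = np.asarray(topo_binary).astype(bool)
    D = b.shape[0]
    run = np.zeros(b.shape[1:], dtype=np.int64)
    best = np.zeros_like(run)
    for k in range(D):
        run = np.where(b[k], run + 1, 0)
        best = np.maximum(best, run)
    return best.astype(float)


def _second_diff(n):
    """(n-2, n) interior second-difference matrix (no boundary penalty)."""
    return sparse.diags(
        [np.ones(n - 2), -2 * np.ones(n - 2), np.ones(n - 2)], [0, 1, 2],
        shape=(n - 2, n),
    )


def _smoothness_penalty_2d(shape):
    r, c = shape
    Dr = sparse.kron(_second_diff(r), sparse.identity(c))
    Dc = sparse.kron(sparse.identity(r), _second_diff(c))
    return (Dr.T @ Dr + Dc.T @ Dc).tocsc()


def als_baseline_1d(y, p=0.25, lam=1.0, n_iter=10):
    """Classic 1D asymmetric Whittaker baseline (oracle for the 2D version)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    D = _second_diff(n)
    DtD = (D.T @ D).tocsc()
    w = np.ones(n)
    z = y.copy()
    for _ in range(n_iter):
        W = sparse.diags(w)
        z = spsolve((W + lam * DtD).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def als_reference_surface(approx_d: np.ndarray, p: float = 0.25, lam: float = 1.0,
                          n_iter: int = 10, downsample: int = 8) -> ReferenceHeightField:
    """2D asymmetric Whittaker baseline of the height image.

    The image is downsampled by ``downsample`` for efficiency and extra
    smoothness, iteratively re-weighted (w = p above the fit, 1-p below),
    and resized back.  The result lies between the rugged surface and the
    flat plane, with protrusion pixels above it.
    """
    y_full = np.asarray(approx_d, dtype=float)
    shape_full = y_full.shape
    small = tuple(max(8, s // downsample) for s in shape_full) if downsample > 1 else shape_full
    y = resize(y_full, small, order=1, anti_aliasing=downsample > 1)
    DtD = _smoothness_penalty_2d(y.shape)
    yf = y.ravel()
    w = np.ones(yf.size)
    z = yf.copy()
    for _ in range(n_iter):
        W = sparse.diags(w)
        z = spsolve((W + lam * DtD).tocsc(), w * yf)
        w = np.where(yf > z, p, 1.0 - p)
    z_img = resize(z.reshape(y.shape), shape_full, order=1)
    return ReferenceHeightField(
        d_ref=z_img, approx_d=y_full,
        als_params={"p": p, "lam": lam, "n_iter": n_iter, "downsample": downsample},
    )


# ---------------------------------------------------------------------------
# Affinity matrices and label spreading
# ---------------------------------------------------------------------------

@dataclass
class AffinityConfig:
    gamma: float = 0.9
    clamp: float = 0.99
    n_iter: int = 20
    binarize_threshold: float = 0.25
    min_area_pre: float = 200.0    # voxel^2, before diffusion
    min_area_post: float = 500.0   # voxel^2, after diffusion

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")


def combined_affinity(mesh: SurfaceMesh, gamma: float = 0.9) -> sparse.csr_matrix:
    """A = gamma * A_dist + (1 - gamma) * A_convex over 1-ring neighbourhoods.

    A_dist uses Gaussian-of-Euclidean edge distances; A_convex a Gaussian of
    the cosine distance (1 - cos(theta))/2 of the dihedral angle between the
    endpoint vertex normals.  Diagonals are 1.  Assembled sparse over the
    mesh edges (the behaviour of dense pairwise affinities at the scales a
    diffusion actually reaches, without the memory).
    """
    e = mesh.edges_unique()
    v = mesh.vertices
    n = mesh.n_vertices
    d_e = np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1)
    normals = mesh.vertex_normals()
    cosang = np.einsum("ij,ij->i", normals[e[:, 0]], normals[e[:, 1]])
    d_c = (1.0 - cosang) / 2.0

    def gauss(d):
        mu = max(d.mean(), 1e-12)
        return np.exp(-(d**2) / (2.0 * mu * mu))

    def assemble(vals):
        A = sparse.coo_matrix(
            (np.r_[vals, vals, np.ones(n)],
             (np.r_[e[:, 0], e[:, 1], np.arange(n)],
              np.r_[e[:, 1], e[:, 0], np.arange(n)])),
            shape=(n, n),
        )
        return A.tocsr()

    return gamma * assemble(gauss(d_e)) + (1.0 - gamma) * assemble(gauss(d_c))


def label_spreading(affinity: sparse.csr_matrix, seeds: np.ndarray, n_iter: int = 20,
                    clamp: float = 0.99, binarize_threshold: float | None = None,
                    background_is_class: bool = True) -> np.ndarray:
    """Graph label spreading: F <- clamp * S F + (1 - clamp) * Y with
    S = D^-1/2 A D^-1/2; optional per-iteration re-binarization.

    ``seeds`` holds class indices.  With ``background_is_class`` (the binary
    two-class mode) 0 competes as a class of its own; otherwise 0 means
    unlabeled and positive labels expand into it.  Returns hard labels;
    diffusion can never invent a label absent from the seeds.
    """
    n = affinity.shape[0]
    classes = np.unique(seeds)
    if not background_is_class:
        classes = classes[classes > 0]
    k = len(classes)
    if k == 0:
        return np.zeros(n, dtype=seeds.dtype)
    class_of = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((n, k))
    for c in classes:
        Y[seeds == c, class_of[c]] = 1.0
    deg = np.asarray(affinity.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    Dh = sparse.diags(1.0 / np.sqrt(deg))
    S = Dh @ affinity @ Dh
    F = Y.copy()
    for _ in range(n_iter):
        if binarize_threshold is not None and k == 2:
            F = np.stack([1.0 - (F[:, 1] >= binarize_threshold),
                          (F[:, 1] >= binarize_threshold).astype(float)], axis=1)
        F = clamp * (S @ F) + (1.0 - clamp) * Y
    hard = classes[np.argmax(F, axis=1)]
    if not background_is_class:
        hard = np.where(F.max(axis=1) > 1e-12, hard, 0)
    return hard


def mesh_components(mesh: SurfaceMesh, mask: np.ndarray):
    """Connected components of the masked vertex subgraph; labels 0/1..k."""
    A = mesh.vertex_adjacency()
    sub = A[mask][:, mask]
    ncomp, lab = sparse.csgraph.connected_components(sub, directed=False)
    out = np.zeros(mesh.n_vertices, dtype=np.int64)
    out[mask] = lab + 1
    return ncomp, out


def _component_areas(mesh: SurfaceMesh, labels: np.ndarray):
    va = mesh.vertex_areas()
    out = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        out[int(lab)] = float(va[labels == lab].sum())
    return out


def remove_small_components(mesh: SurfaceMesh, mask: np.ndarray, min_area: float):
    ncomp, lab = mesh_components(mesh, mask)
    areas = _component_areas(mesh, lab)
    keep = {c for c, a in areas.items() if a >= min_area}
    return np.isin(lab, list(keep)) if keep else np.zeros_like(mask)


# ---------------------------------------------------------------------------
# Binary protrusion segmentation
# ---------------------------------------------------------------------------

def binary_protrusions(
    topo_mesh: TopographicMesh,
    ref_field: ReferenceHeightField | None,
    affinity_cfg: AffinityConfig | None = None,
    area_mesh: SurfaceMesh | None = None,
) -> np.ndarray:
    """Per-vertex protrusion binary on the topographic mesh.

    Height h = d - d_ref at the vertex's (u, v); threshold at the mean
    height; prune small components; smooth by 2-class label spreading on
    the combined affinity; prune again.  ``ref_field=None`` uses the flat
    d_ref = 0 plane (the under-segmenting baseline).  Areas are measured on
    ``area_mesh`` (default: the Cartesian twin) in voxel^2.
    """
    cfg = affinity_cfg or AffinityConfig()
    m = topo_mesh.mesh
    d = m.vertices[:, 0]
    if ref_field is None:
        d_ref_at = np.zeros(len(d))
    else:
        pts = m.vertices[:, 1:].T
        d_ref_at = ndi.map_coordinates(ref_field.d_ref, pts, order=1, mode="nearest")
    h = d - d_ref_at
    # small deadband so a uniformly flat sheet (h constant to rounding)
    # yields no foreground
    fg = h > h.mean() + 1e-6
    area_m = area_mesh or topo_mesh.twin_mesh()
    fg = remove_small_components(area_m, fg, cfg.min_area_pre)
    if not fg.any():
        warnings.warn("empty protrusion segmentation")
        return fg
    A = combined_affinity(m, cfg.gamma)
    seeds = fg.astype(np.int64)
    out = label_spreading(A, seeds, n_iter=cfg.n_iter, clamp=cfg.clamp,
                          binarize_threshold=cfg.binarize_threshold)
    fg = out == 1
    fg = remove_small_components(area_m, fg, cfg.min_area_post)
    if not fg.any():
        warnings.warn("empty protrusion segmentation after postprocessing")
    return fg


# ---------------------------------------------------------------------------
# Instance segmentation
# ---------------------------------------------------------------------------

def instance_protrusions(
    topo_binary: VolumeImage,
    topo_mesh: TopographicMesh,
    ref_field: ReferenceHeightField | None = None,
    motif_mode: str = "blebs_filopodia",
    seed: int = 0,
    min_voxels: int = 500,
    min_area: float = 100.0,
    expand: int = 3,
    diffusion_iters: int = 10,
    affinity_cfg: AffinityConfig | None = None,
):
    """Instance labels for individual protrusions.

    Tops of protrusions are found as connected regions of high topographic
    mean curvature (3-class k-means on smoothed H for blebs/filopodia, a
    3-component Gaussian mixture on multiscale H for lamellipodia), expanded,
    transferred to the mesh, intersected with the binary segmentation, and
    diffused by label spreading (no re-binarization).  Returns (vertex
    labels, voxel seed labels).
    """
    from sklearn.cluster import KMeans
    from sklearn.mixture import GaussianMixture
    from .mesh import signed_distance
    from skimage.morphology import ball

    if motif_mode not in ("blebs_filopodia", "lamellipodia"):
        raise ValueError("motif_mode must be 'blebs_filopodia' or 'lamellipodia'")
    b = topo_binary.data.astype(bool)
    sdf = signed_distance(b, positive_inside=True)
    sdf = ndi.gaussian_filter(sdf, 1.0)
    g = np.stack(np.gradient(sdf), axis=0)
    gn = np.linalg.norm(g, axis=0)
    gn[gn == 0] = 1.0
    nh = g / gn
    H = -0.5 * sum(np.gradient(nh[k], axis=k) for k in range(3))
    se = ball(2)
    shell = ndi.binary_dilation(b, se) & ~ndi.binary_erosion(b, se)
    vox = np.argwhere(shell)
    rng = np.random.default_rng(seed)
    samp = vox[rng.choice(len(vox), min(10000, len(vox)), replace=False)]

    if motif_mode == "lamellipodia":
        feats = np.stack([ndi.gaussian_filter(H, s) for s in (1, 3, 5)], axis=-1)
        X = feats[samp[:, 0], samp[:, 1], samp[:, 2]]
        try:
            gm = GaussianMixture(n_components=3, random_state=seed).fit(X)
            means = gm.means_[:, 0]
            labels_all = gm.predict(feats[shell])
        except ValueError:
            gm = None
    else:
        feats = ndi.gaussian_filter(H, 1.0)[..., None]
        X = feats[samp[:, 0], samp[:, 1], samp[:, 2]]
        gm = KMeans(n_clusters=3, random_state=seed, n_init=5).fit(X)
        means = gm.cluster_centers_[:, 0]
        labels_all = gm.predict(feats[shell])
    if gm is None or len(np.unique(means)) < 2:
        warnings.warn("degenerate clustering; falling back to Otsu threshold")
        thr = threshold_otsu(feats[shell][:, -1])
        high = feats[..., -1] > thr
        high &= shell
    else:
        top = int(np.argmax(means))
        high = np.zeros_like(b)
        high[shell] = labels_all == top
    # drop small high-curvature components, label, expand
    lab = cc_label(high, connectivity=1)
    counts = np.bincount(lab.ravel())
    small = np.nonzero(counts < min_voxels)[0]
    lab[np.isin(lab, small)] = 0
    lab = cc_label(lab > 0, connectivity=1)
    lab = expand_labels(lab, distance=expand)
    # transfer to mesh vertices
    pts = topo_mesh.mesh.vertices.T
    vlab = ndi.map_coordinates(lab, pts, order=0, mode="nearest").astype(np.int64)
    # intersect with binary protrusion segmentation
    binmask = binary_protrusions(topo_mesh, ref_field, affinity_cfg)
    vlab[~binmask] = 0
    # prune by Cartesian 3D area
    twin = topo_mesh.twin_mesh()
    va = twin.vertex_areas()
    for c in np.unique(vlab):
        if c and va[vlab == c].sum() < min_area:
            vlab[vlab == c] = 0
    # relabel consecutively
    uniq = np.unique(vlab)
    remap = {c: i for i, c in enumerate(uniq)}
    vlab = np.vectorize(remap.get)(vlab)
    if vlab.max() == 0:
        return vlab, lab
    A = combined_affinity(topo_mesh.mesh, (affinity_cfg or AffinityConfig()).gamma)
    out = label_spreading(A, vlab, n_iter=diffusion_iters, clamp=0.99,
                          background_is_class=False)
    out[~binmask] = 0
    return out, lab


# ---------------------------------------------------------------------------
# Direct 2D unwrapping of protrusion submeshes
# ---------------------------------------------------------------------------

def extract_submesh(mesh: SurfaceMesh, vertex_mask: np.ndarray):
    """Submesh of faces whose three corners are all selected; returns
    (submesh, original vertex indices)."""
    keep_face = vertex_mask[mesh.faces].all(axis=1)
    faces = mesh.faces[keep_face]
    used = np.unique(faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(mesh.vertices[used], remap[faces]), used


def harmonic_disk_map(submesh: SurfaceMesh) -> np.ndarray:
    """Conformal-style disk parameterization: boundary mapped to the unit
    circle preserving edge-length fractions, interior by the cotangent
    Laplace equation."""
    loops = boundary_loops(submesh)
    if len(loops) != 1:
        raise ValueError(f"disk map needs exactly one boundary loop, got {len(loops)}")
    loop = np.asarray(loops[0])
    v = submesh.vertices
    seg = np.linalg.norm(v[np.roll(loop, -1)] - v[loop], axis=1)
    t = np.r_[0.0, np.cumsum(seg)][:-1] / seg.sum() * 2 * np.pi
    bpos = np.stack([np.cos(t), np.sin(t)], axis=1)
    n = submesh.n_vertices
    L = build_operators(submesh, "robust").laplacian.tolil()
    is_b = np.zeros(n, dtype=bool)
    is_b[loop] = True
    interior = ~is_b
    Lii = L[interior][:, interior].tocsc()
    Lib = L[interior][:, is_b].tocsr()
    xy = np.zeros((n, 2))
    xy[loop] = bpos
    order = np.nonzero(is_b)[0]
    bvals = np.zeros((len(order), 2))
    bvals[np.searchsorted(order, loop)] = bpos
    if interior.any():
        sol = splu(Lii).solve(-Lib @ bvals)
        xy[interior] = sol
    # orient counter-clockwise (positive signed areas)
    if _tri_area_2d(xy, submesh.faces).sum() < 0:
        xy[:, 1] = -xy[:, 1]
    return xy


def _tri_area_2d(xy, faces):
    a, b, c = xy[faces[:, 0]], xy[faces[:, 1]], xy[faces[:, 2]]
    return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                  - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))


def relax_disk_areas(submesh: SurfaceMesh, xy: np.ndarray, n_iter: int = 50,
                     step: float = 0.2) -> np.ndarray:
    """Area-distortion relaxation in the disk: advect interior vertices along
    minus the gradient of log(area-distortion), boundary fixed, rejecting
    steps that flip a triangle."""
    faces = submesh.faces
    a3d = submesh.face_areas()
    f3d = a3d / a3d.sum()
    loops = boundary_loops(submesh)
    is_b = np.zeros(len(xy), dtype=bool)
    is_b[np.asarray(loops[0])] = True
    cur = xy.copy()
    for _ in range(n_iter):
        a2d = _tri_area_2d(cur, faces)
        if (a2d <= 0).any():
            break
        f2d = a2d / a2d.sum()
        lam = f3d / np.maximum(f2d, 1e-300)
        loglam = np.log(np.maximum(lam, 1e-12))
        # vertex-averaged lambda and its 2D per-face gradient
        lv = np.zeros(len(cur))
        cnt = np.zeros(len(cur))
        for k in range(3):
            np.add.at(lv, faces[:, k], loglam)
            np.add.at(cnt, faces[:, k], 1.0)
        lv /= np.maximum(cnt, 1.0)
        # P1 gradient in 2D
        a, b, c = cur[faces[:, 0]], cur[faces[:, 1]], cur[faces[:, 2]]
        det = 2.0 * a2d
        g0 = np.stack([b[:, 1] - c[:, 1], c[:, 0] - b[:, 0]], axis=1) / det[:, None]
        g1 = np.stack([c[:, 1] - a[:, 1], a[:, 0] - c[:, 0]], axis=1) / det[:, None]
        g2 = np.stack([a[:, 1] - b[:, 1], b[:, 0] - a[:, 0]], axis=1) / det[:, None]
        gf = (g0 * lv[faces[:, 0], None] + g1 * lv[faces[:, 1], None]
              + g2 * lv[faces[:, 2], None])
        V = np.zeros_like(cur)
        cnt2 = np.zeros(len(cur))
        for k in range(3):
            np.add.at(V, faces[:, k], -gf)
            np.add.at(cnt2, faces[:, k], 1.0)
        V /= np.maximum(cnt2, 1.0)[:, None]
        nv = np.linalg.norm(V, axis=1)
        med = np.median(nv[nv > 0]) if (nv > 0).any() else 0
        if med == 0:
            break
        el = np.linalg.norm(cur[faces[:, 0]] - cur[faces[:, 1]], axis=1).mean()
        V *= el / med
        nrm = np.linalg.norm(V, axis=1, keepdims=True)
        V *= np.minimum(1.0, el / np.maximum(nrm, 1e-30))
        V[is_b] = 0.0
        new = cur + step * V
        if (_tri_area_2d(new, faces) <= 0).any():
            step *= 0.5
            if step < 1e-3:
                break
            continue
        cur = new
    return cur


def disk_to_square(xy: np.ndarray) -> np.ndarray:
    """Elliptical grid mapping of the unit disk onto [-1, 1]^2."""
    u, v = xy[:, 0], xy[:, 1]
    t = u * u - v * v
    x = 0.5 * np.sqrt(np.maximum(2 + t + 2 * np.sqrt(2) * u, 0)) - 0.5 * np.sqrt(
        np.maximum(2 + t - 2 * np.sqrt(2) * u, 0))
    y = 0.5 * np.sqrt(np.maximum(2 - t + 2 * np.sqrt(2) * v, 0)) - 0.5 * np.sqrt(
        np.maximum(2 - t - 2 * np.sqrt(2) * v, 0))
    return np.stack([x, y], axis=1)


def rasterize_square(square_xy: np.ndarray, faces: np.ndarray, vertex_values: np.ndarray,
                     N: int = 128) -> np.ndarray:
    """Linear interpolation of vertex values onto an N x N pixel grid."""
    from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

    pix = (square_xy + 1.0) * 0.5 * (N - 1)
    gr = np.stack(np.meshgrid(np.arange(N), np.arange(N), indexing="ij"), axis=-1).reshape(-1, 2)
    lin = LinearNDInterpolator(pix[:, ::-1], vertex_values)  # (col,row)->(x,y) order fix
    vals = lin(gr[:, 1], gr[:, 0])
    nn = NearestNDInterpolator(pix[:, ::-1], vertex_values)
    miss = ~np.isfinite(vals)
    if miss.any():
        vals[miss] = nn(gr[miss, 1], gr[miss, 0])
    return vals.reshape(N, N)


@dataclass
class SquareParam:
    submesh: SurfaceMesh
    disk_xy: np.ndarray
    square_xy: np.ndarray
    N: int

    def raster(self, vertex_values, N=None):
        return rasterize_square(self.square_xy, self.submesh.faces, vertex_values,
                                N or self.N)

    def n_flipped(self):
        return int((_tri_area_2d(self.disk_xy, self.submesh.faces) <= 0).sum())


def unwrap_submesh_to_square(submesh: SurfaceMesh, N: int = 128,
                             relax: bool = True) -> SquareParam:
    """Open genus-0 submesh -> harmonic disk -> area relaxation -> square."""
    chi, g, b, _ = euler_genus(submesh)
    if b != 1 or g != 0:
        raise ValueError(
            f"square unwrap needs a genus-0 submesh with one boundary loop (genus={g}, boundaries={b})"
        )
    xy = harmonic_disk_map(submesh)
    if relax:
        xy = relax_disk_areas(submesh, xy)
    sq = disk_to_square(xy)
    return SquareParam(submesh=submesh, disk_xy=xy, square_xy=sq, N=N)


# ---------------------------------------------------------------------------
# Refinement of under-segmented blebs
# ---------------------------------------------------------------------------

def refine_blebs(mesh: SurfaceMesh, labels: np.ndarray, H: np.ndarray | None = None,
                 N: int = 128, min_area: float = 10.0, diffusion_iters: int = 10,
                 seed: int = 0) -> np.ndarray:
    """Split conjoined (under-segmented) blebs label by label.

    Each labelled submesh is unwrapped to an N x N square; the mapped mean
    curvature is thresholded at the upper 3-class Otsu threshold of the
    whole-mesh H, closed morphologically, and a gradient watershed on the
    Euclidean distance transform separates conjoined pseudo-circular
    regions.  Refined labels are diffused globally and small instances
    dropped.  Labels whose unwrap fails pass through unchanged.
    """
    from .mesh import mean_curvature_from_sdf
    from skimage.morphology import closing as binary_closing, disk
    from skimage.feature import peak_local_max

    labels = np.asarray(labels).copy()
    if H is None:
        H = mean_curvature_from_sdf(mesh)
    finite = H[np.isfinite(H)]
    try:
        thr = threshold_multiotsu(finite, classes=3)[-1]
    except ValueError:
        thr = float(np.percentile(finite, 75))
    next_label = labels.max() + 1
    new_labels = labels.copy()
    # a 'label' spanning several disconnected patches is first split into
    # one label per patch
    for lab in [l for l in np.unique(labels) if l > 0]:
        ncomp, comp = mesh_components(mesh, labels == lab)
        for c in range(2, ncomp + 1):
            new_labels[comp == c] = next_label
            next_label += 1
    labels = new_labels.copy()
    adjacency = mesh.vertex_adjacency()
    for lab in [l for l in np.unique(labels) if l > 0]:
        mask = labels == lab
        # impute interior holes: complement components below 10% of total area
        comp_n, comp = mesh_components(mesh, ~mask)
        va = mesh.vertex_areas()
        total = va.sum()
        for c in range(1, comp_n + 1):
            if va[comp == c].sum() < 0.10 * total:
                mask |= comp == c
        orig_mask = mask.copy()
        # one-ring dilation thickens pinched necks so the patch is a disk
        mask = mask | (adjacency @ mask.astype(float) > 0)
        sub, used = extract_submesh(mesh, mask)
        if sub.n_faces < 4:
            continue
        # keep the largest face-connected piece
        fe = np.sort(sub.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        uniq, inv = np.unique(fe, axis=0, return_inverse=True)
        inv = inv.reshape(-1, 3)
        E2F = sparse.coo_matrix(
            (np.ones(inv.size), (np.repeat(np.arange(sub.n_faces), 3), inv.ravel())),
            shape=(sub.n_faces, len(uniq)))
        FF = (E2F @ E2F.T) > 0
        ncf, flab = sparse.csgraph.connected_components(FF, directed=False)
        if ncf > 1:
            big = np.bincount(flab).argmax()
            keep_v = np.zeros(sub.n_vertices, dtype=bool)
            keep_v[np.unique(sub.faces[flab == big])] = True
            sub2, used2 = extract_submesh(sub, keep_v)
            used = used[used2]
            sub = sub2
        try:
            sq = unwrap_submesh_to_square(sub, N=N)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"unwrap failed for label {lab}: {exc}; passed through")
            continue
        Himg = sq.raster(H[used], N=N)
        binary = Himg > thr
        binary = binary_closing(binary, disk(1))
        if not binary.any():
            continue
        edt = ndi.distance_transform_edt(binary)
        # scale-adaptive peak separation: a single convex blob (inradius ~
        # edt.max) must yield one peak; conjoined lobes two
        peaks = peak_local_max(edt, min_distance=max(3, int(edt.max())),
                               labels=binary)
        if len(peaks) <= 1:
            continue
        markers = np.zeros_like(binary, dtype=np.int64)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        ws = watershed(-edt, markers=markers, mask=binary)
        sizes = np.bincount(ws.ravel())
        sizes[0] = 0
        substantial = (sizes >= 0.25 * binary.sum()).sum()
        if substantial < 2:  # no convincing split: keep the label whole
            continue
        # drop the insubstantial fragments from the split
        for c in np.nonzero((sizes > 0) & (sizes < 0.25 * binary.sum()))[0]:
            ws[ws == c] = 0
        # map split labels back to vertices of the submesh
        pix = np.clip(((sq.square_xy + 1) * 0.5 * (N - 1)).round().astype(int), 0, N - 1)
        vlab = ws[pix[:, 1], pix[:, 0]]
        for c in np.unique(vlab):
            if c <= 1:
                continue
            sel = used[vlab == c]
            sel = sel[orig_mask[sel]]  # never relabel the dilation ring
            new_labels[sel] = next_label
            next_label += 1
    # global re-diffusion
    A = combined_affinity(mesh)
    out = label_spreading(A, new_labels, n_iter=diffusion_iters, clamp=0.99,
                          background_is_class=False)
    out[labels == 0] = 0
    va = mesh.vertex_areas()
    for c in np.unique(out):
        if c and va[out == c].sum() < min_area:
            out[out == c] = 0
    return out


# ---------------------------------------------------------------------------
# Volume decomposition
# ---------------------------------------------------------------------------

def decompose_volume(
    topo_space: TopographicSpace,
    topo_binary: VolumeImage,
    topo_mesh: TopographicMesh,
    vertex_labels: np.ndarray,
    expand: int = 3,
    remesh_above: int = 1000,
    seed: int = 0,
):
    """Partition the topographic cell volume into a cortex and per-protrusion
    volumes, returning closed protrusion meshes.

    (1) d_ref image from the protrusion-free surface, inpainted over the
    removed-label pixels -> cortex binary {d < d_ref}; (2) surface labels
    stamped to voxels, expanded, masked by the cell binary; (3) top-to-bottom
    slice-wise marker watershed on the EDT, previous-slice labels taking
    precedence; (4) cortex masked out, largest component kept per label;
    (5) marching cubes (+ remesh when large) per protrusion.
    """
    from skimage.restoration import inpaint_biharmonic

    b = topo_binary.data.astype(bool)
    D, R, C = b.shape
    m = topo_mesh.mesh
    # -- reference d image from unlabeled (cortex) vertices
    d_img = np.full((R, C), np.nan)
    cnt = np.zeros((R, C))
    rows = np.clip(np.round(m.vertices[:, 1]).astype(int), 0, R - 1)
    cols = np.clip(np.round(m.vertices[:, 2]).astype(int), 0, C - 1)
    cortex_v = vertex_labels == 0
    acc = np.zeros((R, C))
    np.add.at(acc, (rows[cortex_v], cols[cortex_v]), m.vertices[cortex_v, 0])
    np.add.at(cnt, (rows[cortex_v], cols[cortex_v]), 1.0)
    have = cnt > 0
    d_img[have] = acc[have] / cnt[have]
    missing = ~have
    if missing.any():
        filled = inpaint_biharmonic(np.nan_to_num(d_img, nan=0.0), missing)
        d_img[missing] = filled[missing]
    dd = np.arange(D)[:, None, None]
    cortex = (dd < d_img[None]) & b
    # -- stamp surface labels to voxels
    lab_vol = np.zeros(b.shape, dtype=np.int64)
    didx = np.clip(np.round(m.vertices[:, 0]).astype(int), 0, D - 1)
    sel = vertex_labels > 0
    lab_vol[didx[sel], rows[sel], cols[sel]] = vertex_labels[sel]
    lab_vol = expand_labels(lab_vol, distance=expand)
    lab_vol[~b] = 0
    # -- slice-by-slice top-down marker watershed
    prev = np.zeros((R, C), dtype=np.int64)
    out_vol = np.zeros_like(lab_vol)
    for k in range(D - 1, -1, -1):
        slice_mask = b[k]
        if not slice_mask.any():
            prev = np.zeros((R, C), dtype=np.int64)
            continue
        markers = lab_vol[k].copy()
        override = prev > 0
        markers[override] = prev[override]
        markers[~slice_mask] = 0
        if markers.any():
            edt = ndi.distance_transform_edt(slice_mask)
            ws = watershed(-edt, markers=markers, mask=slice_mask)
        else:
            ws = np.zeros((R, C), dtype=np.int64)
        out_vol[k] = ws
        prev = ws
    # -- mask out cortex, keep largest component per label
    out_vol[cortex] = 0
    prot_vols = {}
    prot_meshes = {}
    for labv in [l for l in np.unique(vertex_labels) if l > 0]:
        this = out_vol == labv
        if not this.any():
            prot_vols[int(labv)] = 0.0
            continue
        cc = cc_label(this, connectivity=1)
        counts = np.bincount(cc.ravel())
        counts[0] = 0
        big = int(np.argmax(counts))
        this = cc == big
        prot_vols[int(labv)] = float(this.sum())
        try:
            pm = marching_cubes_like(this, remesh_above=remesh_above, seed=seed)
            prot_meshes[int(labv)] = pm
        except (ValueError, RuntimeError):
            pass
    return {
        "cortex_volume": VolumeImage(cortex.astype(np.uint8)),
        "protrusion_volumes": prot_vols,
        "protrusion_meshes": prot_meshes,
        "label_volume": VolumeImage(out_vol.astype(np.int32)),
        "d_ref_image": d_img,
    }


def marching_cubes_like(binary: np.ndarray, remesh_above: int = 1000, seed: int = 0):
    from .mesh import marching_cubes_mesh, remesh as _remesh

    vol = VolumeImage(np.pad(binary, 2).astype(np.uint8))
    mc = marching_cubes_mesh(vol, smooth_sigma=0.5)
    mc.vertices -= 2.0
    if mc.n_vertices > remesh_above:
        try:
            return _remesh(vol, 0.25, smooth_sigma=0.5, seed=seed)
        except ValueError:
            pass
    return mc


# ---------------------------------------------------------------------------
# Direct Cartesian decomposition (cap by least-bending patch)
# ---------------------------------------------------------------------------

def cap_boundary_loop(mesh: SurfaceMesh, loop: np.ndarray, subdivisions: int = 3):
    """Centroid-fan cap over a boundary loop, midpoint-subdivided and solved
    for least bending energy (bilaplacian) with the loop fixed."""
    import trimesh as _tm

    loop = np.asarray(loop)
    centroid = mesh.vertices[loop].mean(axis=0)
    verts = np.vstack([mesh.vertices[loop], centroid[None]])
    n = len(loop)
    faces = np.array([[k, (k + 1) % n, n] for k in range(n)], dtype=np.int64)
    for _ in range(subdivisions):
        # centroid (1-to-3) splits: boundary edges stay intact, so the cap
        # welds to the submesh rim without T-junctions
        cents = verts[faces].mean(axis=1)
        base = len(verts)
        verts = np.vstack([verts, cents])
        new = []
        for i, (a, b, c) in enumerate(faces):
            m = base + i
            new += [[a, b, m], [b, c, m], [c, a, m]]
        faces = np.asarray(new, dtype=np.int64)
    cap = SurfaceMesh(verts, faces)
    # fixed vertices: those on the original loop polyline (boundary of cap)
    bl = boundary_loops(cap)
    fixed = np.zeros(cap.n_vertices, dtype=bool)
    for l in bl:
        fixed[np.asarray(l)] = True
    L = build_operators(cap, "robust").laplacian
    B = (L @ L).tolil()
    free = ~fixed
    Bff = B[free][:, free].tocsc()
    Bfb = B[free][:, fixed].tocsr()
    x = cap.vertices.copy()
    if free.any():
        x[free] = splu(Bff).solve(-Bfb @ x[fixed])
    cap.vertices = x
    return cap


def cartesian_decompose(mesh: SurfaceMesh, labels: np.ndarray, subdivisions: int = 2):
    """Close each labelled protrusion submesh (and the residual cortex) with
    least-bending caps; returns per-label closed meshes + capped cortex."""
    prot = {}
    cortex_mask = labels == 0
    for lab in [l for l in np.unique(labels) if l > 0]:
        sub, used = extract_submesh(mesh, labels == lab)
        loops = boundary_loops(sub)
        if len(loops) != 1:
            warnings.warn(f"label {lab}: {len(loops)} boundary loops; skipped")
            continue
        cap = cap_boundary_loop(sub, np.asarray(loops[0]), subdivisions)
        merged = merge_meshes(sub, cap)
        prot[int(lab)] = merged
    cortex_sub, used = extract_submesh(mesh, cortex_mask)
    caps = []
    for loop in boundary_loops(cortex_sub):
        if len(loop) >= 3:
            caps.append(cap_boundary_loop(cortex_sub, np.asarray(loop), subdivisions))
    cortex = cortex_sub
    for cap in caps:
        cortex = merge_meshes(cortex, cap)
    return prot, cortex


def merge_meshes(a: SurfaceMesh, b: SurfaceMesh, tol: float = 1e-9) -> SurfaceMesh:
    """Concatenate two meshes, welding coincident vertices."""
    import trimesh as _tm

    verts = np.vstack([a.vertices, b.vertices])
    faces = np.vstack([a.faces, b.faces + a.n_vertices])
    tm = _tm.Trimesh(verts, faces, process=True)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
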