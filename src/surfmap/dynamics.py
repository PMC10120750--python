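"""Distortion-corrected timeseries, 2D bleb tracking, event alignment and
ruffle correlation/speed analyses on unwrapped (u, v) movies.

Because the equirectangular unwrap distorts area (most strongly at the
poles), every statistic over a (u, v) region is weighted by the
differential area dA of the underlying 3D surface — making means taken in
2D equal to means taken on the 3D mesh.  Dense optical flow enters through
a pluggable callable (two 8-bit images in, per-pixel 2D displacement out);
tests use synthetic ground-truth flow, and a standard iterative Lucas-
Kanade backend is provided for real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import interp1d
from scipy.optimize import linear_sum_assignment
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde


# ---------------------------------------------------------------------------
# Distortion-corrected statistics
# ---------------------------------------------------------------------------

def corrected_mean(uv_field: np.ndarray, uv_dA: np.ndarray, region_mask: np.ndarray):
    """dA-weighted mean of a (u, v) field over a region: the 2D equivalent of
    a 3D surface-area-weighted mean.  Returns NaN for an empty mask."""
    m = np.asarray(region_mask, dtype=bool)
    if not m.any():
        return float("nan")
    w = np.asarray(uv_dA, dtype=float)[m]
    f = np.asarray(uv_field, dtype=float)[m]
    return float((f * w).sum() / w.sum())


def spherical_pad(uv_image: np.ndarray, pad: int) -> np.ndarray:
    """Pad a (u, v) image respecting spherical topology: periodic wrap along
    u (columns); across each pole (rows) reflect and shift by half a period
    (a great-circle path over the pole re-enters at u + pi)."""
    img = np.asarray(uv_image)
    rows, cols = img.shape[:2]
    if pad >= rows / 2:
        raise ValueError("pad must be < rows/2")
    out = np.concatenate([img[:, -pad:], img, img[:, :pad]], axis=1)
    half = cols // 2
    top = out[1:pad + 1][::-1]
    top = np.roll(top, half, axis=1)
    bottom = out[-pad - 1:-1][::-1]
    bottom = np.roll(bottom, half, axis=1)
    return np.concatenate([top, out, bottom], axis=0)


# ---------------------------------------------------------------------------
# Optical flow backends
# ---------------------------------------------------------------------------

def ilk_flow_backend(im0: np.ndarray, im1: np.ndarray) -> np.ndarray:
    """Reference dense-flow backend (iterative Lucas-Kanade, scikit-image).
    Returns per-pixel (d_row, d_col) displacement of im0 -> im1."""
    from skimage.registration import optical_flow_ilk

    v, u = optical_flow_ilk(im0.astype(np.float32), im1.astype(np.float32))
    return np.stack([v, u], axis=-1)


def to_uint8(movie: np.ndarray) -> np.ndarray:
    """8-bit rescale with global (whole-movie) min/max."""
    lo, hi = float(np.min(movie)), float(np.max(movie))
    if hi <= lo:
        return np.zeros_like(movie, dtype=np.uint8)
    return ((movie - lo) / (hi - lo) * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Bleb tracking
# ---------------------------------------------------------------------------

@dataclass
class Track:
    id: int
    frames: list = field(default_factory=list)        # frame indices
    boxes: list = field(default_factory=list)         # (umin, vmin, umax, vmax)
    interpolated: list = field(default_factory=list)  # bool per entry

    @property
    def lifetime(self) -> int:
        return len(self.frames)

    def lifetime_seconds(self, frame_interval: float) -> float:
        return self.lifetime * frame_interval


def _boxes_from_labels(lab: np.ndarray, pad: int = 0):
    """Bounding box of each label's principal connected component.

    Padding duplicates blebs across the seam/poles; the box comes from the
    copy with the most pixels inside the unpadded core (ties: most pixels
    overall)."""
    from skimage.measure import label as cc_label

    core = np.zeros(lab.shape, dtype=bool)
    if pad:
        core[pad:lab.shape[0] - pad, pad:lab.shape[1] - pad] = True
    else:
        core[:] = True
    out = {}
    for c in np.unique(lab):
        if c == 0:
            continue
        comp = cc_label(lab == c, connectivity=2)
        ncomp = comp.max()
        counts_core = np.bincount((comp * core).ravel(), minlength=ncomp + 1)
        counts_all = np.bincount(comp.ravel(), minlength=ncomp + 1)
        counts_core[0] = counts_all[0] = 0
        score = counts_core * (counts_all.max() + 1) + counts_all
        rs, cs = np.nonzero(comp == np.argmax(score))
        out[int(c)] = (cs.min(), rs.min(), cs.max(), rs.max())
    return out


def _iou(a, b):
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    ix0, iy0 = max(ax0, bx0), max(ay0, by0)
    ix1, iy1 = min(ax1, bx1), min(ay1, by1)
    iw, ih = max(0.0, ix1 - ix0), max(0.0, iy1 - iy0)
    inter = iw * ih
    ua = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / ua if ua > 0 else 0.0


@dataclass
class TrackParams:
    pad: int = 50
    iou_threshold: float = 0.25
    max_propagation: int = 5
    min_track_length: int = 5
    min_mean_H: float = 0.1
    lifetime_match_fraction: float = 0.5
    area_jump: float = 500.0
    moving_avg_window: int = 3


def _shift_box(box, flow):
    x0, y0, x1, y1 = box
    r0 = int(np.clip(y0, 0, flow.shape[0] - 1))
    r1 = int(np.clip(y1, 0, flow.shape[0] - 1))
    c0 = int(np.clip(x0, 0, flow.shape[1] - 1))
    c1 = int(np.clip(x1, 0, flow.shape[1] - 1))
    sub = flow[r0:r1 + 1, c0:c1 + 1]
    if sub.size == 0:
        return box
    dv = float(np.median(sub[..., 0]))
    du = float(np.median(sub[..., 1]))
    return (x0 + du, y0 + dv, x1 + du, y1 + dv)


def track_blebs(per_frame_labels, per_frame_H=None, params: TrackParams | None = None,
                flow_backend=None):
    """Track per-frame instance label images into bleb tracks.

    Boxes are extracted on spherically padded images; frame-to-frame
    association is bipartite matching of flow-predicted boxes by IoU (> 0.25
    accepts); unmatched tracks are propagated by flow for up to 5 frames;
    tracks must exceed the minimum length and mean curvature; each bleb is
    uniquely matched per frame, tracks matched for < 50% of their lifetime
    are dropped; sudden box-area jumps are replaced by spline interpolation.
    """
    params = params or TrackParams()
    n_frames = len(per_frame_labels)
    pad = params.pad
    padded = [spherical_pad(l, pad) for l in per_frame_labels]
    flows = [None] * n_frames
    if flow_backend is not None and per_frame_H is not None:
        H8 = to_uint8(np.asarray(per_frame_H))
        H8p = [spherical_pad(h, pad) for h in H8]
        flows = [None] + [flow_backend(H8p[t - 1], H8p[t]) for t in range(1, n_frames)]
    frame_boxes = [_boxes_from_labels(l, pad=pad) for l in padded]

    active = []   # list of dict(track, last_box, misses)
    done = []
    next_id = 1
    for t in range(n_frames):
        boxes = list(frame_boxes[t].values())
        # predict active boxes by flow
        preds = []
        for a in active:
            box = a["last_box"]
            if flows[t] is not None:
                box = _shift_box(box, flows[t])
            preds.append(box)
        # bipartite matching on IoU
        if preds and boxes:
            cost = np.zeros((len(preds), len(boxes)))
            for i, p in enumerate(preds):
                for j, bx in enumerate(boxes):
                    cost[i, j] = -_iou(p, bx)
            ri, cj = linear_sum_assignment(cost)
        else:
            ri, cj = np.array([], int), np.array([], int)
        matched_tracks, matched_boxes = set(), set()
        for i, j in zip(ri, cj):
            if -cost[i, j] > params.iou_threshold:
                a = active[i]
                a["track"].frames.append(t)
                a["track"].boxes.append(boxes[j])
                a["track"].interpolated.append(False)
                a["last_box"] = boxes[j]
                a["misses"] = 0
                matched_tracks.add(i)
                matched_boxes.add(j)
        # unmatched active: propagate by flow
        still = []
        for i, a in enumerate(active):
            if i in matched_tracks:
                still.append(a)
                continue
            a["misses"] += 1
            if a["misses"] <= params.max_propagation:
                a["last_box"] = preds[i]
                still.append(a)
            else:
                done.append(a["track"])
        active = still
        # unmatched boxes: new tracks
        for j, bx in enumerate(boxes):
            if j not in matched_boxes:
                tr = Track(id=next_id)
                tr.frames.append(t)
                tr.boxes.append(bx)
                tr.interpolated.append(False)
                active.append({"track": tr, "last_box": bx, "misses": 0})
                next_id += 1
    done.extend(a["track"] for a in active)

    # filters
    kept = [tr for tr in done if tr.lifetime > params.min_track_length]
    if per_frame_H is not None:
        out = []
        for tr in kept:
            vals = []
            for t, (x0, y0, x1, y1) in zip(tr.frames, tr.boxes):
                Hp = spherical_pad(per_frame_H[t], pad)
                r0, r1 = int(max(y0, 0)), int(min(y1, Hp.shape[0] - 1))
                c0, c1 = int(max(x0, 0)), int(min(x1, Hp.shape[1] - 1))
                if r1 >= r0 and c1 >= c0:
                    vals.append(Hp[r0:r1 + 1, c0:c1 + 1].mean())
            if vals and np.mean(vals) > params.min_mean_H:
                out.append(tr)
        kept = out
    # unique bleb-to-track matching and lifetime-match fraction
    final = []
    for tr in kept:
        matched = 0
        for t, box in zip(tr.frames, tr.boxes):
            best = max((_iou(box, b) for b in frame_boxes[t].values()), default=0.0)
            if best > params.iou_threshold:
                matched += 1
        if matched / tr.lifetime >= params.lifetime_match_fraction:
            final.append(tr)
    # box-area jump correction
    for tr in final:
        _correct_area_jumps(tr, params)
        # unpad coordinates
        tr.boxes = [(x0 - pad, y0 - pad, x1 - pad, y1 - pad) for x0, y0, x1, y1 in tr.boxes]
    return final


def _moving_average(x, w):
    x = np.asarray(x, dtype=float)
    if len(x) < w:
        return x.copy()
    k = np.ones(w) / w
    out = np.convolve(x, k, mode="same")
    # fix edges with shrinking windows
    for i in range(w // 2):
        out[i] = x[: i + w // 2 + 1].mean()
        out[-(i + 1)] = x[-(i + w // 2 + 1):].mean()
    return out


def _correct_area_jumps(tr: Track, params: TrackParams):
    if tr.lifetime < 4:
        return
    areas = np.array([(x1 - x0) * (y1 - y0) for x0, y0, x1, y1 in tr.boxes], dtype=float)
    smooth = _moving_average(areas, params.moving_avg_window)
    bad = np.abs(areas - smooth) > params.area_jump
    if not bad.any() or bad.all():
        return
    good = ~bad
    tt = np.asarray(tr.frames, dtype=float)
    boxes = np.asarray(tr.boxes, dtype=float)
    for k in range(4):
        kind = "linear" if good.sum() > 1 else "nearest"
        f = interp1d(tt[good], boxes[good, k], kind=kind, bounds_error=False,
                     fill_value=(boxes[good, k][0], boxes[good, k][-1]))
        boxes[bad, k] = f(tt[bad])
    tr.boxes = [tuple(b) for b in boxes]
    tr.interpolated = list(np.asarray(tr.interpolated) | bad)


# ---------------------------------------------------------------------------
# Event alignment
# ---------------------------------------------------------------------------

def align_bleb_events(area_series_list, window: int = 14, prominence: float = 0.5,
                      min_separation: int = 3, smooth_window: int = 3):
    """Detect blebbing events as peaks of (smoothed) per-track area series and
    average windows of +-``window`` timepoints centred on each peak.

    Returns dict with per-event windows (NaN-padded), the mean profile, the
    s.e.m., and event (track_index, time) pairs.
    """
    events = []
    windows = []
    width = 2 * window + 1
    for ti, series in enumerate(area_series_list):
        s = np.asarray(series, dtype=float)
        sm = _moving_average(s, smooth_window)
        peaks, _ = find_peaks(sm, prominence=prominence, distance=min_separation)
        for p in peaks:
            events.append((ti, int(p)))
            w = np.full(width, np.nan)
            lo = max(0, p - window)
            hi = min(len(s), p + window + 1)
            w[lo - (p - window): width - (p + window + 1 - hi)] = s[lo:hi]
            windows.append(w)
    if not windows:
        return {"events": [], "windows": np.zeros((0, width)),
                "mean": np.full(width, np.nan), "sem": np.full(width, np.nan)}
    W = np.vstack(windows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(W, axis=0)
        n = np.sum(np.isfinite(W), axis=0)
        sem = np.nanstd(W, axis=0) / np.sqrt(np.maximum(n, 1))
    return {"events": events, "windows": W, "mean": mean, "sem": sem}


# ---------------------------------------------------------------------------
# ROI tracking and cross-correlation
# ---------------------------------------------------------------------------

def normalized_xcorr(a, b):
    """Full-lag normalized cross-correlation of two 1D series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return np.zeros(2 * len(a) - 1)
    return np.correlate(a, b, mode="full") / denom


def track_rois_and_correlate(uv_TC_movie, uv_H_movie, uv_dA, n_rois: int = 100,
                             roi_width: int | None = None, flow_backend=None,
                             region_mask=None):
    """Grid-initialized ROI tracking by median dense flow + distortion-
    corrected TC/H timeseries + per-ROI normalized cross-correlation.

    Returns per-ROI tracks, correlation curves, and the population mean with
    a 95% normal-approximation confidence band per lag.
    """
    TC = np.asarray(uv_TC_movie, dtype=float)
    H = np.asarray(uv_H_movie, dtype=float)
    n_frames, rows, cols = TC.shape
    if flow_backend is None:
        flow_backend = ilk_flow_backend
    TC8 = to_uint8(TC)
    # grid init
    ngrid = int(np.ceil(np.sqrt(n_rois * rows / cols)))
    mgrid = int(np.ceil(n_rois / ngrid))
    r0 = np.linspace(0, rows - 1, ngrid + 2)[1:-1]
    c0 = np.linspace(0, cols - 1, mgrid + 2)[1:-1]
    R0, C0 = np.meshgrid(r0, c0, indexing="ij")
    pos0 = np.stack([R0.ravel(), C0.ravel()], axis=1)[:n_rois]
    if region_mask is not None:
        sel = region_mask[pos0[:, 0].astype(int), pos0[:, 1].astype(int)]
        pos0 = pos0[sel]
    if roi_width is None:
        roi_width = max(3, int(round(np.sqrt(rows * cols / max(len(pos0), 1)) / 2)) * 2 + 1)
    half = roi_width // 2
    traj = np.zeros((n_frames, len(pos0), 2))
    traj[0] = pos0
    alive = np.ones(len(pos0), dtype=bool)
    for t in range(1, n_frames):
        flow = flow_backend(TC8[t - 1], TC8[t])
        for i in range(len(pos0)):
            if not alive[i]:
                traj[t, i] = traj[t - 1, i]
                continue
            r, c = traj[t - 1, i]
            rr0, rr1 = int(max(r - half, 0)), int(min(r + half, rows - 1))
            cc0, cc1 = int(max(c - half, 0)), int(min(c + half, cols - 1))
            sub = flow[rr0:rr1 + 1, cc0:cc1 + 1]
            dr = float(np.median(sub[..., 0])) if sub.size else 0.0
            dc = float(np.median(sub[..., 1])) if sub.size else 0.0
            nr, nc = r + dr, c + dc
            if not (0 <= nr < rows and 0 <= nc < cols):
                alive[i] = False
                nr, nc = r, c
            traj[t, i] = (nr, nc)
    # corrected timeseries + cross-correlation per ROI
    curves = []
    for i in range(len(pos0)):
        tc_series, h_series = [], []
        for t in range(n_frames):
            r, c = traj[t, i]
            rr0, rr1 = int(max(r - half, 0)), int(min(r + half, rows - 1))
            cc0, cc1 = int(max(c - half, 0)), int(min(c + half, cols - 1))
            mask = np.zeros((rows, cols), dtype=bool)
            mask[rr0:rr1 + 1, cc0:cc1 + 1] = True
            tc_series.append(corrected_mean(TC[t], uv_dA, mask))
            h_series.append(corrected_mean(H[t], uv_dA, mask))
        curves.append(normalized_xcorr(np.array(tc_series), np.array(h_series)))
    curves = np.asarray(curves)
    mean = curves.mean(axis=0) if len(curves) else np.zeros(2 * n_frames - 1)
    sem = curves.std(axis=0, ddof=1) / np.sqrt(max(len(curves), 1)) if len(curves) > 1 else np.zeros_like(mean)
    ci95 = 1.96 * sem
    lags = np.arange(-(n_frames - 1), n_frames)
    lag0 = n_frames - 1
    significant = abs(mean[lag0]) > ci95[lag0]
    return {
        "trajectories": traj,
        "curves": curves,
        "lags": lags,
        "mean": mean,
        "ci95": ci95,
        "lag0_significant": bool(significant),
    }


# ---------------------------------------------------------------------------
# Speed populations and conditional expectation
# ---------------------------------------------------------------------------

def speed_populations(track_speeds, speed_range=(0.0, 10.0), nbins: int = 25):
    """Slow/fast population means of per-track speeds (um/min) estimated as
    the two 3-class Otsu thresholds of the speed distribution.

    The lower threshold is reported as the slow (retrograde-flow) mean, the
    upper as the fast (ruffle) mean.  Near-unimodal inputs trigger a
    bimodality warning.
    """
    from skimage.filters import threshold_multiotsu

    s = np.asarray(track_speeds, dtype=float)
    s = s[(s >= speed_range[0]) & (s <= speed_range[1])]
    if len(np.unique(s)) < 3:
        warnings.warn("degenerate speed distribution")
        v = float(s.mean()) if len(s) else float("nan")
        return v, v
    hist, edges = np.histogram(s, bins=nbins, range=speed_range)
    try:
        t1, t2 = threshold_multiotsu(hist=(hist, (edges[:-1] + edges[1:]) / 2), classes=3)
    except ValueError:
        warnings.warn("3-class Otsu failed; falling back to percentiles")
        t1, t2 = np.percentile(s, [33, 66])
    # crude bimodality check: dip between the two otsu classes
    mids = (edges[:-1] + edges[1:]) / 2
    lowpk = hist[(mids < t1)].max() if (mids < t1).any() else 0
    midmin = hist[(mids >= t1) & (mids <= t2)].min() if ((mids >= t1) & (mids <= t2)).any() else 0
    hipk = hist[(mids > t2)].max() if (mids > t2).any() else 0
    if not (midmin < 0.8 * lowpk and midmin < 0.8 * hipk):
        warnings.warn("speed distribution may be unimodal; population split unreliable")
    return float(t1), float(t2)


def conditional_expectation(x, y, x_range=(-0.2, 0.6), y_range=(-1.0, 1.0), nbins: int = 100):
    """E[Y | X = x] curve and conditional s.d. from a Gaussian KDE (Scott
    bandwidth) of the joint density, via the marginal integral ratios."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    kde = gaussian_kde(np.vstack([x, y]))
    xs = np.linspace(*x_range, nbins)
    ys = np.linspace(*y_range, nbins)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    P = kde(np.vstack([X.ravel(), Y.ravel()])).reshape(nbins, nbins)
    px = P.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Ey = (P * ys[None]).sum(axis=1) / px
        Ey2 = (P * ys[None] ** 2).sum(axis=1) / px
        sd = np.sqrt(np.maximum(Ey2 - Ey**2, 0.0))
    empty = px < 1e-3 * px.max()
    Ey[empty] = np.nan
    sd[empty] = np.nan
    return xs, Ey, sd


def plane_fit_speed_projection(tracks_3d, bottom_vertices, voxel_size=(1.0, 1.0, 1.0),
                               frame_interval: float = 1.0):
    """Project 3D track velocities onto the best-fit plane of the cell-bottom
    vertices (PCA normal) and return per-track mean planar speeds (um/min).

    ``tracks_3d``: list of (n_frames, 3) coordinates in voxel units.
    """
    pts = np.asarray(bottom_vertices, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 bottom vertices for a plane fit")
    pts_um = pts * np.asarray(voxel_size)
    ctr = pts_um.mean(axis=0)
    _, _, VT = np.linalg.svd(pts_um - ctr, full_matrices=False)
    normal = VT[-1]
    speeds = []
    for tr in tracks_3d:
        p = np.asarray(tr, dtype=float) * np.asarray(voxel_size)
        v = np.diff(p, axis=0) / frame_interval  # um per second
        v_plane = v - np.outer(v @ normal, normal)
        sp = np.linalg.norm(v_plane, axis=1).mean() * 60.0  # um/min
        speeds.append(float(sp))
    return np.asarray(speeds), normal


def surface_proximal_sampling(volume, mesh, depth_um: float = 1.0, statistic: str = "mean",
                              voxel_size=(1.0, 1.0, 1.0), n_steps: int = 10,
                              normalize_to_volume_mean: bool = False,
                              cell_binary=None):
    """Per-vertex intensity by sampling inward along the steepest gradient of
    the distance transform to an absolute depth (um).

    ``statistic``: 'mean' (diffuse markers) or 'p95' (the brightest cortical
    accumulation along the trajectory).  Optionally normalizes by the whole-
    cell mean intensity (bleaching correction).
    """
    from scipy import ndimage as ndi
    from .mesh import signed_distance

    if statistic not in ("mean", "p95"):
        raise ValueError("statistic must be 'mean' or 'p95'")
    data = volume.data.astype(float)
    if cell_binary is None:
        from .mesh import voxelize
        cb = voxelize(mesh, dilation_radius=3, grid_shape=volume.data.shape,
                      offset=volume.origin_offset)
        cell = cb.data.astype(bool)
    else:
        cell = cell_binary.data.astype(bool)
    sdf = signed_distance(cell, positive_inside=True)
    g = np.stack(np.gradient(sdf), axis=0)
    gn = np.linalg.norm(g, axis=0)
    gn[gn == 0] = 1.0
    g = g / gn
    vsize = np.asarray(voxel_size, dtype=float)
    depth_vox = depth_um / vsize.mean()
    step = depth_vox / n_steps
    pts = mesh.vertices + volume.origin_offset
    samples = []
    shape = np.array(data.shape)
    truncated = 0
    cur = pts.copy()
    for _ in range(n_steps + 1):
        coords = cur.T
        samples.append(ndi.map_coordinates(data, coords, order=1, mode="nearest"))
        vel = np.stack([ndi.map_coordinates(g[k], coords, order=1, mode="nearest")
                        for k in range(3)], axis=1)
        nxt = cur + step * vel  # +grad of positive-inside SDF points inward
        oob = ((nxt < 0) | (nxt > shape - 1)).any(axis=1)
        truncated += int(oob.sum())
        nxt[oob] = cur[oob]
        cur = nxt
    S = np.stack(samples, axis=0)  # (n_steps+1, n_vertices)
    out = np.percentile(S, 95, axis=0) if statistic == "p95" else S.mean(axis=0)
    if normalize_to_volume_mean:
        denom = data[cell].mean() if cell.any() else data.mean()
        out = out / max(denom, 1e-12)
    return out
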