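# Methods

This note documents the models and numerical choices behind `surfmap`: what
each stage computes, which parameters matter, what the synthetic phantoms do
and do not emulate, and where the design was genuinely open.

## Discrete operators and conventions

Meshes are triangle meshes with vertices in voxel units, `(z, y, x)` grid
order when tied to a volume; a `VolumeImage` carries the physical voxel size
for conversion to micrometres.  The Laplacian is the cotangent matrix with
zero row sums; genuinely negative cotangent weights of obtuse triangles are
**kept** (they carry the conformal structure — clamping them measurably
biases the spherical map away from conformality), and only non-finite
weights from degenerate faces are zeroed.  The "robust" variant applies
intrinsic mollification (a constant added to edge lengths until every
triangle inequality holds with slack) before computing cotangents from the
law of cosines.  The mass matrix is the barycentric lump (vertex area =
one third of incident face area).

Mean curvature is measured volumetrically as H = −½ ∇·n̂ with n̂ the unit
gradient of the Euclidean signed distance transform of the binary cell mask
(positive inside, so a sphere has H = +1/r and protrusions are positive).
This is deliberately independent of mesh tessellation quality.  Gaussian
curvature uses the angular deficit, 2π − Σθ at interior and π − Σθ at
boundary vertices, so Gauss–Bonnet (ΣK = 2πχ) holds exactly on closed
meshes.

## Voxelization and remeshing

Voxelization subdivides faces until the mean edge is below one voxel,
stamps face barycenters, then closes holes by ball-kernel dilation (default
radius 5, configurable — larger kernels close larger defects at the price
of smoothing fine protrusions), binary fill, and erosion with the same
kernel.  Because the stamped shell straddles the true surface, the filled
body overshoots by about half a voxel; a final face-connected erosion
debiases the volume (ball phantoms then agree with 4/3πr³ to within ~5%).

Remeshing is marching cubes at isovalue 0.5 (after Gaussian σ = 1 smoothing
of the binary) followed by a deterministic Lloyd-style vertex-clustering
remesh: cluster centers seeded by a seeded permutation, a few
nearest-center/centroid-update rounds, and the cluster-adjacency dual as
the output faces.  Occasional pinch defects (edges shared by more than two
faces) are repaired by edge collapse.  The result is watertight, genus-0
for simply connected binaries, with median radius ratio ≈ 0.83 — above the
0.7 quality floor the relaxation needs.  Any uniform-clustering isotropic
remesher meeting these postconditions would be interchangeable here.

## Conformalized mean curvature flow

cMCF solves (M_t − δt L₀) v(t+δt) = M_t v(t) by sparse LU each iteration
(M_t changes, so the matrix is refactorized); the frozen L₀ preserves face
aspect ratios and avoids pinch singularities.  After each step the surface
area is normalized to 1 and the centroid recentred, and the mean absolute
Gaussian curvature |K̄_t| is evaluated on the normalized mesh so the
stopping criterion is scale-free.  Default δt = 5·10⁻⁴ on the unit-area
mesh; the automatic stop is stop_t = max(t_min, t_K) with t_K the first
iteration at which |Δ|K̄_t|| falls below Δ_thresh (default 10⁻⁵) — the
elbow of the curvature trace.  A literal alternative reading (first
iteration *exceeding* the threshold) is available behind a flag but fires
immediately on any realistic trace; the elbow reading is the default
because the intended reference surface is the smoothed-but-not-yet-spherical
iterate.

The active-contour variant adds an external force:
(M_t − δt L₀) v(t+1) = M_t (v(t) + α f(v)).  With f the unit SDF gradient,
the mesh advances in equal α-voxel normal steps (verified against analytic
sphere offsets).  The topographic variant flattens open (d, u, v) sheets:
interior vertices follow cMCF, boundary vertices keep (u, v) fixed while d
evolves under a 1D line mass/Laplacian along the boundary polyline, so the
flow limit is the planar rectangle rather than a point.

## Spherical parameterization

Stage one maps a closed genus-0 mesh to the unit sphere: cMCF run until the
vertex-radius spread drops below 2·10⁻³ (for genus-0 input the flow
converges conformally to the sphere), radial projection, then Möbius
centering of the area centroid (Möbius transforms are the conformal
automorphisms of the sphere, so centering is free).  On smooth reference
surfaces this yields global conformal error 𝒬 ≈ 1.007 with zero flipped
faces; on raw bumpy phantoms 𝒬 ≈ 1.02–1.05, which is why the pipeline
parameterizes the smooth reference, not the input.

Stage two relaxes area distortion.  Per iteration: normalize source/sphere
face areas to fractions, λ_f = ref-fraction / sphere-fraction, V = −∇log λ
via the per-face P1 gradient of the vertex-averaged log λ, rescale V so its
median norm equals the mean edge length, cap the heavy tail at one edge
length (so no vertex jumps across its one-ring — without the cap the rare
λ-gradient spikes in strongly compressed patches flip faces immediately),
average to vertices, project tangentially, advect by an implicit
active-contour step (ε = 1, stiffness δ = 0.1, retry δ = 5·10⁻³ if the
equiareal target is missed), and renormalize to the sphere.  The iteration
stops when |mean λ − 1| < 10⁻², a face collapses (flip or interior angle
below 5% of the initial minimum — the last valid iterate is returned,
flagged), or the budget (100) is reached.  The whole (𝒬, λ) trajectory is
cached, so the four stopping criteria — equiareal |λ̄ − 1|, MIPS
σ₂/σ₁ + σ₁/σ₂ (minimal, 2, at iteration 0), area-preserving MIPS
(σ₂/σ₁ + σ₁/σ₂)(σ₁σ₂ + 1/(σ₁σ₂))^θ with θ = 1, and the isometric
combination (1−θ)𝒬 + θ·log λ̄ with θ = 0.5 — can be extracted post hoc
without re-running.  Singular values come from the per-face simplicial map
between the unit-area-normalized meshes.

Two area-distortion conventions are exposed under distinct names:
`area_distortion_lambda` (source fraction over target fraction, the
quantity relaxed to 1) and `area_fraction_ratio` (its reciprocal, used when
reporting how much area a mapped feature retains).

## UV unwrapping

The unwrapping axis comes from the weighted second moment Σᵢ wᵢ vᵢ vᵢᵀ of
the sphere vertices about the origin; the smallest-eigenvalue eigenvector
is the pole axis, with sign fixes making a proper rotation.  Taking moments
about the origin (not the weighted mean) is essential: for a weight patch
at direction n the small-variance axes are then perpendicular to n, so the
patch rotates to the equator where equirectangular distortion is least.
Near-isotropic weights fall back to the identity with a warning.

The equirectangular grid samples pixel centres, rows v ∈ (0, π), columns
u ∈ (0, 2π), rows:cols = 1:2 (2N columns for images; 2N+1 with duplicated
seam when the grid will be triangulated and stitched).  Pixel directions
are matched to spherical triangles by KD-tree candidates plus ray-triangle
intersection; unmatched pixels (numerical gaps) fall back to the nearest
candidate face and are counted.  Barycentric weights then pull back the
vertices of any bijective partner mesh, or any vertex field.  v = 0 is the
north pole along +e₃ and u = 0 the azimuth of +e₁ (the convention is
otherwise free).

## Topographic space

Φ is the signed distance of the voxelized reference (negative inside, so
+d is outward).  The UV lookup sheet is propagated by explicit Euler steps
S(d±α) = S(d) ± α ∇Φ/|∇Φ| with per-step sheet smoothing (separable box
filter window 5 by default; a heavier Gaussian "robust" mode for noisy
propagation).  α defaults to 0.5 voxels; D_out is chosen automatically so
the space encapsulates the whole cell binary; D_in defaults to half the
maximum internal distance.  Monotonicity of Φ along each trajectory is
audited and violations flagged.  Forward (d, u, v) → (x, y, z) mapping is
trilinear interpolation of the lookup; the inverse is a KD-tree nearest
node plus Gauss-Newton refinement in the trilinear cell (round trips are
sub-voxel).  Volumes are pulled into topographic space by trilinear
interpolation at the lookup coordinates, out-of-grid voxels zeroed and
counted.

## Protrusion segmentation

The (u, v) height image takes, per pixel, the longest contiguous
foreground run along d (robust to internal voids from meshing errors).
The reference height field is a 2D asymmetric Whittaker baseline: minimize
Σ w (d − z)² + λ‖Δz‖² with w = p above the fit and 1−p below (p = 0.25,
λ = 1, 10 iterations, 8× downsampling for speed and extra smoothness).
The difference matrices penalize only interior second differences —
penalizing boundary rows drags the baseline toward zero at the edges.
The 1D version of the same objective serves as the test oracle.

Binary segmentation thresholds h = d − d_ref at the mean height (with a
tiny deadband so an exactly flat sheet yields nothing), prunes components
below the pre-threshold area, smooths by 2-class label spreading
(F ← 0.99·S F + 0.01·Y on A = 0.9·A_dist + 0.1·A_convex, 20 iterations,
re-binarizing foreground probability at 0.25 each iteration), and prunes
again.  Affinities are assembled sparsely over mesh edges: Gaussian of
Euclidean edge length, and Gaussian of the cosine distance (1 − cos θ)/2
between endpoint vertex normals (the dihedral term that slows diffusion
across curvature discontinuities).  The area thresholds (200/500/100/10
voxel²) are the defaults for full-size cells and scale down for test-size
phantoms via the config.

Instance segmentation finds protrusion tops as connected regions of high
topographic mean curvature: 3-class k-means on σ = 1-smoothed H for
blebs/filopodia, a 3-component Gaussian mixture on (σ = 1, 3, 5) features
for lamellipodia, both fitted on 10 000 sampled shell voxels with a seeded
state and an Otsu fallback if clustering degenerates.  Labels are expanded
3 voxels, transferred to the mesh, intersected with the binary mask,
pruned by Cartesian area, and diffused 10 iterations with the background
treated as *unlabeled* (labels must be able to expand; in the 2-class
binary mode the background is a competing class — the two semantics are an
explicit switch).

Undersegmented blebs are refined per label: interior holes imputed
(complement components under 10% of total area), a one-ring dilation to
thicken pinched necks, unwrap of the largest face-connected piece to a
square (harmonic disk map with boundary edge-length fractions preserved,
in-disk −∇log λ relaxation with flip rejection, elliptical disk-to-square
mapping), thresholding of the mapped H at the upper whole-mesh 3-class
Otsu threshold, and a watershed on the Euclidean distance transform.  The
peak separation is scale-adaptive (minimum distance = the EDT maximum, the
blob inradius) and a split is accepted only when at least two regions hold
≥ 25% of the binary each — a single convex blob therefore never splits.
Labels that fail to unwrap pass through unchanged.

Volume decomposition inpaints the protrusion-free d_ref image (biharmonic
inpainting), takes {d < d_ref} as the cortex, stamps surface labels into
the volume, expands 3 voxels, and propagates them top-to-bottom by
slice-wise marker watershed on the EDT with previous-slice labels taking
precedence; cortex voxels are then masked out and the largest component
kept per label.  The partition conserves the cell volume to < 2% on
phantoms.  The purely Cartesian alternative closes each protrusion
boundary loop with a centroid fan, refines it by centroid (1-to-3) splits
— midpoint subdivision would split rim edges and leave T-junctions when
welding — and solves the bilaplacian for least-bending interior positions.

## Dynamics

All regional statistics are dA-weighted so 2D means equal 3D means (tested
to 1% against the mesh-side oracle).  Spherical padding wraps u
periodically and reflects across each pole with a half-period u-shift.
Bleb tracking extracts per-label boxes on padded images (per label, the
connected component with most pixels in the unpadded core — padding
duplicates blebs across the seam), associates frames by bipartite matching
of flow-predicted boxes with IoU > 0.25, propagates unmatched tracks up to
5 frames, filters by length (> 5), mean curvature (> 0.1 μm⁻¹), and
lifetime-match fraction (≥ 50%), and replaces box-area jumps (> 500 px²
from the 3-frame moving average) by linear-spline interpolation.  Dense
optical flow is a pluggable callable (two 8-bit frames → per-pixel 2D
displacement); the provided backend is iterative Lucas–Kanade
(scikit-image), and tests use ground-truth synthetic flow so tracking
logic is tested independently of any flow estimator.

Event alignment smooths per-track area series (window 3), detects peaks
with prominence > 0.5 separated by ≥ 3 timepoints, and averages ±14-point
windows (NaN-padded at track ends, excluded lag-wise from the mean).  ROI
tracking seeds a uniform grid, advances each ROI by the median flow in its
window, extracts corrected TC and H series, and reports per-ROI normalized
cross-correlations with a normal-approximation 95% band (significant
instantaneous coupling = band excluding 0 at lag 0).  Speed populations
follow the 3-class-Otsu convention: the two thresholds of the per-track
speed distribution (25 bins over 0–10 μm/min) are reported as the slow and
fast population means, with a bimodality warning on near-unimodal input;
on a planted 0.5/4.2 μm/min mixture the fast estimate lands within 0.5 of
4.2.  Conditional expectation curves use a Scott-bandwidth Gaussian KDE
over 100×100 bins and the marginal integral ratios.

## Synthetic phantoms

Phantoms are icosphere-based cells (default base radius 20–25 voxels, so
complete pipelines run in seconds to minutes on one CPU) with hemispherical
blebs, elongated Gaussian ridges and conical spikes at seeded Fibonacci
directions; hole defects remove a surface cap and handle defects weld a
tube between two punched openings, raising the genus.  Volumes add a
membrane-proximal Gaussian shell channel with optional curvature-coupled
amplitude and exponential bleach.  Movies oscillate bleb radii
sinusoidally with per-bleb phase and emit ground-truth boxes and event
times.  Everything is bit-identical under a fixed (spec, seed).

What phantoms do *not* emulate: microscope anisotropy and PSF blur,
Poisson shot noise, segmentation errors beyond idealized holes/handles,
drifting or deforming cortices, and protrusion densities at which
neighbouring features merge.  Passing tests therefore demonstrate the
correctness of the geometry processing and the recovery logic under
controlled conditions, not robustness to raw microscopy artefacts.

## Problem sizes

The default test and validation scales are chosen for single-CPU runs:
the seeded validation phantom is the 10242-vertex icosphere with five
hemispherical blebs (remeshed reference ≈ 13k vertices), unit-test
phantoms use 642–2562 vertices, UV grids N = 64 in tests (the production
default is N = 256, matching the 1:2 equirectangular aspect at 512×1024),
and the robustness battery runs twenty phantom specs at the small scale.

## Known limitations

* The spherical map is flow-based; on highly elongated or very
  high-curvature inputs its conformal error grows (≈ 1.02–1.05 on raw
  bumpy phantoms), whereas quasi-conformal composition methods hold 𝒬
  closer to 1.  The pipeline mitigates this by always parameterizing the
  smooth reference surface.
* The disk relaxation for protrusion submeshes is a capped gradient flow
  without Delaunay edge flips; very long, thin spikes may retain residual
  area distortion (the prescribed fallback — downsample and remesh the
  submesh first — is what `refine_blebs` does).
* Volume voxelization carries a ±half-voxel surface bias after debiasing;
  sub-voxel volume accuracy requires finer grids.
* The topographic space is static; timelapse use assumes cell shape stays
  within the mapped subvolume (one space is reused across frames).
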