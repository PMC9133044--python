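# Methods

This note documents the models, conventions and numerical choices behind
`duratrace`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic-data validation does and
does not demonstrate.

## Synthetic phantoms (`synthgen`)

**Neurite trees.** Phantom innervation is a random binary tree: a trunk
grows from a random interior point, each active tip extends by one straight
segment (length ~ U(45, 70) µm by default, in-plane direction wandering
±10°, gentle z drift) and either bifurcates (in-plane branch angle
U(25, 50)°) or terminates, until the requested endpoint count (root + leaves)
is placed. Whole trees are rejection-sampled until they fit inside the stack
margins **and** all non-adjacent branches stay ≥ 12 µm apart in the xy
projection (`min_clearance_um`). The clearance rule is deliberate: branches
that collide in projection genuinely change the 2D topology (crossings fuse
into degree-4 nodes), so exact endpoint recovery is only a meaningful claim
for non-overlapping phantoms. Real dural networks do contain crossings;
recovered endpoint counts on real data inherit that ambiguity.

**Rendering.** Voxels within the tube radius (default 2 µm) of any
centerline take a constant amplitude (default 100), blurred by an isotropic
Gaussian PSF (σ = 1 µm), on a constant background (10), with additive
Gaussian read noise and optional Poisson shot noise. SNR is
amplitude / Gaussian σ. Voxel spacing defaults to (1.14, 1.14, 1.0) µm,
matching the confocal acquisition the phantoms emulate. What the model
omits: depth-dependent attenuation, anisotropic PSF, autofluorescence,
vessel channels, tissue deformation — passing tests bound algorithmic error,
not robustness to these effects.

**Point patterns.** CSR is a homogeneous Poisson process (Poisson count,
uniform positions); `fixed_n` is the binomial process; Thomas clusters draw
Poisson parents in a 4σ buffer around the window (edge-stationary) with
Poisson offspring displaced by an isotropic Gaussian; hard-core uses
sequential inhibition. Patterns live in continuous µm coordinates;
rasterization to pixels happens only in `render_blob_image`. All generators
are pure functions of (spec, seed).

## Enhancement (`enhance`)

MIP along z, then multiscale Frangi vesselness (scikit-image backend):
bright-ridge response `exp(−R_B²/2β²)(1 − exp(−S²/2c²))`, zero where the
large Hessian eigenvalue is positive, maximum over scales. Defaults:
β = 0.5, scales {1, 2, 4, 8} px, `c="auto"` = half the maximum Hessian norm
per scale (the filter's classic recommendation). None of these are dictated
by the emulated protocol; they are canonical defaults, exposed in every
entry point. The enhanced image is min-max normalized to [0, 1]; a constant
input maps to P ≡ 0 so the cost image is 1 everywhere (no preferred path).
The bright map P drives segmentation; its complement 1 − P is the path cost.

## Tracing (`trace`)

**Centerline.** The "minimal path" is realized as the exact shortest path
on the 8-connected pixel graph with trapezoidal edge weights
`((c_u + c_v)/2 + ε)·step`, step ∈ {1, √2}, ε = 10⁻³. The discrete chamfer
metric was chosen over continuous fast marching because it admits an
*exact* independent oracle (exhaustive Dijkstra on the full pixel graph),
so optimality is testable as equality rather than approximation. ε keeps
the metric strictly positive (well-posed across zero-cost plateaus) and
the path finite.

**Segmentation.** Morphological front evolution: the dilated centerline
grows one pixel per iteration into neighbors whose speed P ≥ 0.5, followed
by a 3×3 majority (curvature) smoothing; 200 iterations, smoothing 1, no
balloon by default. Zero speed everywhere returns the initialization with a
warning; the final mask is the connected component containing the
centerline.

**Morphometry.** Diameter = 2 × Euclidean distance transform of the mask at
each centerline pixel, scaled by in-plane spacing. Each centerline pixel is
lifted to the arg-max z of its (1-voxel Gaussian-smoothed) stack column,
ties to the lowest z. Before summing segment lengths the lifted polyline is
smoothed with a centered 7-point moving average (endpoints pinned). This
matters: a raw 8-connected path overestimates Euclidean length by up to
8.2% at worst-case orientations (a staircase at 22.5°); the moving average
removes that bias while leaving collinear paths exact (a 101-pixel straight
run at 1.14 µm spacing measures exactly 114.0 µm). Both raw pixels and the
smoothed 3D polyline are retained on the trace.

## Innervation graph (`graph`)

Traces are merged on their shared pixel grid: identical consecutive-pixel
steps contributed by several traces (axons traced from a common stem) count
once; pixels of degree ≠ 2 become nodes; degree-2 chains become edges;
nodes within `merge_radius` (default 3 µm ≈ 2–3 px) are fused by
single-linkage, and fused pass-through nodes are spliced out. Metrics:
total length = Σ edge lengths (3D µm), endpoint count = degree-1 nodes.
2D crossings fuse into degree-4 junctions rather than being resolved as 3D
overpasses — a documented limitation of analyzing the projection.

## Point statistics (`pointstats`)

**Maxima.** Descending-intensity flood with union-find. When the region of
a lower summit meets a higher one, its prominence is summit − saddle level;
it is reported iff prominence ≥ noise tolerance (default 35, the emulated
detector's setting). Equal summits are ordered by the smallest linear index
of the summit plateau; plateau maxima are reported at the plateau centroid;
prominence-0 merges are never reported (plateau fragments). With edge
exclusion on, a maximum is dropped when the connected component of
`img ≥ summit − tolerance` containing it touches the border. All
conventions are mirrored by an independent threshold-descent oracle in the
tests, which the detector matches exactly on random integer images.

**Quadrats.** rows × cols equal rectangles, half-open on right/top except
the last row/column (every point counted once). Normality of the flattened
counts is Shapiro–Wilk (D'Agostino selectable); p > 0.05 is read as "do not
reject Gaussian". Identical counts return NaN (test undefined).

**Ripley K.** `K̂(r) = (A/(n(n−1))) Σ_{i≠j} e_ij 1(d_ij ≤ r)`; translation
correction `e_ij = A/((W−|Δx|)(H−|Δy|))` (exact for rectangles, default) or
uncorrected (retained because it admits an exact brute-force oracle).
Default r-grid: 50 points up to ¼ of the shorter window side.

**Envelope.** `n_sims` (default 100) binomial CSR patterns with the
observed n in the observed window; band = pointwise min/max of simulated
K̂; verdict "random" iff the observed curve stays inside the band at every
grid distance. The pointwise band is exact at level 2/(n_sims+1) per
distance (verified: 2.25% measured at a single r), but the *joint* "outside
anywhere" rule inflates type-I error over the correlated grid: measured
~17–26% across realistic settings, ~20% at the default window/density/grid.
This is an inherent property of pointwise Monte-Carlo envelopes, not a
calibration knob; the test suite asserts a 15% specificity bound that this
default verdict does not meet, and the corresponding check is expected to
fail. Power against tight Thomas clusters is essentially 100%. A
rank-aware alternative (global envelopes) would restore nominal level at
the cost of departing from the emulated pointwise-band protocol.

## Coverage (`coverage`)

Phansalkar threshold on images pre-scaled to [0, 1] (by bit-depth maximum,
not observed range): `t = μ(1 + p·e^{−qμ} + k(s/r − 1))` over a disk
(default radius 40 px; k = 0.25, r = 0.5, p = 2, q = 10 — the published
defaults), reflective border padding. % area counts mask pixels; mean gray
is computed over the whole ROI independent of the mask (the masked variant
is exported alongside). Spot detection is a scale-matched LoG at
σ = diameter/(2√2) with non-maximum suppression at one diameter; quality is
the scale-normalized response rescaled so an ideal matched blob of unit
contrast scores 1000 (an amplitude-A blob scores 1000·A), so the default
cut of 500 keeps half-contrast spots. The original detector's quality units
are proprietary; this scale emulates, not reproduces, them.

## Cohort pipelines and statistics (`pipeline`)

Per-subject values average replicate images and left/right sides before any
group statistics (hemiskull averaging). Two-group comparisons: pooled-
variance Student's t, or two-sided Mann–Whitney U; "auto" uses t only when
both groups pass Shapiro–Wilk at α = 0.05. Bonferroni adjustment across the
metric family (`adjusted_p = min(1, m·p)`). Degenerate zero-variance groups
return (0, p = 1) when equal and (∞, p = 0) when not. Reports are plain
JSON, byte-identical under a fixed seed.

## Verification problem sizes

The acceptance script and test suite use deliberately scaled problem sizes
chosen to keep the full verification run in the tens of minutes on one CPU:
geodesic exactness on 100 random cost images up to 50×50; 20 branching
phantoms at 320×320×6 voxels (3–10 endpoints) clean and at SNR 5; 100–200
envelope replicates at the 3.7 × 2.4 mm² window and 38 cells/mm²; 100
null-calibration and 100 power replicates of the full innervation pipeline
on 8-vs-9-subject cohorts of 144×144×4 phantoms (the planted effect scales
segment lengths 1.5×, i.e. +50% expected total length). Larger images
change runtimes, not the algorithms.

## Known limitations

* The imaging model is idealized (see phantom section); real-data
  performance depends on staining quality and seed placement.
* Endpoint counts on projections conflate 3D overpasses with junctions.
* The pointwise envelope verdict over-rejects CSR (documented above).
* The active-contour family and Frangi parameters are conventions, chosen
  for robustness and reproducibility, not fitted to data.
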