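# Methods

This note records the models, parameter choices and numerical
conventions behind `earcount`, including the places where the design
was genuinely open and what the synthetic validation does and does not
demonstrate.

## Pipeline model and assumptions

The counter assumes a single maize ear photographed side-on against a
uniform backdrop whose colour is separable from plant tissue (blue, or
failing that, dark). Kernels are assumed to be convex, roughly
elliptical, brighter in the centre than at their rims, and arranged so
that each kernel's interior is at least partly visible; kernels fully
occluded on the silhouette edge are out of reach of any single-view
method and are not counted.

The recognition principle: after segmentation the kernel regions form
a binary image in which touching kernels survive as fused blobs.
Smoothing that binary image with a Gaussian whose window matches the
kernel width turns each kernel into an intensity peak; the union of
two touching kernels narrows at the contact (a waist), so a saddle
forms between the two peaks and a block-local maxima scan recovers one
point per kernel. This presupposes *rounded* kernels: numerically, the
union of two near-rectangular shapes pressed edge-to-edge has no waist
and produces a single plateau no matter the window or σ chosen. The
saddle mechanism, not the smoothing bandwidth, is what separates
touching kernels.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `pyramid_level` | 2 | levels | working layer (G2); halves dimensions per level |
| `mean_shift_sp` | 40 | px (original scale) | spatial radius; divided by 2^level on the working layer so the window covers the same physical extent |
| `mean_shift_sr` | 60 | intensity | colour radius (Euclidean in RGB) |
| `mean_shift_max_pyramid_level` | 3 | levels | coarse-to-fine levels, counted from the original scale; the pipeline subtracts the compression level already applied |
| `mean_shift_max_iters` / `eps` | 5 / 1.0 | – / intensity+px | per-pixel termination |
| `background_mode` | auto | – | backdrop statistic; auto reads the border median (blue-dominant → blue mode) |
| `min_area` | 20 | px | small-component removal |
| `canny_low` / `canny_high` | 80 / 176 | intensity | edge-integrity diagnostic hysteresis (176 = 80 × 2.2) |
| `blocksize` | derived | px, odd | adaptive-threshold window = avg kernel MBR length |
| `gaussian_window` / `local_block` | derived | px, odd | smoothing window and maxima block = avg kernel MBR width; σ = N/6 (±3σ spans the window) |
| `merge_radius_factor` | 0.5 | – | merge ellipse semi-axes as a fraction of the MBR sides |
| `fallback_mbr` | (11, 7) | px (working scale) | used when the bootstrap finds < 3 usable components; a typical 44 × 28 px kernel seen at G2 |

## Kernel-size bootstrap

The adaptive-threshold block and the smoothing window derive from the
average kernel minimum bounding rectangle, which is not known before
kernels are segmented. The bootstrap Otsu-thresholds the enhanced grey
inside the fruit, labels 8-connected components, drops those under
20 px and the largest 5 %, and then — because touching kernels fuse
into components whose areas are near-integer multiples of the
single-kernel area — identifies the single-kernel class as components
within 1.6× of the 25th-percentile area and takes the median of that
class's bounding-box sides. A plain mean over all components doubles
the window estimate whenever fusions dominate, which collapses
touching pairs into single recognition points; anchoring on the
smallest consistent class is deliberate, since the recognition windows
must resolve the smallest kernels while oversized windows merge
neighbours. Under a genuine mixture of kernel sizes the estimate
therefore tracks the smaller size class.

## Numerical conventions

- **Pyramid.** 5×5 binomial window (outer product of [1,4,6,4,1]/16);
  replicate-edge padding; ceil-halving for odd dimensions; expansion
  pads the source before zero-interleaving so constants are preserved
  exactly at borders, and accepts an explicit output shape for
  odd-size round trips.
- **Lab encoding.** The a and b rows are evaluated in difference form
  (0.2213(R−G) + 0.1177(B−G), etc.), whose coefficients cancel
  exactly, so every grey input maps to a = b = 128 exactly in floating
  point.
- **Optical density.** OD = −log₂₅₆((v+1)/256) ∈ [0, 1]; the +1 offset
  forestalls log 0. Density maps are displayed as
  256^(1−density) − 1, the exact inverse, clamped to [0, 255]. An
  8-bit display map cannot encode densities outside [0, 1] (e.g.
  negative residual-stain densities), so the deconvolution round trip
  is exact only on the representable gamut; the tests sample from it.
- **Stain basis completion.** A single supplied OD vector is
  normalised and completed with an orthogonal unit vector (component
  rotation + Gram–Schmidt; a fixed fallback axis when the vector has
  equal components) and their cross product, giving an orthonormal C.
  The all-zero "white" vector denotes a pure-brightness absorber
  (1,1,1)/√3 — brightness is the feature that separates a kernel from
  its touching edges. Densities follow the row-vector convention
  R*_row = R′_row C⁻¹, under which a pixel whose OD vector is k times
  stain 1's direction has density k on stain 1 and zero elsewhere.
- **Stain selection centroids.** The shipped Lab centroids are
  synthetic, chosen to partition this package's generated fixtures;
  real deployments should compute centroids from their own reference
  images and supply them as a YAML library.
- **Adaptive threshold.** Strict `value > window mean`; ties go to
  background, so constant regions produce no foreground. Integer
  images compare v·(window count) > window sum in int64, making the
  decision exact and a global +c offset provably unable to flip any
  pixel. With a fruit mask the mean is taken over fruit pixels only
  (normalised masked mean): an unmasked mean near the silhouette is
  dragged down by the dark backdrop and marks the whole fruit boundary
  foreground.
- **Otsu.** Computed on the exact integer histogram (values rounded to
  uint8): generic float binning can return a slightly suboptimal cut
  on integer-valued data, and the contract is the variance-maximising
  threshold.
- **Local maxima.** A pixel qualifies if it is ≥ everything in its
  L×L block, strictly greater than at least one block member, and
  positive. Adjacent qualifying pixels necessarily share a value, so
  connected candidate regions are plateaus; each contributes only the
  member nearest its centroid (ties: first in scan order).
- **Merging and localization.** Points are single-linkage clustered
  inside a merge ellipse with semi-axes 0.5 × MBR-length (rows) and
  0.5 × MBR-width (columns) — an isotropic radius of half the width
  under-merges duplicate maxima strung along an elongated kernel's
  axis — and each surviving point moves to the intensity-weighted
  centroid of its L×L block, which centres it on the kernel with
  sub-pixel precision. Merging repeats until stable, so the result is
  order-independent.
- **Coordinate mapping.** Work-layer point (r, c) maps to the original
  scale as r·2^level + (2^level − 1)/2, the centre of the block each
  reduced pixel summarises.
- **Mean shift.** Box spatial window, Euclidean colour distance,
  coarse-to-fine over the internal pyramid with the coarser result
  seeding the finer level; a seed farther than sr from the pixel's own
  colour restarts from the pixel's colour (a cross-basin seed would
  otherwise capture the wrong pixels). With the production termination
  settings (5 iterations) the filter stops before full convergence, so
  it is *not* idempotent on smoothly shaded regions; idempotence holds
  where colour basins are separated by more than sr, and that is the
  regime the property test checks.

## Synthetic data: what it emulates, what it does not

The generator draws a convex ear silhouette (a p=4 superellipse) on a
blue (40,55,175) or black (14,14,16) backdrop, tiles it with shaded
elliptical kernels — centre colour (230,200,75) shading to a 0.6×
darker rim, sizes 44 × 28 px ± 10 % jitter, cell pitch 1.15× the
kernel — over grooves of deep-shadow colour (70,50,30), and adds
Gaussian pixel noise (σ = 4). Touching pairs are constructed per
topology: edge-to-edge pairs press together by a quarter of their
combined widths, deep enough that the union's waist exceeds a kernel
width and iterative erosion provably cannot split it; corner contacts
overlap 1.5 px. The visible contact renders as a narrow seam of the
groove colour (configurable, e.g. a hue-shifted same-luminance shade
for enhancement experiments). Optional features: a kernel-free bald
tip of pale cob tissue, a linear illumination gradient, or a Gaussian
highlight.

The standard validation suite holds 50 fixtures (seeds 1–50): 20–60
kernels, up to 30 % of kernels in touching pairs spread over the three
topologies, gradient illumination with amplitude 40–60, backgrounds
alternating blue and black.

Deliberately not emulated: photographic texture (pericarp mottling,
specular glints), perspective foreshortening and lens distortion,
silhouette-edge kernels seen at grazing angles, and the partial
occlusions of a real 3-D ear. Passing the synthetic suite therefore
demonstrates that the algorithmic chain — compression, background
separation, enhancement, adaptive segmentation, maxima recognition —
is implemented coherently and separates the stated touching
topologies under uneven illumination; it does not by itself establish
accuracy on field photographs, which depends on acquisition conditions
the generator idealises.

## Evaluation semantics

Detections are matched one-to-one to truth centres greedily in
ascending distance, with matches beyond the radius (default half a
kernel width) rejected; correct rate = 100 × matched / truth, reported
to one decimal. The published-table convention truncates rather than
rounds the final decimal (1500/1531 = 97.97 % prints as 97.9), so
truncation is the default and half-up rounding is available via
`rounding="round"`. Batch summaries average per-image rates rather
than pooling counts.

## Problem sizes

The validation suite runs ears of roughly 250–600 px per side; at the
G2 working layer a default kernel spans about 11 × 7 px, matching the
scale at which the reference parameterisation (sp = 40, blocksize ≈
kernel length) was designed to operate. The acceptance script
processes the 50-fixture suite in well under a minute on one CPU.

## Known limitations

- Kernels occluded at the ear silhouette are not recognised (single
  side-view input).
- Bald-tip tissue is removed only by the colour threshold; residual
  bright cob patches can contribute occasional false positives, as
  the colour statistics of cob and kernel overlap.
- The Hough baseline's accumulator threshold (0.45, normalised) was
  fixed on the fixture suite and is reported in the config for
  reproducibility; it is a comparison baseline, not a tuned
  competitor.
- On ears with genuinely bimodal kernel sizes the MBR bootstrap tracks
  the smaller class; very large kernels may then yield duplicate
  points, controllable via the explicit `blocksize` /
  `gaussian_window` / `local_block` overrides.
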