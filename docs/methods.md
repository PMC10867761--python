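# Methods

## The measurement problem

In the murine oxygen-induced retinopathy (OIR) model, pups exposed to 75%
oxygen from postnatal day P7 to P12 develop central vaso-obliteration (VO)
and, on return to room air, ischemia-driven neovascularization (NV) that
peaks around P17.  The large superficial vessels also become measurably
tortuous, and that tortuosity tracks disease activity and treatment response.
`vasctort` quantifies this from binary vessel-segmentation masks of retinal
flat-mounts: the masks (typically hand-traced large vessels) and the
optic-disc center coordinates are the inputs; the outputs are per-image
tortuosity indices, inter-grader agreement, NV/VO area fractions, and group
statistics.

## Pipeline

1. **Load** — any nonzero pixel is vessel (manual segmentations are binary
   by construction).  All coordinates are 0-based `(row, col)`, row 0 at the
   image top; sidecar files in `(x, y)` order are declared with `--xy-order`
   and swapped on load, so no module downstream ever handles x/y.
2. **Skeletonize** — topology-preserving morphological thinning
   (Zhang–Suen-style, via `skimage.morphology.skeletonize`).  Thinning is
   idempotent and preserves 8-connectivity components.
3. **Vessel graph** — every skeleton pixel is a node, every 8-adjacency an
   edge.  Degree classes: endpoint (1), slab (2), branch (≥ 3), isolated (0).
4. **Disc exclusion** — nodes within `disc_radius_px` (default 50 px) of the
   optic-disc center are removed before segment extraction.  The confluence
   hub at the disc is a dense tangle of crossings where junction geometry is
   degenerate; how exactly the disc center should enter the computation is
   an open design point, and exclusion by a configurable radius (0 disables)
   is the declared choice here.
5. **Segments** — terminal spurs shorter than `spur_length_px` (default
   10 px; thinning artifacts at vessel margins) are pruned iteratively to a
   fixpoint; junction pixels whose neighbors are already mutually connected
   are dissolved (they carry no topology); adjacent branch pixels are merged
   into single junction clusters.  Each maximal slab chain between
   endpoint/junction terminals becomes one segment; chains shorter than
   `min_length_px` (default 20 px) are discarded.  Chains are oriented
   proximal-to-distal relative to the disc and traced in fixed row-major
   neighbor order, so extraction is fully deterministic.
6. **Metrics** — each chain is smoothed and resampled (below), then:
   - **CTI** (cumulative tortuosity index): arc length / chord length of the
     resampled polyline.  Scale-invariant; exactly 1 for a straight vessel.
   - **IC** (integrated curvature): Σ|θᵢ| over the interior turning angles,
     in radians — the discrete integral of curvature along the segment.
   - **OC** (overall curvature): mean |θᵢ|, radians.

   Image-level values are unweighted means over segments
   (`aggregate="length_weighted"` is available).  Segments whose chord is
   shorter than the sampling spacing (closed loops) are flagged, logged and
   excluded from image means.

### Why CTI is the arc-to-chord ratio

The index is described in the source literature as a cumulative sum of
angles normalized by vessel length.  Taken literally, that quantity is 0 for
a straight vessel and depends on the pixel scale, which is incompatible with
the reported normoxic baseline of ≈ 1.04 on a scale where straight vessels
sit at 1.  The arc-to-chord ratio has exactly those properties (baseline 1,
dimensionless, scale-free) and reproduces the observed 1.04–1.14 range, so
it is the default.  The literal angle-sum variant, `1 + Σ|θ|/L_arc`
(units rad/px), remains available as `cti_formula = "angle_sum"` for
sensitivity analysis; the ambiguity is documented rather than resolved.

### Smoothing and resampling

8-connected skeleton chains quantize direction to multiples of π/4, so raw
turning angles are dominated by staircase noise.  Each chain is therefore
smoothed by a centered Savitzky–Golay filter — a local quadratic fit of the
positions, `smoothing_window` = 21 chain pixels by default — and then
resampled at equal arc-length spacing (`spacing_px` = 5 by default; the last
step carries the remainder).  A local quadratic is used instead of a flat
moving average because it is unbiased for curvature up to second order: it
suppresses pixel jitter without flattening genuine bends, which a flat
average of the same width would.  The window (≈ 4× the typical stroke
width, ≈ λ/5 of the curvature scales of interest) was chosen on phantoms as
the best trade-off between staircase suppression and curvature attenuation.
The resampled polyline ends at the smoothed chain ends rather than the raw
pixel endpoints: pinning the raw endpoints would introduce an artificial
kink whose spurious turning angles (up to ~0.3 rad on perfectly straight
vessels) contaminate IC and OC.

Accuracy at these defaults, measured on rasterized analytic curves (stroke
width 5): CTI of a semicircle of radius 100 px within 0.8% of π/2; CTI of
sinusoids within 0.7% of the quadrature arc/chord through amplitude 40 px;
IC within ~0.5% of the total-absolute-curvature quadrature oracle.

## Dice agreement

`dice_coefficient` is 2|A∩B|/(|A|+|B|) over pixels; `pairwise_dice` emits
one value per unordered grader pair (k graders → k(k−1)/2 pairs).  Two empty
masks return 1.0 — vacuous agreement — with a warning, since an all-empty
pair almost always indicates an input error.

## NV / VO ratios

The NV/VO segmentations themselves come from an upstream (external)
segmenter; this package only converts masks to area fractions and records
expert overrides.  The denominator defaults to the whole image — for
flat-mount leaflets cropped to the retina this is the operative region —
and an optional retina-region mask refines it.  Overrides (e.g. zeroing a
spurious VO call caused by light pigmentation in a normoxic retina) replace
the value but retain the original, the reason, and a flag in provenance.

## Statistics

Two groups: classical two-tailed unpaired Student t test with pooled
variance (Welch optional).  Three or more: one-way ANOVA.  No
multiple-testing correction is applied.  Stars use strict inequalities:
`****` p < 1e−4, `***` p < 1e−3, `**` p < 0.01, `*` p < 0.05, else `ns`
(p = 0.05 is `ns`).  Groups need n ≥ 2 to be tested; singleton groups are
summarized with SD reported as 0 and flagged.

## Synthetic phantoms

`generate_retina` builds flat-mount-like masks with known ground truth:
`n_vessels` (default 8) radial centerlines from the disc, each perturbed
perpendicular to its ray by `a·sin(2πt/λ + φ)` with per-vessel random phase,
rasterized by stamping a disc of half the stroke width (default 5 px) at 4
samples per pixel of arc.  The true arc length of each centerline is
computed by adaptive quadrature of `√(1 + (a k cos(kt+φ))²)` *before*
rasterization, so every vessel carries an exact arc/chord ratio; amplitude
is the single tortuosity dial, mirroring how disease shifts a scalar index.
A sinusoid is used rather than a random walk precisely so this closed
quadrature form exists.

Default geometry (1024² image): vessels run from radius 130 px to 460 px.
The start radius keeps adjacent vessels disjoint up to amplitude 40 px
(`2 r sin(π/8) > 2a + stroke`); overlapping lobes would fuse into spurious
junctions and corrupt the ground truth.  Configurations whose vessels would
leave the canvas are rejected.  All randomness flows from one integer seed;
a fixed seed reproduces masks bit for bit.  Optional straight branches
(`branch_prob`) exercise junction handling, with ratio exactly 1 recorded
for each branch.

What the phantoms do *not* emulate: capillary background, neovascular
tufts, VO zones, uneven illumination, grader disagreement about which
vessels are "large", and vessel-width variation.  Passing tests on phantoms
therefore validate the geometry pipeline (skeleton → graph → segments →
metrics) and the statistical machinery, not robustness to real segmentation
noise.

## Known limitations

- **IC/OC noise floor.**  IC sums ~60+ turning angles per segment; each
  carries irreducible quantization noise (~0.01 rad after smoothing — the
  staircase period of near-axis-aligned chains exceeds any fixed window).
  A perfectly straight rasterized vessel therefore reads IC ≈ 0.5–1.2 rad
  rather than 0, and IC/OC move by up to ~1% under rigid motion of the
  input, where CTI moves < 0.1%.  A hard noise floor on angles was tested
  and rejected: zeroing angles small enough to matter biases IC on genuinely
  curved vessels by 6–13% and worsens rigid-motion stability.  CTI, the
  primary index, is unaffected; treat absolute IC/OC values as
  estimator-dependent and compare them only within a fixed configuration.
- **Segment ends.**  Skeleton endpoints wobble ±1–2 px between
  rasterizations of the same geometry; IC is extensive in sampled arc, so
  this contributes directly to its variance.
- Every tunable (spacing, window, spur/min lengths, disc radius, formula
  and aggregation variants) is part of `RunConfig` and hashed into every
  output row, so results are attributable to an exact configuration.
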