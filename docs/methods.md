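# Methods

This note records the modelling choices, parameter semantics and numerical
conventions behind `filascan`, and what the synthetic-scene tests do and do
not demonstrate about real micrographs.

## Imaging model and coordinate conventions

Images are 8-bit monochrome bright-field frames from a submersible in-situ
microscope: nominal 1392 × 1040 px sensor, 6.45 µm pixel pitch, ×40
magnification (tube length 160 mm, so the nominal magnification applies).
Intensities are normalised to [0, 1] at load time; all variance thresholds
are expressed on this unit scale, where they fall in the 10⁻⁴–10⁻³ range.
Pixels are addressed row-major, 0-based, with pixel centers at integer
coordinates; every distance computation shares this convention.

A `GrayImage` carries a `downsample_factor` recording how far its grid is
from the native sensor grid. The pipeline resizes an image only by the
ratio between the configured factor (default 2) and the image's current
factor. Synthetic scenes are generated directly at the post-resize
geometry (520 × 696, factor 2) because all pixel-unit parameters of the
method — filament widths 2.5–5 px, lengths 31–620 px, the 77-px area rule —
are defined in that frame; such scenes pass through the pipeline without
being resized a second time.

## Pipeline stages

**Resize.** Bicubic interpolation with anti-aliasing, integer factor;
halving is exact for even dimensions. The anti-aliased bicubic kernel also
acts as a mild low-pass filter, removing single-pixel noise.

**Gamma.** g = f^0.6 expands the dark end of the range where in-focus
objects live.

**Contrast enhancement.** Two stages: (i) high-boost sharpening, image
plus `boost` (default 1.0) times its high-pass residual, with the residual
defined as image minus its 3 × 3 mean — the kernel is our choice, the
operation itself being standard unsharp masking; (ii) add the grayscale
top-hat and subtract the bottom-hat, both over a diamond structuring
element of radius 3, which sharpens bright peaks and dark valleys
symmetrically. The result is clipped to [0, 1] after both stages; range
handling here is a design choice, as is reflect padding for every local
filter.

**Variance transform.** Population variance (n normalisation) of the
3 × 3 neighbourhood, computed as E[x²] − E[x]² with uniform filters. A
`sample_variance` switch selects the n−1 estimator for sensitivity
analysis. Thresholding is inclusive (≥). The default threshold
10.5 × 10⁻⁴ together with distance 6.4 and RRG 3.2 is the ROC-optimal
triple used as the package default.

**Size filter and hole filling.** 8-connected components below 77 px are
removed (smallest expected filament: ~2.5 px wide × ~31 px long ≈ 77.5 px).
Holes are 4-connected background components not touching the border; a
hole is filled iff its equivalent-area diameter 2√(area/π) is below
2.5 px, so enclosed loops formed by curved filaments stay open. Hole
"diameter" as equivalent-area diameter is our reading; only the 2.5-px
figure is fixed by the size derivation.

**Floc removal.** Exact Euclidean distance transform; pixels at distance
≥ 6.4 px from background form eroded floc cores; dilation restores their
extent. The dilation radius defaults to the distance threshold — the
erosion depth equals the threshold, so an equal-radius disc dilation is
the natural reconstruction — and both are configurable. Real-valued radii
are honoured exactly by dilating via EDT thresholding of the complement
rather than a rasterized integer footprint.

**Skeletonization and spine pruning.** Topology-preserving thinning
(scikit-image), one skeleton per 8-connected object, processed inside its
bounding frame. Endpoints are skeleton pixels with exactly one
8-neighbour. To bound cost, only the four endpoints nearest the four
frame borders are endpoint candidates (ties to the smaller row-major
index); this can in principle miss the true diameter on pathological
shapes, and the exhaustive search exists in the test suite as an oracle
only. Geodesic distances use the quasi-euclidean metric (1 axial, √2
diagonal) via Dijkstra restricted to skeleton pixels. The spine is
recovered from the sum of the geodesic maps from both strongest ends:
pixels within ε of the minimum belong to the spine, with
ε = 10⁻⁶ × frame diagonal absorbing floating-point drift; the path is
ordered by distance from the first end. Closed skeletons without
endpoints (loops) are kept whole as a single spine whose length is the
cycle perimeter — loop handling is not otherwise specified by the method
and this choice preserves total length. Residual branches with geodesic
extent > 31 px (`min_filament_len_px`) are reprocessed recursively.

**RRG filter and lengths.** The reduced radius of gyration is computed on
the pruned spine pixel set (not the filled object), with population
second moments; spines with RRG ≥ 3.2 become filament records. Lengths
convert as geodesic px × downsample_factor × pitch / magnification
(0.3225 µm/px at defaults). Per-image TEFL is the sum of lengths; the
batch statistic ISM-oTEFL is the mean of per-image TEFLs.

## Evaluation machinery

Reference masks are combined by consensus: a pixel is ground truth iff
marked by ≥ 3 of the annotators. Matching tolerates small displacement:
TP/FN partition the reference against the disc-dilated detection, FP
compares the detection against the dilated reference. The dilation radius
(default 3 px) is our choice; the methodology fixes only that a dilation
is used. Both TPR and FPR are normalised by the positives P — FPR = FP/P
deliberately, because negatives are dominated by background and flocs and
an FP/N rate would overstate specificity; FPR can therefore exceed 1, and
specificity = 1 − FPR. Grid evaluation nests variance → distance → RRG so
that expensive stages are reused (the RRG threshold only re-filters
already-extracted spines); counts are pooled over images before computing
pooled rates, and per-image rates are retained for dispersion analysis.
The convex hull in (FPR, TPR) space first removes dominated points, then
keeps the concave upper envelope including collinear frontier points.

## Synthetic scenes

The generator emulates the post-resize imaging geometry with exact ground
truth. Choices, made once as the study conditions:

- **Background** 0.6 (mid-grey), **filament contrast** −0.35 (in-focus
  objects are dark; off-focus away from the objective renders bright).
- **Noise** σ = 0.004 ≈ 1 grey level of an 8-bit sensor. The fixed
  variance threshold that defines the virtual sample volume presupposes a
  background whose post-enhancement local variance stays below it; ~1 LSB
  of sensor noise is the regime consistent with a fixed 10.5 × 10⁻⁴
  operating point and with a well-exposed pulsed bright-field camera.
- **Filament geometry**: integrated bounded-curvature headings
  (σ ≈ 0.015 rad/px, AR(1)-smoothed), matching mostly elongated organisms
  with few directional changes; widths uniform in 2.5–5 px, lengths in
  31–620 px. Centrelines are rasterized as Bresenham chains between
  anchors ~2 px apart, so the stored ground-truth geodesic length is that
  of a minimal 8-connected chain rather than an inflated per-sample
  rounding. Tubes are rendered with anti-aliased coverage from the
  continuous distance to the centreline.
- **Flocs**: irregular blobs (radius 15–60 px, low-order radial
  perturbations) with grainy interior texture (σ ≈ 0.08, correlation
  ~0.7 px) so their interiors — like real aggregates — carry local
  variance and binarize as solid objects.
- **Out-of-focus objects**: curvilinear tubes blurred with σ ≥ 5 px,
  contrast attenuated to 25 % and rendered bright; they are excluded from
  the ground-truth filament mask and must be rejected by the variance
  threshold.
- **Debris**: 1–2.5 px specks removed by the 77-px size filter.
- The five-scene battery (isolated / crossing / touching flocs / dense
  flocs / mixed focus) covers the difficult configurations; the isolated
  scene additionally enforces a 12-px separation margin **including
  self-separation**, because the length-recovery check is only meaningful
  for filaments that do not cross anything, themselves included.

What the scenes do **not** model: realistic point-spread functions,
illumination gradients, motion blur, partial-focus gradients along one
filament, and densely overlapping filament networks. Passing the
synthetic battery therefore demonstrates the correctness of the
algorithmic chain and its parameter semantics, not field performance on
plant data; the detection rates measured on real expert-annotated
micrographs in routine operation can be substantially lower (crossing
and floc-touching scenes in the battery already show the expected drops).

## Problem sizes and determinism

Oracle-equivalence checks run the geodesic machinery against an
independent Dijkstra on 200 random skeletons of ≤ 60 px and the distance
transform against brute-force search on random masks up to 32 × 32 — sizes
at which the oracles are exact and exhaustive. Scenario metrics use the
full 520 × 696 battery; ROC-grid demonstrations use a 3 × 2 × 3 grid on a
reduced 220 × 300 scene, which exercises every code path of the sweep.
All randomness flows from explicit integer seeds; identical seeds produce
bit-identical scenes and results.

## Known limitations

- Short filaments crossing other objects can fall below the RRG cut after
  pruning and be discarded; closely spaced filaments may binarize as one
  object and be removed with the flocs. Both behaviours are inherent to
  the method's thickness/elongation logic.
- The four-candidate endpoint preselection can truncate the spine on
  shapes whose true geodesic diameter does not involve a border-nearest
  endpoint.
- FPR = FP/P is not a probability; comparisons with conventional ROC
  analyses must account for the denominator.
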