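# Methods

This note documents the models, algorithms and numerical choices behind
`organocyte`, the assumptions they rest on, and what the synthetic
benchmark does and does not demonstrate.

## Imaging model and working image

Inputs are 8- or 16-bit brightfield frames (TIFF/PNG/JPEG), single-channel
or RGB.  RGB is reduced with ITU-R 601 luma weights (0.299, 0.587, 0.114).
Images carry no trusted physical calibration; μm-per-pixel comes from the
configuration (default 1 μm/px per axis; the synthetic scenes use 2 μm/px).
Frames from instruments that export a different grid can be resampled to an
analysis grid (default 2,560 × 2,000 px) by bilinear interpolation; the
calibration is rescaled per axis, so physical sizes are preserved and the
two axes may end up anisotropic — all downstream geometry uses per-axis
μm/px throughout.

The working image is the grayscale frame minus a windowed-median background
model, clipped at zero.  The median window is square, side `2r+1` with
reflective borders, default r = 25 px: larger than the membrane half-width
(so ridges survive), smaller than a typical organoid diameter.  Clipping
(rather than re-centering) of negative residuals discards dark objects;
membranes are bright, so nothing of interest is lost.  For integer-valued
images the median is computed with a sliding-histogram rank filter on a
reflect-padded copy, which is exactly equal to the direct windowed median;
float images take the direct path.

## Membrane detection

A pixel is membrane if, along at least one of four scan orientations
(0°, 45°, 90°, 135°), it lies inside a 1-D intensity excursion that rises
by ≥ `min_prominence` (default 20 on the 8-bit scale) above the flanking
minima on both sides within ≤ `max_width_px` (default 9) samples.  Peaks
are found per scan line with a prominence window of `2·max_width+1`
samples, and the excursion is marked from the left to the right flanking
minimum, shoulders included, so the mask is contiguous across the ridge.
Four orientations suffice for closed curves: every closed outline crosses
at least one orientation transversally.  A plateau wider than the window
has zero within-window prominence and is correctly not marked.  The mask,
scaled by `boost` (default 60), is added onto the working image to sharpen
contours before classification.

## Pixel classification

A random forest (100 trees, depth unlimited, `min_samples_leaf=2`, fixed
seed) maps 14 per-pixel features to two classes: *organoid contour*
(membrane) vs *tissue* (immune cells, lumen, plain background, debris).
Features: raw intensity; Gaussian smoothings σ = 1, 2, 4, 8 px; median
filters r = 2, 4 px; gradient magnitude σ = 1, 2 px; Laplacian-of-Gaussian
σ = 2 px; local variance and local entropy in 7×7 windows; and
co-occurrence contrast and homogeneity computed in sliding 15×15 windows
on a 16-level quantized image.  The co-occurrence statistics use the
sliding-window identity contrast = mean(d²), homogeneity = mean(1/(1+d))
over the per-offset quantized level differences d (offsets right and
down), which makes them computable with box filters at full resolution.

Training pools the labeled pixels of any number of annotated images
(0 = unlabeled, 1 = contour, 2 = tissue); unlabeled pixels are ignored and
re-training means calling again with the enlarged pool.  Dense annotations
are subsampled to at most 20,000 pixels per class (seeded) — beyond that
the forest's accuracy saturates while fitting time grows linearly.  Models
persist as a single file: a JSON header line (feature names, class names,
seed, format version) followed by the pickled estimator; save→load
reproduces predictions exactly.

Thresholding at `prob_threshold` (default 0.5) yields a contour mask and a
disjoint tissue mask.  Contour components smaller than 20 μm² are
discarded (they are classifier speckle, not membrane).

## From masks to organoids

**Background vs inner areas.** The tissue mask contains both the vast
connected culture background and the small enclosed objects that are
candidate organoid inner areas; they are separated by size: tissue
components larger than the seed-area gate maximum (default 500,000 μm²)
are background, the rest stay candidates.  Seed candidates are then the
8-connected components of "neither contour nor background" within the area
gate (default 200–500,000 μm²); components touching the frame are kept but
flagged.

**Bridging membrane breaks.** Disrupted outlines would let an inner area
leak into the background through the break, so solid organoid footprints
are reconstructed before seeding: each 8-connected contour component is
dilated by `contour_close_radius_px` (default 5 px), hole-filled, and
eroded by the same radius.  This seals breaks up to roughly twice the
radius — matched to the break scale the pipeline is designed to tolerate —
while the per-component treatment guarantees that interstitial pockets
bounded by *several* distinct outlines are never sealed into phantom inner
areas.  Two cheaper alternatives fail: plain morphological closing of the
thin contour re-opens the bridge during its erosion half, and global (not
per-component) bridging seals inter-organoid pockets and produces false
positives.  The background size criterion runs on the tissue field outside
these footprints, so a sealed inner area is not dragged into the
background component through its former break.

**Seed validation.** ring_support = fraction of a seed's outer boundary
(8-neighborhood) whose Euclidean distance to the nearest contour pixel is
≤ `ring_probe_px` (default 3 px); seeds need support ≥ 0.6 and a mean
working-image intensity inside the (by default permissive) intensity gate.
Boundary pixels clipped by the image frame count as unsupported, which
prevents frame-bounded background regions from masquerading as enclosed
seeds.  Each surviving seed is smoothed by morphological closing then
opening (disk r = 2 px, largest component kept) and must have circularity
within the compactness gate (default 0.3–1.0): true lumens are round,
clutter gaps are not.

**Growing.** The growing mask is seeds ∪ contours ∪ the bridged-footprint
interiors that contain a seed.  Each seed expands by geodesic dilation
inside this mask and claims the pixels geodesically nearest to it (exact
ties to the lower seed id), subject to two physical limits read from the
interactive tool this pipeline automates: expansion stops at geodesic
distance `organoid_grow_radius` (default 90 μm) from the seed boundary and
at `seed_grow_radius` (default 280 μm) from the seed centroid, and in any
case at the contour outer edge (beyond it there is no mask).  Distances
are computed exactly with multi-source Dijkstra on the masked pixel graph
(8-connectivity; edge weights in μm, anisotropy-aware; per-seed source
supernodes carry a 10⁻⁹ μm pseudo-weight because the sparse graph codec
drops explicit zeros).  Seed pixels always keep their own label, so with
both radii zero each organoid equals its seed exactly.  Enclosed holes are
filled per label and labels renumbered 1..N in seed order.

**Rescue.** Contour components untouched by any label, enclosing at least
one interior pixel, with hole-filled area in [20, 2,000] μm², are added as
small organoids — outlines whose inner area was too small to seed.  The
enclosure requirement distinguishes a small ring from a solid blob of
classifier noise; without it, cluttered scenes systematically gain false
positives.

## Quantification

Per organoid: area (pixel count × pixel area), perimeter, compactness,
centroid (μm), size class, border flag.  Compactness is the isoperimetric
circularity 4πA/P² clipped to [0, 1].  The perimeter P is the length of
the 0.5-level marching-squares contour of the region after smoothing the
traced boundary coordinates with a Gaussian of σ = 2 samples (circular for
closed curves).  The smoothing removes rasterization staircase bias:
against closed forms, a raw pixel-edge perimeter puts a digital disk at
circularity 0.91 and the raw marching-squares length at 0.90, while the
four-direction Crofton estimator puts a square at 0.88 (true π/4 ≈ 0.785);
the smoothed-boundary estimator scores disk 0.999, square 0.806, 100×2
rectangle 0.064, and is stable under rotation.  Size classes are
lower-inclusive bins with default edges 18,000 / 60,000 / 120,000 μm².
Well summaries group records by plate/well/stimulation/time point: total
count, per-class counts, median area, mean compactness.  Statistical
hypothesis testing is deliberately out of scope — the exported CSV/XLSX
tables feed external statistics tools.

## Evaluation

Detections and truth objects are matched one-to-one by greedy descending
IoU above `iou_min` (default 0.3; organoid boundaries are fuzzy and
object identity matters more than pixel-perfect overlap), ties broken by
(pred id, truth id).  On geometric instances (compact objects, sparse
overlaps) greedy matching equals exhaustive optimal matching; the test
suite verifies this on randomized instances of up to six objects.
Precision = TP/(TP+FP), recall = TP/(TP+FN); a zero denominator yields 0
with an explicit degenerate flag.  Area fidelity is ordinary least squares
of detected on true area.

## Synthetic scenes

The generator emulates the imaging regime the pipeline targets, with exact
ground truth (areas are pixel counts, never estimates; rendering is a pure
function of the scene spec, seed included).  Default photometry (8-bit):
background 60, lumen +12, a 2 px darker ring (−12) inside a 3 px bright
membrane band (+90); organoid radii uniform in 24–90 μm; immune cells are
1–3 px dark bodies (−18) with 1 px bright halos (+45), partly aggregated
into Gaussian clusters (σ = 12 px) sized to overlap the organoid range
(contour mimicry); fused pairs share a tangent boundary; disruption erases
a membrane arc of 4–10 px; a planar illumination gradient (±16), Gaussian
blur (σ = 1 px) and additive noise (σ = 3) finish the frame.  These
contrasts were chosen once as representative of focus-merged brightfield
acquisitions — membranes well above the noise floor, single immune cells at
the detection margin — and are exposed, not hard-coded.

Complexity presets (512×512 px at 2 μm/px, counts scaled so a desk-scale
scene carries 10–30 organoids): level 1 = 12 organoids, 20 cells/mm²,
1 cluster, no fusion/disruption; level 2 = 18, 60 cells/mm², 3 clusters,
fusion 0.15, disruption 0.08; level 3 = 24, 120 cells/mm², 5 clusters,
fusion 0.25, disruption 0.15.  Time-lapse rendering fixes the layout and
grows radii linearly (μm/day), with frames every `interval` hours
(6 days × 8 h → 19 frames).

What the generator does **not** emulate: depth-of-focus variation inside
the Matrigel dome, organoid interior texture and debris, membrane
intensity variation along the outline, and annotation noise (training
labels derive from exact truth).  Passing the synthetic benchmark
therefore shows that the pipeline's logic is sound under the stated
artifact model — mimicry, fusing, disruption, illumination, noise — not
that these precision/recall levels transfer verbatim to any particular
microscope or culture.

## Benchmark protocol and problem sizes

The surrogate benchmark (`scripts/acceptance.py`, mirrored in the test
suite) trains the classifier on six scenes of cycling complexity
(seeds 1–6), then scores the full pipeline on twenty unseen scenes per
preset (seeds 101–120, 201–220, 301–320), pooling object-level TP/FP/FN at
IoU ≥ 0.3.  Scene size 512×512 px at 2 μm/px keeps the whole benchmark at
a few minutes on one CPU while every organoid still spans 24–90 px in
diameter — comfortably above all structural scales of the pipeline.  The
`--seed` argument drives the training randomness; scene seeds are part of
the protocol.

## Known limitations

- Per-frame detection only: no tracking of organoid identity across
  time-lapse frames.
- 2D only: the Matrigel dome is treated as its projected appearance;
  inputs are assumed focus-merged.
- Organoids whose membrane break exceeds ~2× the bridge radius are lost;
  raising the radius trades against sealing narrow true gaps between
  adjacent organoids.
- The interactive tool's exact growing semantics and compactness formula
  are unpublished; the two grow radii are implemented under one
  self-consistent reading (centroid-limit + boundary-limit) and the
  compactness tolerance bands absorb estimator differences.
- The reported organoid area includes the membrane ring.
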