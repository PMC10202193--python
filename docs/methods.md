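# Methods

This note records the models, parameter choices and numerical decisions
behind `stereofood`, and what the synthetic evaluation does and does not
demonstrate.

## Problem model and assumptions

Two photographs of a dish are taken with the same calibrated camera
(intrinsics K known), roughly 40–50 cm from the food at about 45° from
the vertical, the second shifted a few centimetres to the right. A
reference card of known physical size (8.5 × 5.5 cm) lies flat on the
table next to the dish; the dish is shallow, so the food's visible
surface determines its volume once the table plane is known. Lens
distortion is assumed corrected (or negligible); both captures share K.

Coordinates: pixels are 0-based, x right / y down, sampled at pixel
centers; "600×800" means 600 rows × 800 columns. A world point X in
camera-1 coordinates maps to camera 2 as x₂ = R x₁ + t; t is kept at
unit norm until the card fixes the metric scale (cm per reconstruction
unit).

## Sparse geometry

**Features.** Two interchangeable 256-bit binary descriptor backends:
single-scale FAST corners with parabolic sub-pixel refinement + BRIEF
(default for the stereo pair — the two views differ by an almost pure
translation, and single-scale detection localizes to ~0.2 px), and ORB
(default for card detection, where scale invariance matters). Matching
is exhaustive Hamming with a mutual cross-check. The relevance gate
counts matches below 64 of 256 bits: genuine correspondences sit near
5–30 bits, chance mutual nearest neighbors near the random level of 128,
so counting raw pairs would let any two busy images pass.

**Robust inliers.** RANSAC homography with symmetric transfer error,
threshold 0.6 % of the largest image dimension (4.8 px at 600×800),
confidence 0.99, iteration cap 5000, seeded. A fundamental-matrix model
(Sampson distance, same threshold) is available for strongly non-planar
scenes via `inlier_model="fundamental"`.

**Fundamental matrix.** A tabletop scene is dominated by one plane, which
makes the unstructured 8-point estimate near-degenerate: every F in the
pencil [e]×H fits the planar points. The pipeline therefore uses
plane + parallax: with the dominant-plane homography H (refit tightly at
2 px), each off-plane correspondence contributes a residual segment from
Hx₁ to x₂ that lies on an epipolar line; the epipole is the
maximum-likelihood meeting point of those segments (the residual is the
pixel deviation of x₂ from the ray cast from Hx₁ toward the epipole —
well-behaved even for an epipole at infinity, where the algebraic
line-based objective is attracted to finite points inside the segment
cluster). Then F = [e]×H. The normalized 8-point method (Hartley
normalization, rank-2 enforcement, unit Frobenius norm) is the fallback
and the reference implementation for non-planar data.

**Optimal correction.** Hartley–Sturm: per correspondence, the pencil of
epipolar line pairs is parametrized by one scalar, the 6th-degree
polynomial of the stationarity condition is solved, the minimizing root
(including the t→∞ asymptote) selected, and both points projected onto
their lines. Corrected pairs satisfy |x₂ᵀFx₁| < 1e−9; points coinciding
with an epipole are flagged and passed through.

**Pose.** For the plane-dominated default path, the tight homography is
decomposed (Faugeras–Lustman SVD) into (R, t, n) candidates; candidates
are scored by the median Sampson distance of the off-plane matches and
the survivors disambiguated by the cheirality check (most triangulated
points in front of both cameras). On rendered scenes this recovers R to
≲0.1° and the translation direction to ≲0.7°, an order of magnitude
better than essential-matrix decomposition from the same data — the
small baseline and shallow relief leave the translation direction of an
eight-point/essential estimate uncertain by several degrees (the
bas-relief ambiguity). Essential-matrix pose with cheirality remains the
fallback and the general-scene path.

## Metric scale

The card is found geometrically: its print is a dense black/white
mixture, segmented by thresholds (luma < 50, or luma > 140 with chroma
< 30) plus the requirement that the mixture fills most of the candidate
region (which rejects a bright dish rim closed into a disk); the border
is line-fit to sub-pixel and corners are line intersections; the
180° ambiguity is resolved by correlating the perspectively unwarped
card with the template. Direct descriptor matching from the
fronto-parallel template to the ~120×50 px foreshortened appearance
proved unreliable (the pattern is locally self-similar), so
feature-based refinement runs in the unwarped card frame and is adopted
only with ≥ 12 RANSAC inliers. Corner accuracy on renders: ≤ 0.5 px.

d_est is the mean of the two reconstructed long edges (the diagonal is
available via `card_edge="diagonal"`); scale = 8.5 cm / d_est. On
renders the scale matches the true baseline to ~0.5 %.

## Dense stereo

Calibrated (Fusiello-style) rectification aligns epipolar lines with
rows (≤ 0.3 px row misalignment on renders). Matching cost is the
Hamming distance between 5×5 census transforms, aggregated semi-globally
over 4 scanline paths (8 optional) with P1 = bits/3, P2 = 1.5·bits on
the census-cost scale; winner-take-all with parabolic sub-pixel, then
per-pixel 1-D photometric (Lucas–Kanade) refinement against the right
image, which removes the pixel-locking bias of discrete matching on
slanted surfaces (table-plane accuracy ~0.25 px median).

Validity: the left-right check compares against a right-reference
disparity obtained by *independently aggregating* the shared cost volume
from the right image's perspective — reading the right map off the
left-aggregated volume would make edge fattening self-consistent and
undetectable.

The WLS filter is a fast global smoother (three alternating 1-D
horizontal/vertical solves with the 4^t regularization schedule),
guided jointly by the rectified image (σ ≈ 16·1.5 gray levels) and by
the disparity map itself (σ_d = 0.7 px) so that genuine depth steps stop
propagation while sub-pixel noise does not. λ defaults to 300 on this
normalization: larger values visibly flatten the few-pixel disparity
relief of the food. In the pipeline, measured pixels keep their refined
values; the smoother's role is hole filling, and half-occlusion fills
dragged more than 0.5 px from the background prior are clamped back —
otherwise they form a skirt of phantom above-plane points along depth
edges.

Reprojection: Z = f·B/d in reconstruction units, × scale into cm;
points outside a 20–100 cm depth gate are dropped (the capture protocol
keeps the dish a few tens of cm away).

## Volume extraction

The table plane is the seeded-RANSAC plane with the largest support
(threshold 0.4 cm), least-squares refined and oriented toward the
camera. Food = points more than 0.3 cm above it (removes table, card and
the shallow dish rim). The convex hull is an extreme-point statistic, so
the pipeline inserts robustness stages between extraction and hulling,
each addressing a failure mode observed on renders:

- **cluster selection** (0.4 cm occupancy grid, ≥ 2 points per cell,
  component containing the 95th-percentile-height points, trimmed to
  1.5 cm around the tall core) — scattered table noise otherwise
  connects into the hull;
- **local plane refit** on the table ring around the dish (adopted only
  if it swings the normal < 2°) — cancels low-frequency reconstruction
  warp from residual pose error;
- **median rasterization** (0.3 cm cells, ≥ 3 points, cells with height
  spread > 1 cm dropped — they are vertical walls, which the hull covers
  anyway, or matching spray around them);
- **tall-component and despeckle filters** on the raster — matting
  artifacts form low disconnected arcs around the silhouette; isolated
  cells more than 0.5 cm above all neighbors are spikes.

The volume is the hull of the surviving surface samples together with
their orthogonal projections onto the plane (closing the unseen base);
weight and macros follow linearly from the composition record. A
Delaunay surface mesh over the food points is available for export and
inspection.

The median rasterization slightly shaves the upper envelope of curved
surfaces and the extraction floor removes the lowest 3 mm of relief, so
the pipeline carries a mild negative bias for domes (−5…−15 % per scene)
and a mild positive one for box-like foods (+5…+20 %, edge fattening);
both are within the advertised overall error.

## Synthetic scenes

The generator ray-casts analytic primitives: a table plane at z = 0 with
multi-octave value-noise texture (finest octave ~2 px at the working
resolution — dense matching needs signal everywhere), the printed card
(texture prefiltered to the expected minification, or its sampling
aliases), a 0.2 cm dish rim, and hemisphere / spherical-cap / box foods
with procedural texture, under one directional Lambertian light. Two
pinhole cameras follow the capture protocol: distance 40–50 cm,
elevation 45 ± 5°, baseline 3.5–4.5 cm, ±0.3° hand-held orientation
jitter on the second view. Everything is deterministic per (spec, seed)
and the truth carries the metric pose, card corners, analytic volume and
a world→pixel correspondence oracle.

The suite protocol mirrors the five-estimates-per-dish evaluation: each
dish is rendered under five perturbed capture poses (±2 cm distance,
±2° elevation, ±4° azimuth, ±0.4 cm baseline), the per-dish MAPE is the
mean absolute relative volume error of the five, and the overall figure
is the mean over dishes. With 20 dishes this takes ~10 min on one CPU;
the problem size is set by that protocol, not by the generator's limits.

What the renders do **not** emulate: sensor noise, motion blur, specular
highlights, shadows, lens distortion, non-convex or multi-component
foods, dish occlusion of food, real food texture statistics. Passing the
synthetic suite therefore demonstrates the geometric pipeline under the
stated capture protocol, not photographic robustness; CLAHE
preprocessing exists for real captures and is bypassed when evaluating
renders (they are already contrast-normalized, and enhancement only
amplifies their procedural texture).

## Degenerate inputs and tie-breaks

Collinear point sets, < 8 pairs for F, < 4 for a homography, < 3 for a
plane, all-coplanar food, zero baselines and epipole-coincident points
all raise typed errors (see `stereofood.errors`); RANSAC and the scene
generator are seeded everywhere, and repeated runs are bit-identical.
Hartley–Sturm root ties resolve to the smaller displacement of the first
point; nearest-neighbor matching ties resolve to the lowest index.

## Known limitations

Convex hulls overestimate concave foods (inherent to the method).
Foods taller than the 20–100 cm depth gate's implied geometry, deep
dishes, multi-food plates and appearance-based segmentation are out of
scope. The packaged composition table is illustrative, not a nutrition
database.
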