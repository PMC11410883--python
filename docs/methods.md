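# Methods

This note documents the models, conventions and numerical choices behind
`voletooth`: what each stage assumes, which parameters matter, what the
synthetic data does and does not emulate, and where the design was
genuinely open.

## Coordinate frames and calibration

Raster operations use the pixel frame: y-down, 0-based, `(x, y)` =
`(column, row)`. Landmarks and all measurements use a y-up mm frame
obtained as `(x_px · s, −y_px · s)` with `s` the mm-per-pixel scale the
user supplies (no scale-bar reading is attempted). The origin of the mm
frame is arbitrary — it inherits the raster margin — so every comparison
downstream is translation-invariant: classifiers centre each specimen on
its own centroid, and linear indices are extents or point-to-point
distances. Size is deliberately **not** normalized anywhere: images are
calibrated, and absolute size separates many arvicoline species.

Canonical pose places the anterior apex leftmost and the buccal (labial)
side at the bottom of the screen. Orientation is an explicit user input
(rotation + flips); photographs are resampled bilinearly, drawings
nearest-neighbour so strokes stay thin and binary.

## Outline extraction

*Photographs* (background already removed): Otsu binarization, the largest
connected component filled and its boundary traced by marching squares
(`skimage.measure.find_contours`), giving an ordered closed sub-pixel
polyline with ≤ 1 px spacing. A circular moving average (window 5) removes
the half-pixel staircase, which would otherwise inflate arc lengths by
about 6%. A foreground touching the image border is rejected (`clipped
specimen`), as is a photo with more than one component.

*Drawings*: the stroke is assumed near-binary (fixed 50% threshold).
Cement areas drawn inside the re-entrant folds are handled twice over:
satellite components separate from the main stroke are simply not part of
the largest component; blobs attached to the stroke are removed by a
morphological opening whose radius derives from the stroke half-width
(median of the foreground distance transform). The remaining stroke is
thinned (`skimage.morphology.skeletonize`) and the largest closed cycle of
the skeleton graph — spur branches pruned until only cycle pixels remain —
is walked into an ordered chain, preferring the straightest continuation at
junctions. No closed cycle means an open drawing (`outline not closed`).

The trace is canonicalized counter-clockwise in the y-up sense. It is a
polyline with sub-pixel vertices rather than an integer pixel chain; every
tolerance downstream is ≥ 2 px, so the distinction is immaterial, and the
sub-pixel boundary halves the quantization error.

## Feature detection

The trace is resampled to 1 px spacing, rolled so the posterior-most point
(a convex-hull vertex) is index 0, and smoothed with a circular moving
average (default window 7 samples — the exposed `smoothing_window`).
Candidate fold tips are vertices that both

* turn concavely by more than 0.2 rad over a ±0.03 mm arc baseline (the
  baseline is physical, so detection does not change with resolution), and
* lie deeper than `reentrant_depth_fraction` × (convex-hull perimeter)
  from the hull.

The depth reference is the **hull perimeter**, not the outline length: the
outline length grows with fold depth itself, so a threshold tied to it
penalizes exactly the deeply folded teeth it is meant to segment. The
default fraction is 2% — ≈ 0.15 mm for a typical 7–8 mm hull, an order of
magnitude above smoothing- and noise-induced pocket depths (a few
hundredths of a mm) and below any true arvicoline re-entrant. Contiguous
candidate runs are merged across sub-window gaps; each run's tip is then
re-localized on the *unsmoothed* curve (smoothing drags the tip of an
asymmetric pocket sideways) as the centre of the near-maximal depth
plateau (within 0.75 px of the deepest point), which is robust to the
flat-bottomed folds of real enamel.

Tips are assigned to the buccal or lingual side by the direction from tip
to nearest hull point (buccal folds open downward in screen coordinates)
and numbered 1, 2, … from the posterior end per side. Salients (triangle
apices) are the extremal points between consecutive same-side re-entrants.
The segment-*a* endpoints are the deepest points of BRA3 and LRA4; fewer
than 3 buccal or 4 lingual re-entrants raises `insufficient re-entrants`
(endpoints may then be supplied manually).

## Semiperimeter and landmarks

The anterior semiperimeter is the arc between the two *a* endpoints that
contains the apex, canonicalized buccal-endpoint-first. It is decimated to
exactly 200 points at uniform arc-length spacing with both endpoints
preserved; 200 is the fixed representation size of the reference database.
A semiperimeter under 20% or over 80% of the perimeter triggers a warning
(suspicious split), not an error.

## Classifiers

All four methods consume the same representation: 200 ordered (x, y) mm
pairs, centred per specimen. Databases are sorted by (species,
specimen_id), so every argmin tie-break ("first in database order") is
reproducible.

* **MHD** — mean-of-minima directed distances, maximized over the two
  directions; vectorised via a single distance matrix. HDV scans all
  specimens, HDC the per-species pointwise mean shapes. Centroids are
  computed on raw coordinates without prior superimposition (an aligned
  variant would be a one-line extension but is not the stored product).
* **Procrustes** — `scipy.spatial.procrustes`: both configurations centred
  and scaled to unit Frobenius norm, the optimal rotation (reflection
  allowed) and scale applied to the second; the dissimilarity is the
  residual sum of squares. Degenerate (all-coincident) configurations are
  rejected.
* **Fisher LDC** — with p = 400 features and realistic class sizes the
  pooled within-class scatter is singular, so the features are first
  reduced by PCA to `p′ = min(n − N, 400)` components, truncated further
  at ≥ 99% cumulative variance (`pca_variance_retained`, never below
  N − 1 components). Canonical variates come from the symmetric
  generalized eigenproblem `S_b v = λ S_w v` (`scipy.linalg.eigh`), whose
  eigenvectors are S_w-orthonormal, keeping `q = min(N−1, p′)` leading
  axes; between-class scatter is diagonal and decreasing in this basis. A
  residually singular S_w (duplicated specimens) receives a logged ridge
  of 1e-8 · trace. Queries are assigned by Mahalanobis distance to class
  means in canonical space.
* **ECOC-SVM** — features standardized per dimension over the training
  set; one linear SVC (C = 1) per unordered class pair, `N(N−1)/2`
  learners under a one-vs-one coding matrix; decoding minimizes the
  aggregate binary hinge loss `Σ_l |m_kl| · max(0, 1 − m_kl f_l) / 2`,
  normalized per class. The hinge loss is the conventional choice for SVM
  binary learners. Single-specimen classes train but are flagged.

`classify_all` runs the five calls (MHD_V, MHD_C, Procrustes, LDC, SVM),
records per-method failures instead of raising (as long as one method
succeeds), and reports the Procrustes nearest specimen.

## Linear indices

In canonical pose, with the *a* line through the deepest points of BRA3
and LRA4 (its x-position taken as the mean of the two endpoints):

| index | definition |
|---|---|
| L | x-extent of the full outline |
| W | y-extent of the part posterior to the *a* line |
| a | x-distance from the *a* line to the anterior-most point |
| b | y-extent between the *a* line and the cap-bounding re-entrants (T4–T5 region) |
| c | y-extent anterior to the cap-bounding re-entrants (the AC) |
| e | distance from the lowest point of T6 to the highest point of T7 |
| La, Li | apex to buccal / lingual *a*-endpoint (chord; arc length optional) |

T6 is identified as the salient between BRA4 and BRA5, T7 between LRA5 and
LRA6; teeth without a detected fifth buccal re-entrant (e.g.
*Alexandromys*-like morphotypes) report `e` absent with the reason "T6 not
detected" rather than a fabricated value — the deliberate policy for every
index whose defining features are missing. Ratios A/L, B/W, C/W are
recomputed from current segment values on every access, so they can never
go stale. `override_segment` replaces one segment with |p1 − p2| and marks
it manual; overriding *a* reinterprets the points as new *a*-line
endpoints and recomputes a, La and Li (`derived-from-manual`). On real
teeth b and c do not exceed W; the synthetic presets include
wide-anteroconid morphotypes where b may slightly exceed W, so this is not
enforced as an invariant.

## Evaluation

Leave-one-out refits LDC and SVM per fold; the nearest-neighbour methods
use precomputed pairwise distance matrices with the held-out column
masked, which is exactly equivalent to excluding the specimen and keeps
the fold loop O(n) after an O(n²) setup. Species with one specimen are
excluded and listed. Accuracy tables aggregate by species × method and by
source kind (photographs vs drawings, pooled for the totals).

The exemplar cluster picks, per species, the all-methods-correct specimen
nearest its species centroid (Procrustes), computes pairwise Procrustes
dissimilarities among exemplars, links by UPGMA (configurable to
complete/single) and emits newick with ultrametric heights (a join at
cophenetic distance d sits at height d/2). The output carries an explicit
disclaimer: it summarizes geometric similarity within the database and has
no phylogenetic meaning.

## Synthetic molars

Templates are built from two per-side knot tables (posterior end → apex)
interpolated with monotone PCHIP cubics, so each labelled knot — T1–T7
apices, BRA1–5/LRA1–6 tips, AC, PL, the *a* endpoints — is an exact vertex
and local extremum of the outline. Auxiliary knots flank every extremum to
give tips a finite curvature radius (tens of µm, as in real enamel);
perfectly sharp cusps would be clipped at rasterization. Seven parameters
control length (2.2–3.6 mm), width, fold depth, cap size, buccal/lingual
asymmetry, anteroconid stretch (the a/L proportion) and T6 presence. The
six presets are morphotype caricatures chosen to satisfy the generator's
own contracts — pairwise MHD separation ≥ 0.1 mm between preset landmark
sets, full detectability of the microtus-like topology at default
thresholds, and robustness of noisy generation up to σ = 0.05 mm — not
calibrations to real species (an explicit non-goal).

Specimens are templates displaced along a smoothed outward-normal field by
circularly correlated Gaussian noise (correlation length 0.25–0.3 mm of
arc, rescaled to the requested pointwise σ). Smoothing the normal field
makes the two walls of a cusp move coherently, which keeps the outline
simple; a draw that still self-intersects is rejected and redrawn
deterministically from the same seeded stream (up to 8 times). Default
study conditions for database experiments are σ = 0.02 mm — about 1–2% of
tooth size, comparable to digitization noise — with 30 specimens per
species; the noise-degradation checks use σ ∈ {0.005, 0.02, 0.05} mm at 6
per species over 10 seeds, sizes chosen to finish comfortably on one CPU.

Rasterization covers both dialects: `filled` (solid dark tooth on white,
the segmented-photo case) and `stroke+cement` (a ~3 px outline plus cement
blobs nestled inside the deep folds, detached from the stroke by 2 px and
sized to the local wall clearance). Ground-truth sidecars store the
polyline and labels in mm and px.

What the generator does **not** emulate: enamel-band thickness (the inner
enamel edge is the mask boundary; a morphological offset hook exists but
defaults to 0), wear and breakage, lighting/greyscale texture, partial
outlines, multi-tooth images, and real interspecific covariance structure.
Passing tests therefore demonstrate the correctness of the geometry,
classification and measurement machinery under known truth — not field
accuracy on real collections, which depends on a curated reference
database.

## Numerical choices and limitations

* Tie-breaks: argmin takes the first minimum; databases are pre-sorted, so
  repeated runs are byte-identical. Reports format floats at 9 significant
  digits; database CSVs at 17 (lossless round trip; reads use pandas'
  round-trip parser).
* Determinism: a single seed feeds every random draw; trained models and
  LOO tables are pure functions of (database, seed).
* The Procrustes dissimilarity is scale-normalized (unit centroid size),
  so unlike MHD it ignores absolute size; the two methods are deliberately
  complementary.
* Feature detection assumes the canonical pose and an approximately
  horizontal tooth; heavily rotated inputs must be oriented first.
* The e index requires the full 5-buccal/6-lingual topology to name T6 and
  T7; shallower anterior notches than the depth threshold make e absent
  even when a human would point at T6 — preferring a missing value to a
  wrong one, consistent with the absent-feature policy.
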