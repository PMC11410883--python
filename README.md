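# voletooth

Outline-based geometric morphometrics and species classification for
arvicoline (vole and lemming) first lower molars.

Identifying arvicoline species — extant or fossil — rests almost entirely on
the occlusal surface of the first lower molar (m1): an elongate outline of
alternating buccal and lingual enamel triangles (T1–T7) separated by
re-entrant angles (BRA/LRA), capped anteriorly by the anterior cap (AC) and
posteriorly by the posterior lobe. Because many species overlap in these
characters, assignments from drawings and photographs are slow and
subjective. `voletooth` automates the workflow: it turns a calibrated image
of a single m1 (a segmented photograph or a literature line drawing) into a
standard 200-landmark representation of the anterior semiperimeter,
classifies it against a labelled reference database with four independent
methods, and measures the classical Van der Meulen linear indices
automatically.

## Methods at the core

Given a cleaned image with a known mm-per-pixel scale in canonical pose
(anterior left, buccal down):

1. **Outline extraction.** Photographs: the boundary of the binarized
   (Otsu) foreground mask. Drawings: cement areas removed, the stroke
   thinned to a one-pixel skeleton, and the largest closed skeleton cycle
   (the stroke midline) traced.
2. **Feature detection.** Re-entrant angles are concave folds whose depth
   from the convex hull exceeds 2% of the hull perimeter, numbered
   BRA1…/LRA1… from the posterior end per side. The segment-*a* line runs
   through the deepest points of BRA3 and LRA4.
3. **Landmarks.** The anterior semiperimeter (from the buccal *a* endpoint
   through the apex to the lingual endpoint — triangles T4–T7 plus the AC)
   is decimated to *n* = 200 points at uniform arc-length spacing, in mm.
4. **Classification.** Four methods, each centring every specimen on its
   own centroid (size is kept — it is diagnostic among arvicolines):
   - **MHD** (modified Hausdorff distance),
     `MHD(A,B) = max( mean_a min_b |a−b|, mean_b min_a |a−b| )`,
     against every specimen (HDV) or per-species mean shapes (HDC);
   - **Procrustes** nearest neighbour: residual sum of squares after
     optimal translation, scaling, rotation and reflection;
   - **Fisher LDC**: canonical variates of between- vs within-class
     scatter after PCA pre-reduction to `p′ = min(n−N, 400)` dimensions
     (≥ 99% variance), `q = min(N−1, p′)` axes, assignment by Mahalanobis
     distance in canonical space;
   - **ECOC-SVM**: all `N(N−1)/2` one-vs-one linear support-vector
     machines, decoded by minimal aggregate hinge loss.
5. **Linear indices.** L, W, a, b, c, e, the La/Li asymmetry and the
   ratios A/L = 100·a/L, B/W, C/W, measured from the full outline; any
   segment can be overridden manually, with dependent quantities
   recomputed.

A parametric synthetic-molar generator (`voletooth.synthetic_molars`)
produces labelled vole-like outlines — six morphotype presets, controllable
smooth noise, photo and drawing rasterization with ground-truth sidecars —
so the entire pipeline is testable without access to specimen collections.

## Worked example

Generate a small synthetic reference set, build a database, and classify
one rendered image end to end:

```sh
for p in microtus-like terricola-like iberomys-like; do
  voletooth synth --preset $p --n 8 --sigma 0.02 --seed 7 -o fixtures
done
voletooth db build fixtures/*.csv -o refdb
# -> 24 specimens, 3 species -> refdb

voletooth process fixtures/microtus-like-003.png \
    --scale-mm-per-px 0.01 --kind photo -o query
voletooth classify query/microtus-like-003.csv --db refdb -o result.json
```

`result.json` (abridged):

```json
"predictions": {
 "mhd_v":      {"score": 0.0029547899,   "species": "microtus-like"},
 "mhd_c":      {"score": 0.0182219978,   "species": "microtus-like"},
 "procrustes": {"score": 3.68204305e-05, "species": "microtus-like"},
 "ldc":        {"score": 0.811786455,    "species": "microtus-like"},
 "svm":        {"score": -0.0,           "species": "microtus-like"}
},
"nearest_specimen_id": "microtus-like-003"
```

All five methods agree on the species. Scores are distances (mm for MHD,
dimensionless Procrustes residual, canonical-space Mahalanobis for LDC) or
a negated decoding loss for the SVM; the Procrustes score is ~0 and the
nearest specimen is the query itself because this demo classifies a
specimen that is also in the database — run `voletooth loo` for honest
held-out accuracy (here: 100% for every method on this separable set).

Automatic measurement of the same image:

```sh
voletooth measure fixtures/microtus-like-003.png --scale-mm-per-px 0.01 -o indices.json
# L 2.91  W 0.88  a 1.4745  b 0.94  c 0.70  e 1.684  La 1.530  Li 1.428  (mm)
# ratios: A/L 50.7, B/W 106.8, C/W 79.5
```

L is the total anteroposterior length; a/L ≈ 51% says half this molar is
anteroconid complex — the kind of value these indices exist to compare
across species. (On this narrow-posterior synthetic morphotype the
anteroconid is wider than the posterior region, so B/W exceeds 100.)

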