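# Methods

## Pipeline model and assumptions

`rowkit` reconstructs crop-row geometry from discrete plant-center points
under three assumptions: rows are straight over the imaged extent, they
lie on a common ground plane, and a single projective map relates that
plane to the image. The pipeline is

1. **IPM.** A homography `M` is estimated from four point correspondences
   by the direct linear method with `h33` fixed to 1 (8 unknowns, exact
   solve). Fixing `h33` fails if the true entry is ~0, which cannot occur
   for ground-plane IPMs; degenerate correspondences (coincident points,
   collinear triples) are rejected up front with an explicit error rather
   than a silent singular solve. One correspondence set describes one
   camera pose and may be reused across images or supplied per image —
   both workflows are supported.
2. **1-D clustering.** After IPM, one row's plants share a transverse
   coordinate x′ up to noise, so DBSCAN runs on x′ alone with the metric
   |x′_j − x′_i|. The point itself counts toward its neighborhood.
   Classic DBSCAN assigns border points in scan order; here a border point
   joins its *nearest* core point (ties to the smaller x′), which makes
   labels a pure function of the multiset of coordinates — clusterings are
   permutation-invariant and reproducible. Ids are ordered left to right
   by cluster mean.
3. **Completeness filter.** Clusters with fewer than `min_row_size`
   members are relabeled noise: a row clipped at the image border shows
   few plants, and plant count is the natural completeness indicator.
4. **Centerline fit.** x′ = m·y′ + c with y′ independent, because rows
   extend along the travel direction and the quantity of interest is the
   transverse residual. LSM is the closed-form normal-equation solution;
   PCA takes the dominant eigenvector of the 2×2 covariance of (y′, x′);
   RANSAC scores random 2-point hypotheses by inlier count (ties by lower
   total inlier residual) and refits the winning inlier set with LSM.
   A row with all y′ equal (perpendicular to travel) is a degenerate-fit
   error for every fitter.
5. **Back-projection and selection.** Lines map to image space through
   `M⁻¹` using the line transform `l_img = Mᵀ l_ipm`, which is exact (no
   endpoint sampling needed). The two rows whose image-space x at the
   reference height lies nearest the image horizontal midpoint become the
   navigation pair. "Image midpoint" is read literally as mid-height
   (`y_ref = H/2`, configurable via `--y-ref`): the alternative —
   evaluating at the bottom edge, the vehicle position — is defensible but
   changes selection only when rows cross, which straight-row scenes do
   not produce.

## Evaluation conventions

* θ uses `arctan(|m₁−m₂| / |1+m₁·m₂|)` with an absolute value on the
  denominator and θ = 90° at the perpendicular singularity. Without the
  absolute value the formula goes negative/undefined for near-perpendicular
  slope pairs; the chosen form preserves the intended inter-line angle and
  satisfies the direction-vector (cross/dot) geometry, which the tests
  check against directly.
* δ averages |x₁ − x₂| at y ∈ {0.25H, 0.5H, 0.75H} by default; "same
  vertical position" is otherwise unspecified, and three spread samples
  capture both offset and tilt error. Configurable.
* Evaluation happens in image space by default (ground truth is annotated
  on images); fitted IPM-space lines are converted by the exact line
  transform first. IPM-space evaluation is available by passing
  ground-space lines instead.
* Ground-truth-to-fitted matching is greedy one-to-one by smallest center
  deviation — deterministic and adequate when rows are well separated;
  Hungarian assignment would differ only in pathological overlaps and is
  deliberately not the default. Unmatched ground-truth rows count as
  invalid (θ = δ = ∞) in the validity rate but are excluded from the θ/δ
  means, which are averaged per image first and then across images,
  matching the double-sum definitions (the test suite pins this order
  against point-pooling).
* Validity threshold: 5° (configurable). FPS = 1000 / mean per-image
  milliseconds; all timing numbers are hardware-dependent diagnostics,
  never assertions.
* Detection AP uses all-point interpolation (area under the monotone
  precision envelope) with greedy confidence-descending IoU ≥ 0.5
  matching; with a single class mAP@0.5 = AP.

## Synthetic scenes

The generator emulates exactly what the pipeline consumes: `n_rows`
parallel ground-plane rows at `row_spacing` (default 5 rows, 80 units),
`n_plants_per_row` plants at `plant_spacing` intervals (12 at 28 units,
filling the rectified region), lateral Gaussian jitter of sd σ
perpendicular to the row direction, independent Bernoulli dropout, and
uniform outlier points over the ground region standing in for weeds and
false detections. Everything is projected through a ground-to-image
homography whose default maps a bottom-wide image trapezoid
(100,440)/(540,440)/(250,120)/(390,120) to an axis-aligned rectangle —
rows converge toward the image top as in a real forward-facing camera.
Scenes are bit-deterministic per seed.

Not modeled: plant appearance, illumination, occlusion-correlated
detection failures, curved rows, growth stages. Passing tests on these
scenes validates the geometry/clustering/fitting/evaluation chain, not
any upstream detector.

The reference stochastic benchmark fixes σ = 1.6 (2% of row spacing),
dropout 0.1, 3 outliers per scene, 200 seeded scenes — a moderate-noise
regime a field dataset of well-established maize seedlings plausibly
occupies. Under it the LSM pipeline holds a validity rate ≥ 0.95 with
mean θ̄ < 1°, and LSM/PCA agree within 0.1°. Problem sizes (20 scenes for
the noise-free closure, 200 for the benchmark) are chosen so the whole
suite runs in seconds on one CPU while keeping Monte-Carlo noise well
below the margins being checked.

## Numerical choices

* Tolerances: 1e-6 px reprojection for exact 4-point estimates, 1e-9 for
  round trips, 1e-12 singularity guards — double precision with
  pixel-scale magnitudes.
* DBSCAN ε is a required parameter (heuristic: ~0.25 × expected row
  spacing in destination-plane units; 20 for the default scenes). An
  automatic ε from inter-cluster gaps is circular and not attempted.
* `min_samples = 3`, `min_row_size = 4` by default: small enough to keep
  a 12-plant row through 10% dropout, large enough to discard a
  half-visible border row or a clump of outliers.
* RANSAC: 100 iterations, inlier tolerance 2.0 destination units, seeded
  generator (per-cluster seed derived from the run seed). In the fitter
  comparison RANSAC instead runs at a deliberately loose tolerance of
  2×ε: any point density-attached to a cluster lies within
  ε + cluster-half-width of the centerline, so at 2×ε the whole cluster
  is the inlier set and the comparison isolates hypothesis selection from
  outlier trimming (at a trimming tolerance RANSAC can quietly excise
  cluster-attached outliers and edge the closed-form fits, which is a
  different experiment).
* LAMP scores sort weights by *ascending* magnitude, so the largest
  weight in each layer scores exactly 1 and pruning the globally lowest
  scores removes small weights; a descending-order variant is available
  behind a flag for comparison, under which the score ordering inverts.
  Ties among equal magnitudes break by original index (stable sort) —
  arbitrary but reproducible. Global masks prune
  `floor(sparsity × total)` weights; masks at increasing sparsity are
  nested.
* PConv FLOPs: both the linear form h·w·k²·c_p and the quadratic form
  h·w·k²·c_p² are implemented; ratios against a standard convolution use
  the quadratic form, under which convolving a quarter of the channels
  costs exactly one-sixteenth, independent of h, w, k.

## Known limitations

Straight rows only (no polynomial/curved models); single frame (no
tracking); the IPM correspondence is user-supplied, not auto-estimated
from vanishing points; evaluation assumes every ground-truth row is
expressible as x = m·y + c in the evaluation space (near-horizontal rows
are excluded by construction); wall-clock FPS figures depend entirely on
the host machine.
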