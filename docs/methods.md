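# Methods

This note documents the models and procedures implemented in `vitis3d`,
the parameters that matter, the synthetic data the tests run on, and the
design choices made where the problem left the design open.

## Problem setting

A grapevine row is photographed from a moving track at three camera
heights, and a multi-view-stereo (MVS) reconstruction turns the images
into a colored 3D point cloud (meters, RGB) together with the corrected
camera positions. The pipeline distills three yield parameters from that
cloud: the number of grape bunches, the number of berries, and the berry
diameter distribution. Only one side of the row is photographed, so only
the camera-facing side of every surface is reconstructed; algorithm design
leans on that asymmetry in two places (normal orientation and the
valley test below).

## Preprocessing

* **Background removal.** Night-time acquisition leaves the background
  black. Colors are converted to HSV (hexcone formulas; H in degrees) and
  points with brightness V below `v_threshold` (default 0.10) are dropped.
  The threshold is a data-dependent choice; the synthetic generator places
  background at V < 0.08 so the default separates cleanly.
* **Statistical outlier removal.** For each point the mean distance d_i to
  its `sor_k` = 6 nearest neighbors is computed; points with
  d_i > μ + `sor_sigma_mult`·σ (μ, σ over all d_i, multiplier 1.0) are
  removed. These are CloudCompare-style defaults.
* **MLS smoothing.** Each point is projected onto a bivariate polynomial
  of order 2 fitted by Gaussian-weighted least squares (weight scale
  radius/2) over its 4 mm neighborhood, expressed in the frame of the
  local weighted-PCA plane. 4 mm spans a berry flank without flattening
  it. Points with fewer than max(6, n_coefficients + 2) neighbors pass
  through unmoved rather than being dropped.
* **Subsampling.** Greedy first-come minimum-distance subsampling to 1 mm
  over a spatial grid; deterministic (storage order), no RNG. All
  downstream density-dependent defaults assume this 1 mm spacing.

## Surface feature histograms (125 + 3 features)

The per-point descriptor concatenates a 125-bin surface feature histogram
with the HSV triplet (H scaled to [0, 1]).

Normals come from PCA over `r_N` = 3 mm neighborhoods — the scale of a
berry's slope — and are oriented toward the nearest camera position, which
is well defined precisely because only camera-facing surfaces exist.
Points with fewer than 3 neighbors are flagged and excluded.

For every unordered pair (i, j) of points within `r_H` = 9 mm of the query
point (about one and a half berries — large enough to span the
valley-ridge alternation of a bunch surface, small enough that leaves stay
locally planar), the three Darboux-frame angle features are computed: with
the source s chosen as the point whose normal subtends the smaller angle
with the connecting vector d, u = n_s, v = u × d̂, w = u × v, the features
are f1 = v·n_t ∈ [−1,1], f2 = u·d̂ ∈ [−1,1], f3 = atan2(w·n_t, u·n_t) ∈
(−π,π]. Each feature is quantized into 5 equal-width bins over its
analytic range (boundary values land in the upper bin) and the joint
5×5×5 histogram is normalized to sum 1, making the descriptor invariant
to point density and rigid motion. All pairs inside the neighborhood
participate (not only pairs through the center), following the
plant-phenotyping adaptation of the point-feature-histogram family.
Points with no valid pair get a zero histogram and a validity flag.

The inner loop is numba-compiled; the test suite checks it against a
pure-Python brute-force reimplementation.

## Import vector machine

The classifier is a sparse kernel logistic regression: p(bunch | x) =
σ(b + Σ_s α_s k(x, x_s)) with an RBF kernel over standardized features and
a small set of import points selected greedily from the training data
(~600 points per class). Unlike an SVM it produces genuine posterior
probabilities, which the graph-cut stage consumes as unary energies.

* Kernel bandwidth: median heuristic, γ = 1 / median ‖x − x′‖² over a
  seeded subsample of standardized training pairs. A rule tied to the
  nominal feature count misbehaves when most columns are near-constant
  (as in low-dimensional toys or degenerate scenes); the median heuristic
  adapts to the effective dimensionality.
* Objective: mean negative log-likelihood + λ αᵀK_SS α, λ = 10⁻³.
* Selection: per step, ≤ 100 seeded random candidates are scored by the
  magnitude of the functional gradient (correlation of the candidate's
  kernel column with the current residual); the top 8 are refined with
  short damped-Newton refits and the best joins the import set, followed
  by a full refit. Selection stops at `max_import` = 200 or when the
  objective improvement drops below `tol` = 10⁻⁴ of the bias-only
  objective — measuring improvement relative to the *initial* objective
  keeps selection from crawling along a near-zero objective on separable
  data.
* Ties in the final argmax go to canopy, which is conservative for bunch
  precision. Invalid feature rows receive the training prior and a flag.

On a 1-D two-Gaussian problem with 2000 training points the predicted
posterior tracks the closed-form Bayes posterior to within 0.1 over the
central ±2.5σ of the data; outside the data's support the RBF model
saturates toward the prior, as any local kernel method does.

## Graph-cut label smoothing

Labels are smoothed by exactly minimizing
E(L) = Σᵢ (1 − Pᵢ(Lᵢ)) + penalty · Σ_(i,j)∈edges 1[Lᵢ≠Lⱼ]
over the radius graph (edge iff distance ≤ 3 mm ≈ 3× the subsampling
distance; uniform Potts penalty 0.5). The bounded unary cost 1 − P is
used rather than −log P so that a single confident point can never
dominate the neighborhood term. For two labels the energy is submodular
and one s-t min-cut yields the global optimum; capacities are scaled to
integers with an adaptive factor keeping the total below 2³¹ (resolution
loss ≪ the unary resolution at every size used), and the reported energy
is recomputed in float64 from the labeling. The suite verifies exactness
against exhaustive enumeration on ≤ 15-node instances.

## Bunch segmentation

Connected components at 5 mm group bunch-labeled points; components with
fewer than `min_points` (400; 300 for the denser hedge-trained canopy)
are misclassification residue and are deleted. Components above
`max_points` (5000 / 3000) usually fuse several bunches and are
re-partitioned at 1 mm; split fragments are re-filtered with `min_points`
so single split-off berries cannot masquerade as bunches — consistent
with the ≥ 3-berry rule below. Implementation: KDTree pair enumeration +
sparse connected components; exact and deterministic (verified against an
O(N²) union-find oracle).

## findBerries

Within one candidate bunch, the detector repeats: draw a source point
from the remaining pool, fit a sphere to its `fit_radius` = 1.2·r_max
neighborhood, and evaluate the candidate through four stages in order:

1. **Radius** — reject outside [`r_min`, `r_max`] = [4, 10] mm (the field
   berry radius is about 6 mm; the dense artificial bunch uses 7–11 mm).
2. **Support** — points within (1 + `inlier_tol`)·r of the center are
   split into shell inliers (| ‖p−c‖ − r | ≤ 0.10·r) and interior
   outliers; require ≥ `min_fit_points` = 10 inliers and an inlier
   fraction ≥ `min_support_ratio` = 0.5. Additionally the support must
   wrap around the sphere: if the mean of the support's unit directions
   exceeds `max_support_concentration` = 0.8 in norm, the "berry" is a
   narrow tangent cap (a noise-induced sphere grazing a flat leaf
   measures ≈ 0.89; genuine berries stay ≤ 0.65 even when only a rear-
   culled cap is visible) and is rejected.
3. **Valley test** — a sphere nestled in the empty space between berries
   has no surface on the ray toward the camera. Support points within
   `line_tol` = 1.5 mm of the segment from the center toward the nearest
   camera (length r + line_tol) are counted; ≥ `min_line_points` = 3 are
   required. Three is the largest density-consistent default: at 1 mm
   subsampling the line tube holds at most ~4 points on a genuine crown
   (measured ridge counts 2–6) and 0–2 in a valley.
4. **Overlap** — overlap ratio (r_a + r_b − ‖c_a − c_b‖) / (2·min(r_a,
   r_b)) above `overlap_ratio` = 0.25 triggers a support comparison. The
   candidate replaces the incumbent only if the support it could
   actually *claim* (unclaimed points plus the incumbent's points) is
   strictly larger than the incumbent's claimed support. Comparing
   claimable against claimed keeps the comparison symmetric; comparing
   raw component-wide counts instead lets a sphere straddling several
   already-claimed shells inflate its support, evict genuine berries,
   and in the worst case cycle forever.

Support is computed over the whole component, not just the fit
neighborhood, so partially reconstructed berries accumulate their full
evidence. On acceptance the claimed support leaves the pool and the
failure counter resets; the loop stops after 2 × (#remaining) consecutive
failures or when the pool shrinks below `min_fit_points`.

Numerical design of the fit: the initial sphere is an algebraic
least-squares fit (linearized ‖p‖² = 2c·p + (r² − ‖c‖²)) with one
Gauss-Newton refinement, Gaussian-weighted around the source (scale
0.35·r_max) so it locks onto the source's own berry; up to three
inlier-trimmed refits over the whole-component neighborhood follow, which
makes the fitted sphere for a given source independent of the acceptance
order — the dominant term in run-to-run repeatability. A candidate whose
final sphere no longer keeps its own source as an inlier has drifted onto
some other structure and is discarded. Sources are drawn in seeded random
order without replacement (reshuffled whenever the pool changes), which
preserves the stated failure budget while guaranteeing every remaining
point a chance within it. After acceptance the sphere is refit once on
its full support — which may span much more of the berry than the source
neighborhood — provided the refined radius stays in range; this step
dominates diameter accuracy for partially occluded berries. The hot loop
is numba-compiled; the public `fit_sphere` keeps the plain numpy
implementation and the suite pins the two against each other implicitly
through the exact-recovery tests.

## Yield report and evaluation

Components with ≥ `min_berries` = 3 detected berries constitute the bunch
count; berry count and diameters are pooled over surviving components,
with an optional per-meter breakdown along the row's first principal
axis. Evaluation follows the field-counting conventions: bunches are
matched to reference bunches greedily by maximum point overlap, so a
component fusing k true bunches scores one true positive and k − 1 false
negatives, and a bunch split across two components scores one true
positive and one false positive. Berries are matched one-to-one by
optimal assignment under a center-distance cap (default 1.2·r_max), and
the diameter RMSE is computed over matched pairs. Recall and precision
are defined as TP/(TP+FN) and TP/(TP+FP), reported as 0 with a flag when
undefined.

## Synthetic scenes

The generator emulates what the pipeline actually receives after MVS
reconstruction, with full ground truth:

* **Bunches.** Berries (radius 6 ± 0.5 mm by default) are packed
  sequentially into an ellipsoidal envelope (~30% packing fraction,
  elongated 1.5× vertically): each new center sits at touching distance
  (up to 25% overlap of the smaller radius, up to 2 mm gap) from an
  existing berry and intrudes no deeper into any other. Sphere surfaces
  are sampled on rotated Fibonacci lattices at 1 mm; points interior to
  another berry are removed, producing the valley-ridge geometry.
* **Canopy.** Leaves are planar disks (Vogel spirals) with
  camera-biased random orientations; stems are near-vertical cylinders
  placed between bunches.
* **One-sided coverage.** Points whose outward normal faces away from
  the nearest camera are culled — a normal-facing test rather than ray
  casting, which is cheap and reproduces the rear-hemisphere loss of a
  single-sided reconstruction; it does not reproduce fine inter-leaf
  occlusion shadows.
* **Noise model.** Gaussian surface noise along the normal (0.2 mm
  default), uniform isolated outliers, and dark background points
  (V < 0.08) behind the row.
* **Colors.** Bunch HSV ≈ (90° ± 20°, 0.40 ± 0.10, 0.45 ± 0.10), canopy
  ≈ (110° ± 15°, 0.60 ± 0.15, 0.55 ± 0.15) — deliberately overlapping so
  that neither color nor geometry alone solves the classification.
* **Cameras.** A track at 0.625 m from the row, 15 cm steps, three
  heights (1.1 / 1.3 / 1.5 m).

The artificial-bunch analog (for the controlled berry-detection analyses)
packs 50 berries with diameters uniform in 15–20 mm, samples at 0.5 mm
with 0.05 mm noise, and keeps only line-of-sight surfaces as seen from 26
viewpoints surrounding the bunch (ray-sphere occlusion culling) — full
surface sampling would include deep crevice surfaces no real scanner
records, which act as spurious attractors for sphere fitting. The
field-quality analog (40 berries, 12 mm, 0.3 mm noise) culls the rear
hemisphere instead, emulating the one-sided track reconstruction.

What passing tests on these scenes do *not* show: robustness to MVS
artifacts absent from the generator — non-Gaussian depth error, melted
berry-leaf transitions, holes from failed matching, exposure variation
along the row — nor to cultivars whose berry radii or colors fall outside
the configured ranges. The scale of the test scenes (1–3 m of row,
10⁴–10⁵ points after subsampling) was chosen so the full suite runs in
minutes on one CPU; all stage algorithms are independent of absolute
scene size except for runtime.

## Degenerate inputs and tie-breaking

Sphere fits with < 4 points or coplanar support raise a degenerate-fit
error and count as candidate failures. Subsampling keeps the
first-encountered point of any close pair. Argmax ties go to canopy.
Zero-posterior-margin graph-cut nodes may land on either side of the cut;
the energy is identical and tests assert energy equality rather than
label equality in tie-prone cases. Empty components, empty berry lists
and zero-denominator metrics return zero-valued reports with explicit
flags rather than NaNs (diameter RMSE stays NaN when no pair matched).

## Known limitations

* Only one row side is processed; no correction for the hidden side is
  attempted, so absolute counts underestimate the row total.
* Berries are modeled as spheres; strongly ellipsoidal berries bias both
  detection and diameter.
* Bunches closer than the 1 mm second-pass threshold stay fused and
  count once; a branch crossing a bunch can split it.
* The IVM is binary (bunch vs canopy) by design; finer organ classes are
  out of scope.
* Chunked processing of very large rows (multiple PLY files) treats
  chunks independently; components are not merged across chunk borders.
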