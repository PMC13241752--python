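# Methods

## The measurement model

The pipeline treats a wound as a closed region in a photograph, delivered
with a binary segmentation mask and a single-channel depth map (both are
*inputs*: segmentation and monocular depth estimation are upstream of this
package). Clinically, edge categories describe how the tissue passes from
peri-wound skin into the wound bed, so the object of measurement is a narrow
annulus around the wound contour, not the wound interior.

The stages and their assumptions:

1. **Mask cleanup.** Only the largest 8-connected component is kept (the
   wound of record; secondary lesions and segmentation debris are dropped)
   and interior holes are filled. Assumption: one wound per image.
2. **Transition band.** `dilate(mask, disk(d_out)) AND NOT
   erode(mask, disk(d_in))` with disk structuring elements (isotropic by
   construction). `d_in = d_out = 20 px` by default, sized for a 512 px
   frame with a 90 px wound radius and exposed in `RunConfig` because the
   appropriate width scales with image resolution.
3. **Contour.** The sub-pixel 0.5 iso-contour of the mask, smoothed with a
   5-point circular moving average and resampled to `K = 360` points at
   uniform arc length. Normals are central-difference tangents rotated 90°,
   sign-fixed to point outward by probing mask occupancy 2 px along the
   normal. The smoothing matters: the raw marching-squares polyline of a
   binary mask overestimates the perimeter of smooth shapes by ~3% and
   carries ~±0.3 px radial jitter; after smoothing a digitized disk's
   measured perimeter is within 0.2% of 2πr.
4. **Depth detrending.** Least-squares plane over the transition band (not
   the full frame, so that crater depth does not bias the fit — `band` vs
   `full` is a config switch), subtracted everywhere. Monocular depth maps
   have arbitrary scale and a strong pose-induced planar trend; subtracting
   the plane leaves edge-relative relief.
5. **Rectification.** The raster is sampled bilinearly at `p_k + δ·n_k`,
   `δ = +d_out … −d_in` in 1 px steps (native resolution, no resampling
   artifacts), giving a `K × (d_in + d_out + 1)` rectangle whose columns run
   outside → inside with the wound border exactly at column `d_out`.
   Samples outside the frame are flagged invalid, never fatal; a row is
   valid when all its samples are.
6. **Edge profile.** Per-column median over valid rows (≥ 50% of rows must
   be valid). The median, rather than per-row fits with voting, absorbs
   local contour noise and produces one profile per wound. The profile is
   anchored (outer end → 0) and scaled by its 10th–90th percentile range;
   profiles with range < `ε_flat = 1e-6` depth units are flagged
   degenerate-flat and left unscaled so noise is not amplified into fake
   structure.
7. **Template classification.** Four trend templates are fitted to the
   normalized profile: flat (`c`, 1 parameter, closed form), linear
   (`α + βδ`, 2, closed form), and the logistic
   `A/(1+exp(−(δ−δ₀)/w)) + c` (4) fitted twice with bounded nonlinear least
   squares — once with `w ≤ w_abrupt = 3 px` (*abrupt*: the transition is
   effectively a step at band scale) and once with `w > w_abrupt`
   (*smooth*). Multi-start: δ₀ on a 5-point grid over the window plus the
   steepest-gradient location, `w ∈ {1, 5, 15}` clipped to the branch
   bounds; analytic Jacobian; `δ₀` constrained to the window. The winner
   minimizes `BIC = n·ln(RSS/n) + p·ln(n)`; without the parsimony term the
   nested flat/linear forms could never win. RSS is floored at 1e-12 inside
   the logarithm for exactly-interpolating fits.
8. **Descriptors.** Geometry: pixel area; contour arc-length perimeter;
   circularity `4πA/P²` (shoelace area of the sub-pixel contour, so a
   digitized disk scores ≈ 1); solidity and eccentricity from region
   properties; border irregularity = perimeter / convex-hull perimeter;
   coefficient of variation of the contour's radial distances; plus the
   profile descriptors (winner one-hot, per-template RSS, logistic
   amplitude/centre/width, max gradient and its location, inside-minus-
   outside mean, rim prominence = max of the outer half-band minus the
   outer baseline). Visual: per-region (bed = mask eroded by `d_in`, inner
   band, outer band) RGB and HSV means/SDs with hue treated circularly,
   redness `R/(R+G+B)`; gray-level co-occurrence contrast/homogeneity/
   energy/correlation of the rectified band (32 levels, offset 1 px along
   the band, i.e. parallel to the border); gradient-magnitude mean and
   entropy. An empty region (e.g. bed erased by erosion of a thin wound)
   yields sentinel zeros and a log warning rather than an error. All sizes
   are in pixels: physical calibration from rulers or colour cards is out
   of scope.

## Agreement statistics

Cohen's κ, the Adjusted Rand Index, optimal cluster-to-category assignment
(exact, via the Hungarian algorithm on the contingency table — "optimal"
matching is an assignment problem, and exactness is cheap at k ≤ 6), and the
classical pooled-variance two-sample Student's t-test. κ is unweighted: the
categories are nominal. Summaries over rater pairs use the sample SD
(ddof = 1); a single pair reports SD 0 by convention. κ is undefined (an
error, not a NaN) when both raters are constant with the same label.

## The experiments

*Unsupervised*: the clustering feature vector is the normalized profile
concatenated with the per-template RSS values and the winning logistic
branch's parameters; PCA (default, deterministic) or UMAP to 2 dims;
k-means (k-means++ init, 10 restarts) with k = 5 so the post-hoc comparison
with the five merged categories is one-to-one. ARI needs no label matching
(it is permutation-invariant); κ is computed after optimal matching, per
rater. The headline single ARI is reported against a configurable reference
rater (default: the first).

*Supervised*: one model per rater — no consensus label is invented, matching
evaluation against each clinician separately. Default classifier:
histogram gradient boosting with class-weighted loss (random forest as a
config alternative); stratified 5-fold CV repeated 10 times with distinct
shuffles; κ is computed on pooled out-of-fold predictions once per repeat,
giving `repeats × raters` runs; accuracy and macro precision/recall/F1 pool
all repeats. Geometry-only and full-feature runs share fold assignments for
a given seed (folds depend only on the labels and the seed); their run-level
κ samples are compared with the two-sample t-test. Feature importances are
permutation importances (10 shuffles on a held-out 25% split, averaged over
raters, normalized to sum 1) — impurity importances would be biased toward
high-cardinality features. Note the boosted-tree default keeps sklearn's
`min_samples_leaf = 20`; cohorts far below ~100 images underfit to the
majority class, so use the random-forest option for very small cohorts.

If a rater's rarest class has fewer members than the fold count the fold
count is reduced to it; raters using fewer than 2 classes are skipped with a
warning.

## The synthetic generator

Scenes emulate exactly the properties the pipeline is sensitive to:
irregular closed contours (radial-Fourier perturbation, modes 2–5 with
amplitudes ~0.01–0.06 drawn per seed unless specified), an archetype-specific
depth crater expressed through the signed distance `s` to the contour,
a planar depth tilt (default `(0.02, 0.01)` depth-units/px) to exercise
detrending, Gaussian depth noise (σ = 0.15, small against crater depths of
~10 so the median-aggregated profile stays clean), and region colouring
(reddish bed, skin-toned periphery, whitened ring for hyperkeratotic, with
per-archetype texture noise). The signed distance is the radial distance
`r − ρ(θ)`: exact for circles (making the radial-symmetry oracle exact) and
a smooth proxy of normal distance for mild perturbations.

The five archetypes map one-to-one onto the merged clinical categories so
recovery is well-posed: indistinct — shallow wide ramp (D = 2.5, w = 10 px);
attached — linear ramp (D = 10, w = 10); not-attached — abrupt logistic drop
(D = 12, w = 1.2); rolled/fibrotic — Gaussian rim (h = 5, centred 4 px
outside, σ = 2.5) plus drop; hyperkeratotic — plateau (h = 5 over 14 px)
before the drop. `scaled_scene_params(scale)` shrinks every pixel length
together so desk-scale frames keep proportional geometry.

Simulated raters draw labels from per-rater confusion matrices. The default
four-rater panel mixes the identity with a uniform response at error rates
(0.50, 0.55, 0.55, 0.60), chosen via the closed-form `expected_kappa` so the
panel's exact pairwise κ sits near 0.2 — the weak-agreement regime reported
for expert clinicians — before any simulation is run.

What passing tests on these scenes do **not** show: robustness to real
photographs (lighting, perspective, heterogeneous skin tones, segmentation
and depth-estimation error, multiple lesions), nor that clinical labels are
geometrically determined — on the contrary, the synthetic cohorts are built
so that geometry (or colour) *does* determine the label, which is what makes
them recovery oracles for the machinery.

## Problem sizes and numerical tolerances

Reference experiments run at half scale (256 px frames, r₀ = 45 px,
d_in = d_out = 10 px, K = 180): archetype recovery on 500 scenes,
feature-set contrasts on 100, the rater-panel benchmark on 1 860 labels, and
Monte-Carlo κ checks at n = 10 000 (κ standard error ~n^(−1/2), tested at
tolerance 0.03).

Template-recovery accuracy is evaluated on 101-sample profiles
(d_in = d_out = 50, the band width at full clinical resolution) with noise
σ = 0.05 and transitions placed and sized to be visible inside the window.
This is an identifiability boundary, not a tuning choice: BIC selection is
invariant to profile scaling, so flat-vs-linear confusion depends only on
window length — at n samples a noise-only profile selects linear whenever
the regression F statistic exceeds ≈ n(n^{1/n} − 1), which happens with
probability ≈ 6% at n = 41 but ≈ 2–3% at n = 101. Shorter bands therefore
cap flat-template accuracy in the low 90s no matter the implementation;
smooth-vs-linear is analogously hopeless when the fitted width approaches
the window length.

Degenerate inputs are errors with named exception types throughout: empty
masks, erosion that annihilates the mask, border-touching components,
collinear plane-fit regions, constant feature matrices, κ with equal
constant raters, zero-variance t-tests with unequal means. Component-area
ties break to the component whose lexicographically smallest (row, col)
pixel comes first.

## Limitations

- The descriptor list and the template family are explicit stand-ins for
  unavailable internals of the original clinical analysis; both are
  documented and config-extensible, and the experiments are designed to be
  meaningful for any reasonable choice.
- The radial signed distance degrades as contour perturbations grow; the
  generator rejects wounds whose excursions leave the frame but does not
  guard against self-overlapping normals at extreme amplitudes.
- Depth is treated as an ordinal relief map; no metric 3-D reconstruction
  or perspective correction is attempted.
- Rectification rows are not angularly registered across wounds, so
  per-row (angular) edge maps are out of scope; only whole-wound profile
  summaries feed the experiments.
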