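# Methods

## Measurement model

A study shares one triangulated template of N vertices; every head is a
configuration of those N corresponded points (mm). The pipeline applied to a
raw cohort is **center → symmetrize → GPA**:

1. **Size.** Centroid size is the mean vertex–centroid distance. The same
   measure is reported in mm and used to scale configurations to unit size,
   so "size" means one thing throughout (it differs from root-sum-of-squares
   centroid size only by a template-constant factor). Physical sizes are
   recorded before scaling, so size trajectories stay in mm even in a
   scale-free shape analysis.
2. **Symmetrization.** Each configuration is centered, reflected across the
   plane through its centroid normal to the template's declared symmetry
   axis, relabelled left↔right by the template pairing, and averaged with
   the original. Output is centered and exactly reflect–relabel symmetric;
   analysis then concerns the symmetric component of shape only. The plane
   through the centroid is the only canonical choice for centered data.
3. **Alignment.** Generalized Procrustes analysis aligns all configurations
   to an iteratively re-estimated consensus. Pairwise fits are robust:
   iteratively reweighted least squares with Gaussian weights
   w_v = exp(−r_v²/2σ²), σ = 1.4826·median(r), 10 iterations — a standard
   redescending-type scheme that discounts artefact-prone vertices. With
   zero residuals it reduces exactly to ordinary Procrustes; under i.i.d.
   noise it deviates from the least-squares fit at the noise scale, which is
   inherent to any robust estimator. With scaling on, configurations are
   fixed at unit size and only rotation/translation are optimized (sizes are
   then exactly 1); with scaling off, sizes pass through unchanged
   (size-and-shape analysis).

Two numerical choices make GPA deterministic. The new consensus is rigidly
re-anchored to the previous one each iteration: a global rotation is a
neutral direction of the robust update, and without anchoring the iteration
can slide indefinitely along the rotation orbit instead of converging. After
convergence the solution is rotated to the consensus principal axes (axes
ordered by decreasing variance, signs fixed by third moments, det +1), so
the output frame is a function of the data, not of input poses — aligned
coordinates are reproducible to ~1e−14 under arbitrary input similarity
transforms. Non-convergence after 100 iterations (consensus change ≥ 1e−8)
warns and flags the cohort.

Shape distance is the plain Euclidean (Frobenius) norm of the coordinate
difference in the common frame — the tangent-space approximation of
Procrustes distance, appropriate for the small shape variation of a single
aligned cohort; no re-superimposition per pair.

Vertex normals are area-weighted averages of incident face normals
(accumulated face cross products, then normalized); isolated vertices get a
zero normal and a warning, and downstream normal-displacement maps mark
them missing.

## Growth trajectories

The expected head (or size) of one group at age *a* is a kernel-weighted
linear fit evaluated at *a*. The kernel is Gaussian with standard deviation
equal to the "kernel width" h — consistent with influence that declines
smoothly, is dominated by cases within one width, and is near zero beyond
two widths (exp(−2) ≈ 0.135). With the single predictor age, weighted PLS
with one component coincides with weighted simple linear regression per
response coordinate; the closed form is implemented directly and the
equivalence to the textbook weighted slope is unit-tested. Predictor and
responses are centered at their weighted means before fitting (local-linear
rather than local-constant behaviour, which removes first-order boundary
bias at the edges of the sampled ages). The per-coordinate slopes form the
3D growth vector at each vertex (units per year); overall growth rate is
their mean length.

Defaults: width 2.75 y for shape, 0.75 y for size (the tuned values);
`n_components = 1`; age grids at 0.01-y steps for curves and range finding.
`tune_kernel_width` re-tunes per dataset: repeated random k-fold (k = 10,
10 repeats, seeded), scoring mean held-out Euclidean prediction error at
each candidate width, per group; widths whose training folds have an empty
evaluation range are marked invalid. The full error table is returned with
the winning width. On linear truth the criterion is flat-to-decreasing in
width, so wide kernels win; genuinely curved trajectories select narrower
widths — both behaviours are tested.

**Evaluation range.** At each grid age the ratio of kernel-weight sums of
strictly older to strictly younger cases (or its inverse) must stay at or
above a support threshold (default 0.4); the model is evaluated only on the
maximal contiguous interval satisfying this. This excludes edge-of-sample
ages where the local fit extrapolates; evaluating outside warns.
Predictions requested outside a range (e.g. scoring infants in
cross-validation) are clamped to the nearest in-range age and flagged.

## Two-group comparison

The dimorphism curve D(a) is the shape distance between the groups' expected
heads on an age grid (NaN with a warning where the grid leaves the
intersection of evaluation ranges). Significance: group labels are permuted
(group sizes preserved), both regressions refitted with the same kernel
width, and D* recomputed; p(a) = (1 + #{D* ≥ D}) / (1 + n_perm) — the
add-one estimator avoids p = 0. Since the two group predictions at a grid
age are linear in the responses, permutation refits are computed by
re-masking one precomputed kernel-weight matrix; this fast path is
unit-tested against the model-based curve. If fewer distinct label
assignments exist than requested permutations, the count is capped with a
warning. P-values are reported per age without multiplicity correction by
default (Benjamini–Hochberg is available to callers via statsmodels if
desired); the per-age permutation null is calibrated — type-I error at
α = 0.05 sits inside exact binomial bounds over hundreds of simulated null
cohorts. Confidence bands come from percentile bootstrap over cases
resampled with replacement *within* group (the comparison is conditional on
group membership); failed resamples are dropped with a warning and the
effective count reported.

Per-vertex maps: signed displacement of one expected head from the other
along the reference group's outward normals (positive = outward); signed
per-axis coordinate differences; growth-rate difference, by default the
difference of normal components (matching inward/outward growth maps), with
a vector-magnitude mode also exposed since overall rate curves use vector
lengths; and the angle in [0°, 180°] between the groups' growth vectors,
missing where either vector vanishes numerically. Morphs are linear
exaggerations ref + factor·(other − ref).

## Age-adaptive classification

A case is scored by projecting it onto the axis between the two groups'
expected heads at the case's own age, normalized by half the inter-head
distance: group means map to −1/+1 (labels sorted; first label → −1), the
midpoint to 0. The score is exactly linear along the axis and invariant to
components orthogonal to it; relabelling the groups negates it.

Repeated stratified k-fold cross-validation (defaults k = 10, 100
repetitions): folds are stratified by group × integer-year age bin (dealt
round-robin within each stratum after shuffling, so per-stratum fold counts
differ by ≤ 1; strata smaller than k are distributed with a warning).
Expected heads are refitted on the k−1 training folds for every held-out
case. Fold-level AUC (rank-based, ties = 1/2) and threshold-zero correct
rates (a score exactly at the threshold is incorrect) are aggregated in age
brackets [0,5), [5,10), [10,15), [15,20): mean plus 2.5/97.5 percentiles
over all repetitions × folds, with per-case mean scores retained for
score-distribution plots. The GPA is run once on the full cohort before CV,
mirroring a pipeline in which alignment precedes any analysis; alignment is
label-blind, so the induced leakage is negligible, but it is a known
property of this design.

## Synthetic cohorts

The generator stands in for restricted clinical imaging data. The template
is a triangulated ellipsoid (half-axes 70 × 85 × 95 mm — lateral, depth,
vertical) with exact left–right vertex pairing; group means are per-vertex
polynomials in age. The default growth field is radial with smooth spatial
modulation and gentle deceleration, X(a) = X₀ + a·V₁ − a²·V₂ with
V₁ = 0.03·g·X₀ and V₂ = 0.0006·g·X₀ (g ∈ [0.75, 1.25] varying over the
surface), i.e. ≈ 35% size growth from birth to 18 y with rates declining
into adolescence. Vertex noise is isotropic Gaussian, default sd = 2% of
template centroid size (≈ 1.7 mm — the scale of measurement error plus
residual individual variation); ages are uniform on [0.5, 18.5] y by
default, or drawn to per-year count weights. Nuisance pose is a random
similarity transform per case: rotations up to 20°, translations up to
50 mm, and *no* scale nuisance by default, since calibrated 3D
photogrammetry is metric — widen `scale_range` to stress scale removal.

Scenarios encode the distinct mechanisms by which two groups can diverge:
`null` (identical), `rate` (same directions, group B coefficients × 1.5),
`direction` (equal rates, growth vectors rotated 45° about a tangential
axis), `pubertal` (a ramp difference switching on at 12 y), and `separated`
(a constant offset of 10 noise sd, for classifier power checks). Means and
their age derivatives are available in closed form, so expected heads,
growth vectors, dimorphism curves and angle maps all have analytic truth.

What the generator does *not* emulate: anatomically realistic surfaces,
correlated (spatially smooth) measurement error, within-individual
(longitudinal) structure, maturation-rate heterogeneity, allometry, or
missing/artefactual regions. Passing tests therefore demonstrate the
statistical machinery — recovery, calibration, invariances — not robustness
to every property of real scan data.

## Verification sizes and numerical choices

End-to-end checks run at deliberately modest sizes chosen to make their own
sampling error small relative to what they assert: trajectory recovery on
400 cases/group (86-vertex template), permutation calibration on 600 null
cohorts of 60/group with 200 permutations at a fixed interior age,
classifier null behaviour averaged over three cohorts of 250/group (a
single cohort's mean CV AUC fluctuates with dataset sd ≈ 0.03, the order of
the assertion band itself), and brute-force oracles for AUC and the
evaluation range. The recovery bound is the analytic pointwise error of a
linear smoother — deterministic kernel-smoothing bias (the smoother applied
to the true mean function) plus noise variance — since at width 2.75 the
quadratic truth has a known bias that a variance-only bound would miss.

Degenerate inputs: all-coincident configurations are rejected in alignment;
identical (effectively weighted) ages make the local predictor singular and
raise; vanishing total kernel weight raises; coincident expected heads make
the classification score undefined and raise. Ties: AUC counts tied pairs
as 1/2; a score exactly at the classification threshold is incorrect;
the first-longest run wins when evaluation-range runs tie. Tolerances:
GPA consensus change < 1e−8 (max 100 iterations), unit sizes exact to
machine precision, angle maps mask vectors with norm < 1e−12.

## Limitations

Cross-sectional "growth" is the age-association of shape, not longitudinal
change; age only approximates maturation. No allometry adjustment is
offered: size is strongly correlated with age in growing cohorts, so
removing it would remove growth itself. Permutation p-values are per-age
and correlated across neighbouring ages. The bootstrap quantifies sampling
variability of the curves, not template or registration error. Tangent-space
shape distance assumes small shape variation; cohorts spanning very large
shape differences would need proper Procrustes distances.
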