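# shapegrowth

Growth-trajectory modelling, two-group comparison and age-adaptive
classification for dense 3D landmark configurations.

Many craniofacial disorders — and ordinary sexual dimorphism — manifest as
shape differences that *emerge and change* during childhood and adolescence.
Comparing a single pair of averaged faces from mixed-age samples hides this:
the same shape difference can arise from groups growing at different rates
along the same directions, or along different directions altogether.
`shapegrowth` models each group's craniofacial development as a continuous
"growth curve" through shape space and compares the curves directly, for
anyone working with cross-sectional cohorts of corresponded surface scans:
clinical researchers charting a dysmorphology, anthropologists studying
dimorphism, and methodologists building shape-based diagnostic scores.

## The model

Each head is measured as a fixed template of N corresponded vertices, so a
configuration is a point **x** ∈ ℝ³ᴺ in shape space. After symmetrization
and generalized Procrustes alignment (robust, optionally size-preserving),
the expected head of a group at target age *a* is a kernel-weighted linear
regression: each case *i* receives weight

    w_i = exp( −(a_i − a)² / (2h²) )

and a weighted linear partial least-squares regression of all point
coordinates onto age (with the single predictor age this is weighted simple
regression per coordinate) gives

    x̂(a) = β₀(a) + β₁(a)·a

* **Expected head**: x̂(a); expected size uses the same machinery on the
  scalar centroid size (mean vertex–centroid distance, mm).
* **Growth vectors**: β₁(a) reshaped to N × 3 — predicted displacement per
  year at each vertex; their mean length is the group's **growth rate**.
* **Dimorphism curve**: D(a) = ‖x̂_A(a) − x̂_B(a)‖, the Procrustes distance
  between expected heads, with permutation p-values (label permutation,
  same kernel width) and within-group bootstrap confidence bands.
* **Per-vertex maps**: signed differences along surface normals or
  coordinate axes, growth-rate differences, and the angle between the two
  groups' growth vectors.
* **Age-adaptive score**: a case **x** of age *a* is projected onto the axis
  between the age-appropriate expected heads and normalised so the group
  means sit at ±1:

      s(x) = ⟨x − (m₋+m₊)/2, u⟩ / (‖m₊−m₋‖/2),  u = (m₊−m₋)/‖m₊−m₋‖

  Performance is assessed by repeated stratified k-fold cross-validation
  with AUC and threshold-zero correct-classification rates per age bracket.

Fits are trusted only on the **evaluation range** — the ages where the
ratio of kernel-weight sums of older to younger cases (or its inverse)
stays above 0.4 — so local fits interpolate rather than extrapolate.
Kernel widths default to the tuned values 2.75 y (shape) and 0.75 y (size)
and can be re-tuned per dataset by repeated grid search.

## Worked example

Cohorts of real heads are rarely shareable, so the `synthetic` module
generates cross-sectional two-group cohorts on a toy ellipsoid "head" with
known growth. Here group B grows 1.5× faster than group A along the same
directions:

```python
import numpy as np
from shapegrowth import synthetic, trajectory, comparison, classify

spec = synthetic.scenario("rate", seed=1)           # B grows 1.5x faster
cohort, truth = synthetic.simulate_cohort(spec, 200, seed=2)

models = {g: trajectory.fit_trajectory(cohort, g, "shape", width=2.75)
          for g in ("A", "B")}
r = models["A"].eval_range
print(f"evaluation range: [{r.a_min:.2f}, {r.a_max:.2f}] years")

ages = np.array([4.0, 9.0, 14.0])
curve = comparison.dimorphism_curve(models["A"], models["B"], ages)
p = comparison.permutation_test(cohort, ages, trajectory.KernelSpec(2.75),
                                n_perm=999, seed=3)
for a, d, pv in zip(ages, curve, p):
    ra = trajectory.growth_rate(models["A"].growth_field_at(a, warn_outside=False))
    rb = trajectory.growth_rate(models["B"].growth_field_at(a, warn_outside=False))
    print(f"age {a:4.1f}: dimorphism {d:6.2f}  p={pv:.3f}  "
          f"rates A={ra:.2f} B={rb:.2f} mm/y  ratio {rb/ra:.2f}")

records = classify.repeated_cv(cohort, k=10, repetitions=5,
                               spec=trajectory.KernelSpec(2.75), seed=4)
report = classify.bracket_report(records)
print(report.metrics[["bracket", "auc_mean", "auc_lo", "auc_hi"]].to_string(index=False))
```

prints

```
evaluation range: [1.66, 17.19] years
age  4.0: dimorphism  44.00  p=0.001  rates A=2.05 B=3.08 mm/y  ratio 1.50
age  9.0: dimorphism  87.67  p=0.001  rates A=1.65 B=2.43 mm/y  ratio 1.48
age 14.0: dimorphism 120.94  p=0.001  rates A=1.19 B=1.84 mm/y  ratio 1.54
bracket  auc_mean  auc_lo  auc_hi
    0-5  0.838356    0.72     1.0
   5-10  1.000000    1.00     1.0
  10-15  1.000000    1.00     1.0
  15-20  1.000000    1.00     1.0
```

The recovered rate ratios sit at the generating truth of 1.5; the
dimorphism magnitude grows with age (the groups diverge) and is significant
at every age; classification is hardest for the youngest children, where
the accumulated difference is smallest — the same qualitative pattern seen
in real sex-difference cohorts.

For file-based workflows the same stages are exposed as a CLI
(`shapegrowth simulate | fit | tune | compare | classify`), reading PLY/OBJ
meshes whose vertex order defines correspondence plus an `id,age,group,path`
metadata CSV, and writing curves and per-vertex maps as CSV.

## Layout

```
src/shapegrowth/
  core.py        configurations, centroid size, symmetrization, robust GPA
  trajectory.py  kernel weights, weighted PLS, expected heads, growth fields
  comparison.py  dimorphism curve, permutation/bootstrap, per-vertex maps
  classify.py    projection score, stratified CV, AUC, bracket reports
  synthetic.py   toy templates and cohorts with analytic ground truth
  io.py, cli.py, config.py   formats, commands, run configuration
docs/methods.md  modelling assumptions, defaults and limitations
```
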