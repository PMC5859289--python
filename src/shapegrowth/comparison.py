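"""Two-group trajectory comparison and per-vertex difference maps.

The overall magnitude of the group difference at each age is the Procrustes
(shape-space Euclidean) distance between the two expected heads — the
*dimorphism curve*.  Its significance is assessed by permuting group labels
and refitting the regressions with the same kernel width; uncertainty by
resampling cases with replacement within each group.  Spatial detail comes
from per-vertex maps: signed displacement along the reference surface
normals or along a coordinate axis, growth-rate differences, and the angle
between the two groups' growth vectors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import Cohort, TemplateTopology, as_configuration, vertex_normals
from .trajectory import (
    GrowthField,
    KernelSpec,
    TrajectoryModel,
    expected_at,
    fit_trajectory,
    kernel_weights,
)

__all__ = [
    "ComparisonResult",
    "BootstrapCI",
    "dimorphism_curve",
    "permutation_test",
    "bootstrap_ci",
    "normal_displacement_map",
    "axis_displacement_map",
    "rate_difference_map",
    "direction_angle_map",
    "morph",
]


@dataclass
class ComparisonResult:
    """Assembled two-group comparison over an age grid."""

    ages: np.ndarray
    magnitude: np.ndarray
    p_values: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    rate_a: np.ndarray | None = None
    rate_b: np.ndarray | None = None
    maps: dict | None = None


def _restrict(model_a: TrajectoryModel, model_b: TrajectoryModel, ages) -> np.ndarray:
    """Mask of grid ages inside both evaluation ranges (warn if restricted)."""
    ages = np.asarray(ages, dtype=float)
    ok = np.ones(ages.size, dtype=bool)
    for m in (model_a, model_b):
        if m.eval_range is not None:
            ok &= (ages >= m.eval_range.a_min) & (ages <= m.eval_range.a_max)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} of {ages.size} grid ages fall outside the "
            "models' common evaluation range; values there are NaN",
            RuntimeWarning,
        )
    return ok


def dimorphism_curve(model_a: TrajectoryModel, model_b: TrajectoryModel, ages) -> np.ndarray:
    """Shape distance between the two expected heads at each grid age.

    Ages outside the intersection of the two evaluation ranges yield NaN
    (with a warning), keeping the output aligned with the input grid.
    """
    ages = np.asarray(ages, dtype=float)
    ok = _restrict(model_a, model_b, ages)
    out = np.full(ages.size, np.nan)
    for i, a in enumerate(ages):
        if ok[i]:
            xa = expected_at(model_a, float(a), warn_outside=False)
            xb = expected_at(model_b, float(a), warn_outside=False)
            out[i] = np.linalg.norm(xa - xb)
    return out


def _group_curves(flat: np.ndarray, ages: np.ndarray, w: np.ndarray,
                  mask_a: np.ndarray, mask_b: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Distance between local-linear group predictions at each grid age.

    ``w`` is the (n_grid, n_cases) kernel-weight matrix; the prediction of a
    group at grid age ``a_j`` is written as a linear combination of that
    group's responses, so permutation refits reduce to re-masking.
    """
    d = np.empty(grid.size)
    for j in range(grid.size):
        preds = []
        for mask in (mask_a, mask_b):
            wj = w[j] * mask
            s0 = wj.sum()
            abar = (wj * ages).sum() / s0
            ac = ages - abar
            sxx = (wj * ac**2).sum()
            c = wj / s0 + wj * ac * (grid[j] - abar) / sxx
            preds.append(c @ flat)
        d[j] = np.linalg.norm(preds[0] - preds[1])
    return d


def permutation_test(
    cohort: Cohort,
    ages,
    spec: KernelSpec,
    n_perm: int = 10000,
    seed: int = 0,
    adjust: str | None = None,
) -> np.ndarray:
    """Permutation p-values for the dimorphism magnitude at each grid age.

    Group labels are permuted (group sizes preserved), the two regressions
    refitted with the same kernel width, and the distance between expected
    heads recomputed; ``p = (1 + #{D* >= D}) / (1 + n_perm)`` per age.
    P-values are per-age by default; ``adjust='bh'`` applies a
    Benjamini–Hochberg correction across the grid ages.
    """
    if adjust not in (None, "bh"):
        raise ValueError("adjust must be None or 'bh'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    grid = np.asarray(ages, dtype=float)
    lab_a, lab_b = cohort.labels
    flat = cohort.coords.reshape(cohort.n_cases, -1)
    w = np.exp(-((cohort.ages[None, :] - grid[:, None]) ** 2) / (2.0 * spec.width**2))
    n_a = int((cohort.groups == lab_a).sum())
    n_distinct = math.comb(cohort.n_cases, n_a)
    if n_perm > n_distinct:
        warnings.warn(
            f"only {n_distinct} distinct label permutations exist; capping n_perm",
            RuntimeWarning,
        )
        n_perm = n_distinct
    observed = _group_curves(flat, cohort.ages, w, cohort.groups == lab_a,
                             cohort.groups == lab_b, grid)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(grid.size)
    for _ in range(n_perm):
        perm = rng.permutation(cohort.groups)
        d = _group_curves(flat, cohort.ages, w, perm == lab_a, perm == lab_b, grid)
        exceed += d >= observed
    p = (1.0 + exceed) / (1.0 + n_perm)
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
    return p


@dataclass(frozen=True)
class BootstrapCI:
    low: np.ndarray
    high: np.ndarray
    n_effective: int


def bootstrap_ci(
    cohort: Cohort,
    estimator: Callable[[Cohort], np.ndarray],
    n_boot: int = 10000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap interval of a curve estimator.

    Cases are resampled with replacement *within* each group (group sizes
    preserved — the comparison is conditional on group membership).
    Resamples on which the estimator fails are dropped with a warning and
    the effective count reported.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    lab_a, lab_b = cohort.labels
    idx_a = np.flatnonzero(cohort.groups == lab_a)
    idx_b = np.flatnonzero(cohort.groups == lab_b)
    draws = []
    failures = 0
    for _ in range(n_boot):
        take = np.concatenate([rng.choice(idx_a, idx_a.size, replace=True),
                               rng.choice(idx_b, idx_b.size, replace=True)])
        # resampling duplicates ids; relabel to keep the cohort valid
        resample = Cohort(
            coords=cohort.coords[take],
            ages=cohort.ages[take],
            groups=cohort.groups[take],
            sizes=cohort.sizes[take],
            ids=[f"b{i}" for i in range(take.size)],
            aligned=cohort.aligned,
            scaled=cohort.scaled,
        )
        try:
            draws.append(np.asarray(estimator(resample), dtype=float))
        except (ValueError, FloatingPointError):
            failures += 1
    if failures:
        warnings.warn(
            f"estimator failed on {failures} of {n_boot} bootstrap resamples",
            RuntimeWarning,
        )
    if len(draws) < 2:
        raise ValueError("fewer than two successful bootstrap resamples")
    stack = np.stack(draws)
    alpha = (1.0 - level) / 2.0
    low = np.nanpercentile(stack, 100 * alpha, axis=0)
    high = np.nanpercentile(stack, 100 * (1 - alpha), axis=0)
    return BootstrapCI(low=low, high=high, n_effective=len(draws))


# ---------------------------------------------------------------------------
# per-vertex maps
# ---------------------------------------------------------------------------

def normal_displacement_map(ref, other, topo: TemplateTopology) -> np.ndarray:
    """Signed displacement of ``other`` relative to ``ref`` along ref's normals.

    Positive values are outward of the reference surface, negative inward.
    Vertices with a zero reference normal yield NaN.
    """
    ref = as_configuration(ref, topo.n_vertices)
    other = as_configuration(other, topo.n_vertices)
    normals = vertex_normals(ref, topo)
    out = np.einsum("ij,ij->i", other - ref, normals)
    zero = np.linalg.norm(normals, axis=1) < 0.5  # unit rows or exact zeros
    out[zero] = np.nan
    return out


def axis_displacement_map(ref, other, axis: str) -> np.ndarray:
    """Signed per-vertex coordinate difference ``other - ref`` along one axis."""
    from .core import AXES

    if axis not in AXES:
        raise ValueError(f"axis must be one of {sorted(AXES)}")
    ref = as_configuration(ref)
    other = as_configuration(other, ref.shape[0])
    return (other - ref)[:, AXES[axis]]


def rate_difference_map(
    field_a: GrowthField,
    field_b: GrowthField,
    normals: np.ndarray,
    mode: str = "normal",
) -> np.ndarray:
    """Per-vertex growth-rate difference (group A minus group B).

    ``mode='normal'`` (default) compares the components of the two growth
    fields along the supplied surface normals — the inward/outward rate of
    change; ``mode='magnitude'`` compares the vector lengths.  Positive
    values mean group A changes faster.
    """
    va, vb = field_a.vectors, field_b.vectors
    if va.shape != vb.shape:
        raise ValueError("growth fields must share the template")
    if mode == "normal":
        normals = np.asarray(normals, dtype=float)
        return np.einsum("ij,ij->i", va, normals) - np.einsum("ij,ij->i", vb, normals)
    if mode == "magnitude":
        return np.linalg.norm(va, axis=1) - np.linalg.norm(vb, axis=1)
    raise ValueError("mode must be 'normal' or 'magnitude'")


def direction_angle_map(field_a: GrowthField, field_b: GrowthField,
                        tol: float = 1e-12) -> np.ndarray:
    """Angle (degrees, in [0, 180]) between the groups' growth vectors per vertex.

    0 means the vectors point the same way, 180 opposite ways; vertices where
    either vector is (numerically) zero yield NaN.
    """
    va, vb = field_a.vectors, field_b.vectors
    if va.shape != vb.shape:
        raise ValueError("growth fields must share the template")
    na = np.linalg.norm(va, axis=1)
    nb = np.linalg.norm(vb, axis=1)
    ok = (na > tol) & (nb > tol)
    out = np.full(va.shape[0], np.nan)
    cosang = np.einsum("ij,ij->i", va[ok], vb[ok]) / (na[ok] * nb[ok])
    out[ok] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return out


def morph(ref, other, factor: float) -> np.ndarray:
    """Exaggeration morph ``ref + factor * (other - ref)``.

    ``factor`` 0 returns the reference, 1 the other configuration, and values
    beyond 1 exaggerate the difference for visualization.
    """
    ref = as_configuration(ref)
    other = as_configuration(other, ref.shape[0])
    return ref + factor * (other - ref)


def compare_trajectories(
    cohort: Cohort,
    ages,
    width: float,
    n_perm: int = 10000,
    n_boot: int = 10000,
    seed: int = 0,
    support_threshold: float = 0.4,
) -> ComparisonResult:
    """Fit both groups and assemble the full comparison over an age grid."""
    from .trajectory import growth_field_at, growth_rate

    grid = np.asarray(ages, dtype=float)
    lab_a, lab_b = cohort.labels
    model_a = fit_trajectory(cohort, lab_a, "shape", width, support_threshold)
    model_b = fit_trajectory(cohort, lab_b, "shape", width, support_threshold)
    mag = dimorphism_curve(model_a, model_b, grid)
    ok = np.isfinite(mag)
    p = np.full(grid.size, np.nan)
    if n_perm:
        p[ok] = permutation_test(cohort, grid[ok], KernelSpec(width), n_perm, seed)
    lo = np.full(grid.size, np.nan)
    hi = np.full(grid.size, np.nan)
    if n_boot:
        def estimator(c: Cohort) -> np.ndarray:
            ma = fit_trajectory(c, lab_a, "shape", width, support_threshold)
            mb = fit_trajectory(c, lab_b, "shape", width, support_threshold)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                return dimorphism_curve(ma, mb, grid[ok])

        ci = bootstrap_ci(cohort, estimator, n_boot, 0.95, seed + 1)
        lo[ok], hi[ok] = ci.low, ci.high
    rate_a = np.full(grid.size, np.nan)
    rate_b = np.full(grid.size, np.nan)
    for i in np.flatnonzero(ok):
        rate_a[i] = growth_rate(growth_field_at(model_a, float(grid[i]), warn_outside=False))
        rate_b[i] = growth_rate(growth_field_at(model_b, float(grid[i]), warn_outside=False))
    return ComparisonResult(
        ages=grid, magnitude=mag, p_values=p, ci_low=lo, ci_high=hi,
        rate_a=rate_a, rate_b=rate_b,
    )
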