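"""Kernel-regression growth trajectories of shape and size.

The growth curve of one group is modelled non-parametrically: to evaluate the
curve at a target age ``a``, every case is weighted by a Gaussian kernel in
age distance, ``w_i = exp(-(a_i - a)^2 / (2 h^2))``, and a weighted linear
partial least-squares regression of the responses (all flattened point
coordinates, or scalar size) onto age is fitted.  The prediction at ``a`` is
the *expected head* (or expected size); the per-coordinate regression slopes
form a 3D *growth vector* at each vertex — the predicted change per year —
and their mean length is the group's overall *growth rate* at that age.

With the single predictor age and one PLS component, the weighted PLS fit
coincides exactly with weighted simple linear regression per response
dimension; that closed form is used here (and unit-tested against the
textbook weighted-slope formula).

A local fit is only interpolation where the kernel has support on both sides
of the target age: the model's *evaluation range* is the maximal contiguous
age interval on which the ratio of kernel-weight sums of older to younger
cases (or its inverse) stays above a support threshold (default 0.4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Cohort

__all__ = [
    "DEFAULT_SHAPE_WIDTH",
    "DEFAULT_SIZE_WIDTH",
    "KernelSpec",
    "EvaluationRange",
    "GrowthField",
    "TrajectoryModel",
    "KernelTuningResult",
    "kernel_weights",
    "weighted_pls_fit",
    "fit_trajectory",
    "expected_at",
    "growth_field_at",
    "growth_rate",
    "evaluation_range",
    "tune_kernel_width",
]

#: Tuned kernel widths (years) for shape and size regressions.
DEFAULT_SHAPE_WIDTH = 2.75
DEFAULT_SIZE_WIDTH = 0.75

#: Age-grid step (years) for curves and range finding.
AGE_GRID_STEP = 0.01


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian age kernel; ``width`` (years) is its standard deviation.

    Cases within one width of the target age dominate the fit; beyond two
    widths the weight ``exp(-2) ~ 0.135`` and below is close to negligible.
    """

    width: float

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise ValueError("kernel width must be positive")


@dataclass(frozen=True)
class EvaluationRange:
    """Age interval on which a trajectory model interpolates rather than extrapolates."""

    a_min: float
    a_max: float
    support_threshold: float = 0.4

    def __post_init__(self) -> None:
        if not (self.a_min < self.a_max):
            raise ValueError("a_min must be below a_max")

    def contains(self, a: float) -> bool:
        return self.a_min <= a <= self.a_max

    def clip(self, a: float) -> float:
        return float(min(max(a, self.a_min), self.a_max))


@dataclass(frozen=True)
class GrowthField:
    """Per-vertex 3D growth vectors (units per year) at one age."""

    vectors: np.ndarray
    age: float

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or not np.all(np.isfinite(v)):
            raise ValueError("growth field must be a finite (n_vertices, 3) array")
        object.__setattr__(self, "vectors", v)


def kernel_weights(ages, a: float, spec: KernelSpec) -> np.ndarray:
    """Gaussian kernel weights of each case for target age ``a``."""
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("empty age list")
    return np.exp(-((ages - a) ** 2) / (2.0 * spec.width**2))


def weighted_pls_fit(responses, ages, weights, n_components: int = 1):
    """Weighted linear PLS of responses on the single predictor age.

    Predictor and responses are centered at their weighted means before
    fitting and the intercept restored, so the local fit behaves like a
    local-linear (not local-constant) smoother at the edges of the kernel.

    Returns ``(intercept, coefficients)``, each of length ``d`` (one entry
    per response dimension); the prediction at age ``a`` is
    ``intercept + coefficients * a`` and the coefficients are the change per
    year.  With one predictor the PLS score space is one-dimensional, so any
    ``n_components >= 1`` yields the same (weighted least-squares) fit.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    y = np.asarray(responses, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    a = np.asarray(ages, dtype=float)
    w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    if not (wsum > 0) or not np.isfinite(wsum):
        raise ValueError("total kernel weight is not positive")
    abar = float((w * a).sum() / wsum)
    ybar = (w[:, None] * y).sum(axis=0) / wsum
    ac = a - abar
    sxx = float((w * ac**2).sum())
    if sxx <= 1e-12 * max(wsum, 1.0) * max(float(np.var(a)), 1e-30) or sxx == 0.0:
        raise ValueError("singular predictor: all (effectively weighted) ages identical")
    coef = (w * ac) @ (y - ybar) / sxx
    intercept = ybar - coef * abar
    return intercept, coef


@dataclass
class TrajectoryModel:
    """One group's kernel-regression growth curve.

    ``responses`` is ``(n_cases, d)``: flattened aligned coordinates
    (``d = 3 * n_vertices``) for ``response_kind='shape'``, or recorded
    physical sizes (``d = 1``) for ``response_kind='size'``.
    """

    ages: np.ndarray
    responses: np.ndarray
    kernel: KernelSpec
    response_kind: str = "shape"
    n_components: int = 1
    n_vertices: int | None = None
    eval_range: EvaluationRange | None = None

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim == 1:
            self.responses = self.responses[:, None]
        if self.ages.size == 0:
            raise ValueError("empty training set")
        if self.response_kind not in ("shape", "size"):
            raise ValueError("response_kind must be 'shape' or 'size'")
        if self.response_kind == "shape":
            if self.n_vertices is None:
                if self.responses.shape[1] % 3:
                    raise ValueError("shape responses must have 3*n_vertices columns")
                self.n_vertices = self.responses.shape[1] // 3

    # convenience method forms
    def expected_at(self, a: float, warn_outside: bool = True):
        return expected_at(self, a, warn_outside=warn_outside)

    def growth_field_at(self, a: float, warn_outside: bool = True) -> GrowthField:
        return growth_field_at(self, a, warn_outside=warn_outside)


def fit_trajectory(
    cohort: Cohort,
    group,
    response_kind: str = "shape",
    width: float | None = None,
    support_threshold: float = 0.4,
    n_components: int = 1,
) -> TrajectoryModel:
    """Build one group's trajectory model from an aligned cohort.

    ``width`` defaults to the tuned values 2.75 y (shape) / 0.75 y (size).
    Shape responses are the flattened aligned coordinates; size responses are
    the recorded physical sizes (mm), so size curves stay in mm even for
    unit-scaled shape cohorts.
    """
    mask = cohort.group_mask(group)
    if not mask.any():
        raise ValueError(f"no cases with group label {group!r}")
    ages = cohort.ages[mask]
    if response_kind == "shape":
        if not cohort.aligned:
            warnings.warn("fitting shape trajectory on an unaligned cohort", RuntimeWarning)
        responses = cohort.coords[mask].reshape(mask.sum(), -1)
        nv = cohort.n_vertices
    elif response_kind == "size":
        responses = cohort.sizes[mask][:, None]
        nv = None
    else:
        raise ValueError("response_kind must be 'shape' or 'size'")
    spec = KernelSpec(width if width is not None else
                      (DEFAULT_SHAPE_WIDTH if response_kind == "shape" else DEFAULT_SIZE_WIDTH))
    rng = evaluation_range(ages, spec, support_threshold)
    return TrajectoryModel(
        ages=ages,
        responses=responses,
        kernel=spec,
        response_kind=response_kind,
        n_components=n_components,
        n_vertices=nv,
        eval_range=rng,
    )


def _local_fit(model: TrajectoryModel, a: float, warn_outside: bool):
    if warn_outside and model.eval_range is not None and not model.eval_range.contains(a):
        warnings.warn(
            f"age {a:.3g} outside evaluation range "
            f"[{model.eval_range.a_min:.3g}, {model.eval_range.a_max:.3g}]; "
            "prediction is an extrapolation",
            RuntimeWarning,
        )
    w = kernel_weights(model.ages, a, model.kernel)
    if w.sum() < 1e-300:
        raise ValueError(f"total kernel weight vanishes at age {a}")
    return weighted_pls_fit(model.responses, model.ages, w, model.n_components)


def expected_at(model: TrajectoryModel, a: float, warn_outside: bool = True):
    """Expected head (``(N, 3)`` array) or expected size (float) at age ``a``."""
    intercept, coef = _local_fit(model, a, warn_outside)
    pred = intercept + coef * a
    if model.response_kind == "shape":
        return pred.reshape(model.n_vertices, 3)
    return float(pred[0])


def growth_field_at(model: TrajectoryModel, a: float, warn_outside: bool = True) -> GrowthField:
    """Per-vertex growth vectors (change per year) of a shape model at age ``a``."""
    if model.response_kind != "shape":
        raise ValueError("growth fields are defined for shape models only")
    _, coef = _local_fit(model, a, warn_outside)
    return GrowthField(vectors=coef.reshape(model.n_vertices, 3), age=float(a))


def growth_rate(field: GrowthField) -> float:
    """Overall growth rate: mean length of the growth vectors over vertices."""
    return float(np.linalg.norm(field.vectors, axis=1).mean())


def age_grid(a_min: float, a_max: float, step: float = AGE_GRID_STEP) -> np.ndarray:
    """Regular age grid ``a_min, a_min + step, ...`` covering ``[a_min, a_max]``."""
    m = int(np.floor((a_max - a_min) / step + 1e-9))
    return a_min + step * np.arange(m + 1)


def evaluation_range(
    ages,
    spec: KernelSpec,
    threshold: float = 0.4,
    step: float = AGE_GRID_STEP,
) -> EvaluationRange:
    """Maximal contiguous age interval with balanced kernel support.

    At each grid age ``a`` (step 0.01 y over the observed range) the ratio
    ``min(S_older / S_younger, S_younger / S_older)`` of kernel-weight sums
    over cases strictly older/younger than ``a`` must reach ``threshold``.
    """
    ages = np.asarray(ages, dtype=float)
    if np.unique(ages).size < 2:
        raise ValueError("need at least two distinct ages")
    grid = age_grid(float(ages.min()), float(ages.max()), step)
    w = np.exp(-((ages[None, :] - grid[:, None]) ** 2) / (2.0 * spec.width**2))
    older = ages[None, :] > grid[:, None]
    younger = ages[None, :] < grid[:, None]
    s_old = (w * older).sum(axis=1)
    s_young = (w * younger).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.minimum(s_old / s_young, s_young / s_old)
    ratio[(s_old <= 0) | (s_young <= 0)] = 0.0
    ok = ratio >= threshold
    if not ok.any():
        raise ValueError("no age satisfies the kernel-support criterion")
    # longest contiguous run of True
    idx = np.flatnonzero(ok)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    best = int(np.argmax(ends - starts))
    i0, i1 = idx[starts[best]], idx[ends[best]]
    return EvaluationRange(float(grid[i0]), float(grid[i1]), threshold)


@dataclass
class KernelTuningResult:
    """Outcome of the repeated grid search over kernel widths."""

    best_width: float
    table: pd.DataFrame  # columns: width, mean_error, valid

    def __float__(self) -> float:
        return self.best_width


def tune_kernel_width(
    cohort: Cohort,
    grid,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    response_kind: str = "shape",
    support_threshold: float = 0.4,
) -> KernelTuningResult:
    """Repeated k-fold grid search for the kernel width.

    For each candidate width, each group's trajectory is refitted on the
    training folds and every held-out case's response predicted at its age
    (clipped into the training evaluation range); the score is the mean
    Euclidean distance between held-out response and prediction over
    ``repeats`` random k-fold splits.  Widths whose evaluation range is empty
    on some training split are marked invalid.
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("empty width grid")
    rng = np.random.default_rng(seed)
    n = cohort.n_cases
    splits = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        splits.append(np.array_split(perm, k))
    rows = []
    for width in grid:
        errors: list[float] = []
        valid = True
        for folds in splits:
            if not valid:
                break
            for test_idx in folds:
                train_idx = np.setdiff1d(np.arange(n), test_idx)
                train = cohort.subset(train_idx)
                try:
                    models = {
                        g: fit_trajectory(train, g, response_kind, width, support_threshold)
                        for g in cohort.labels
                    }
                except ValueError:
                    valid = False
                    break
                for i in test_idx:
                    m = models[cohort.groups[i]]
                    a_eff = m.eval_range.clip(cohort.ages[i])
                    pred = expected_at(m, a_eff, warn_outside=False)
                    if response_kind == "shape":
                        obs = cohort.coords[i]
                        errors.append(float(np.linalg.norm(obs - pred)))
                    else:
                        errors.append(abs(float(cohort.sizes[i]) - pred))
        rows.append(
            {"width": width, "mean_error": float(np.mean(errors)) if valid else np.inf,
             "valid": valid}
        )
    table = pd.DataFrame(rows)
    if not table["valid"].any():
        raise ValueError("no candidate width has a non-empty evaluation range")
    best = float(table.loc[table["mean_error"].idxmin(), "width"])
    return KernelTuningResult(best_width=best, table=table)
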