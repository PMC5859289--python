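"""Dense landmark configurations: size, symmetry, robust Procrustes alignment.

A *configuration* is an ``(n_vertices, 3)`` float array of point coordinates
in fixed correspondence with a template mesh.  All configurations in a study
share one :class:`TemplateTopology`, so a configuration can equally be read
as a single point in a ``3 * n_vertices``-dimensional shape space.

The module provides the measurement primitives of a spatially dense
morphometric pipeline:

* :func:`centroid_size` — scalar size, the mean vertex distance from the
  centroid (in mm for raw data),
* :func:`symmetrize` — averaging a configuration with its reflected,
  left/right-relabelled copy, isolating the symmetric component of shape,
* :func:`robust_align` / :func:`ordinary_align` — pairwise (robust)
  Procrustes superimposition,
* :func:`gpa` — generalized Procrustes alignment of a whole cohort to an
  iteratively refined consensus,
* :func:`shape_distance` — Euclidean (Procrustes) distance between aligned
  configurations,
* :func:`vertex_normals` — outward per-vertex surface normals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AXES",
    "TemplateTopology",
    "Cohort",
    "as_configuration",
    "centroid_size",
    "symmetrize",
    "ordinary_align",
    "robust_align",
    "gpa",
    "shape_distance",
    "vertex_normals",
]

AXES = {"x": 0, "y": 1, "z": 2}


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateTopology:
    """Fixed template defining correspondence for every configuration.

    Parameters
    ----------
    n_vertices : int
        Number of template vertices.
    faces : (F, 3) int array
        Triangles as vertex-index triples (0-based).
    symmetry_pairs : (P, 2) int array
        Bilateral (left, right) vertex-index pairs.
    midline_vertices : (M,) int array
        Vertices lying on the sagittal midline (self-paired).
    reflection_axis : {"x", "y", "z"}
        Coordinate axis normal to the symmetry plane.
    """

    n_vertices: int
    faces: np.ndarray
    symmetry_pairs: np.ndarray
    midline_vertices: np.ndarray
    reflection_axis: str = "x"

    def __post_init__(self) -> None:
        object.__setattr__(self, "faces", np.asarray(self.faces, dtype=np.int64).reshape(-1, 3))
        object.__setattr__(
            self, "symmetry_pairs", np.asarray(self.symmetry_pairs, dtype=np.int64).reshape(-1, 2)
        )
        object.__setattr__(
            self, "midline_vertices", np.asarray(self.midline_vertices, dtype=np.int64).reshape(-1)
        )
        if self.n_vertices < 1:
            raise ValueError("template needs at least one vertex")
        if self.reflection_axis not in AXES:
            raise ValueError(f"reflection_axis must be one of {sorted(AXES)}")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise ValueError("face indices out of range")
        for tri in self.faces:
            if len(set(tri.tolist())) != 3:
                raise ValueError(f"degenerate face {tri.tolist()}")
        counts = np.zeros(self.n_vertices, dtype=int)
        for i, j in self.symmetry_pairs:
            counts[i] += 1
            counts[j] += 1
        counts[self.midline_vertices] += 1
        if not np.all(counts == 1):
            bad = np.flatnonzero(counts != 1)
            raise ValueError(
                f"each vertex must appear in exactly one symmetry pair or the midline; "
                f"offending vertices: {bad[:10].tolist()}"
            )

    @property
    def reflection_dim(self) -> int:
        return AXES[self.reflection_axis]

    def relabel_permutation(self) -> np.ndarray:
        """Permutation swapping left and right vertices (midline fixed)."""
        perm = np.arange(self.n_vertices)
        left, right = self.symmetry_pairs[:, 0], self.symmetry_pairs[:, 1]
        perm[left] = right
        perm[right] = left
        return perm


def as_configuration(coords, n_vertices: int | None = None) -> np.ndarray:
    """Validate and return coordinates as a float ``(N, 3)`` array."""
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"configuration must be (N, 3), got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("configuration contains non-finite coordinates")
    if n_vertices is not None and x.shape[0] != n_vertices:
        raise ValueError(f"expected {n_vertices} vertices, got {x.shape[0]}")
    return x


@dataclass
class Cohort:
    """A cross-sectional sample of corresponded configurations.

    ``coords`` stacks all configurations as ``(n_cases, n_vertices, 3)``.
    ``sizes`` records each head's physical centroid size (mm) *before* any
    unit-size scaling, so size trajectories stay in physical units even when
    the shape analysis is scale-free.
    """

    coords: np.ndarray
    ages: np.ndarray
    groups: np.ndarray
    sizes: np.ndarray
    ids: list[str]
    aligned: bool = False
    scaled: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        self.groups = np.asarray(self.groups)
        self.sizes = np.asarray(self.sizes, dtype=float)
        n = self.coords.shape[0]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_cases, n_vertices, 3)")
        if not (len(self.ages) == len(self.groups) == len(self.sizes) == len(self.ids) == n):
            raise ValueError("cohort fields must have equal length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in cohort")
        if np.any(self.ages <= 0):
            raise ValueError("ages must be positive")
        if len(np.unique(self.groups)) != 2:
            raise ValueError("cohort must contain exactly two distinct group labels")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate case ids in cohort")

    @property
    def n_cases(self) -> int:
        return self.coords.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[1]

    @property
    def labels(self) -> tuple:
        """The two group labels, sorted."""
        u = sorted(np.unique(self.groups).tolist())
        return tuple(u)

    def group_mask(self, label) -> np.ndarray:
        return self.groups == label

    def subset(self, idx) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort(
            coords=self.coords[idx],
            ages=self.ages[idx],
            groups=self.groups[idx],
            sizes=self.sizes[idx],
            ids=[self.ids[i] for i in np.atleast_1d(idx)],
            aligned=self.aligned,
            scaled=self.scaled,
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# size and symmetry
# ---------------------------------------------------------------------------

def centroid_size(config) -> float:
    """Mean Euclidean distance of the vertices from their centroid.

    This is the study's size measure (mm on raw data).  It differs from the
    classical root-sum-of-squares centroid size only by a template-constant
    factor, and it is the measure used to scale configurations to unit size.
    """
    x = as_configuration(config)
    if x.shape[0] < 2:
        raise ValueError("centroid size needs at least two vertices")
    c = x.mean(axis=0)
    return float(np.linalg.norm(x - c, axis=1).mean())


def reflect_relabel(config, topo: TemplateTopology) -> np.ndarray:
    """Mirror a *centered* configuration and swap left/right labels."""
    x = as_configuration(config, topo.n_vertices).copy()
    x[:, topo.reflection_dim] *= -1.0
    return x[topo.relabel_permutation()]

def symmetrize(config, topo: TemplateTopology) -> np.ndarray:
    """Symmetric component of a configuration.

    The configuration is centered, reflected across the plane through the
    centroid normal to the template's reflection axis, relabelled so left and
    right vertices swap, and averaged with the original.  The returned
    configuration is centered and exactly invariant under reflect-and-relabel.
    """
    x = as_configuration(config, topo.n_vertices)
    xc = x - x.mean(axis=0)
    return 0.5 * (xc + reflect_relabel(xc, topo))


# ---------------------------------------------------------------------------
# Procrustes superimposition
# ---------------------------------------------------------------------------

def _weighted_superimpose(source, target, w, allow_scale):
    """Weighted least-squares similarity (or rigid) fit of source onto target.

    Returns (aligned, rotation, scale, translation) with the convention
    ``aligned = scale * source @ R + t`` and ``det(R) = +1``.
    """
    w = np.asarray(w, dtype=float)
    wsum = w.sum()
    sbar = (w[:, None] * source).sum(axis=0) / wsum
    tbar = (w[:, None] * target).sum(axis=0) / wsum
    s0 = source - sbar
    t0 = target - tbar
    h = (w[:, None] * s0).T @ t0
    u, sig, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    dvec = np.array([1.0, 1.0, d])
    rot = (u * dvec) @ vt
    denom = float((w[:, None] * s0 * s0).sum())
    if denom < 1e-300:
        raise ValueError("degenerate (all-coincident) source configuration")
    scale = float((sig * dvec).sum() / denom) if allow_scale else 1.0
    t = tbar - scale * sbar @ rot
    aligned = scale * source @ rot + t
    return aligned, rot, scale, t


def ordinary_align(source, target, allow_scale: bool = False):
    """Ordinary least-squares Procrustes superimposition of source onto target."""
    source = as_configuration(source)
    target = as_configuration(target, source.shape[0])
    w = np.ones(source.shape[0])
    aligned, rot, scale, t = _weighted_superimpose(source, target, w, allow_scale)
    return aligned, {"rotation": rot, "scale": scale, "translation": t}


def robust_align(source, target, allow_scale: bool = False, n_iter: int = 10):
    """Robust Procrustes superimposition by iteratively reweighted least squares.

    Vertex weights are Gaussian in the residual, ``w_v = exp(-r_v^2 / (2
    sigma^2))`` with ``sigma = 1.4826 * median(r)`` (the normal-consistent MAD
    scale), so vertices far off the fit — e.g. artefactual regions — lose
    influence.  On outlier-free data the result coincides with the ordinary
    least-squares superimposition to numerical precision.
    """
    source = as_configuration(source)
    target = as_configuration(target, source.shape[0])
    n = source.shape[0]
    w = np.ones(n)
    aligned, rot, scale, t = _weighted_superimpose(source, target, w, allow_scale)
    for _ in range(n_iter):
        r = np.linalg.norm(aligned - target, axis=1)
        sigma = 1.4826 * np.median(r)
        if sigma < 1e-12 * max(1.0, float(np.abs(target).max())):
            break  # essentially a perfect fit
        w = np.exp(-(r**2) / (2.0 * sigma**2))
        aligned, rot, scale, t = _weighted_superimpose(source, target, w, allow_scale)
    return aligned, {"rotation": rot, "scale": scale, "translation": t, "weights": w}


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Rotation taking a centered consensus to its principal-axes frame.

    Axes are ordered by decreasing variance; signs are fixed by the third
    moment along each axis (det kept +1), making the GPA output frame a
    deterministic function of the data rather than of the input orientations.
    """
    _, _, vt = np.linalg.svd(consensus, full_matrices=False)
    r = vt.T
    y = consensus @ r
    for k in (0, 1):
        if (y[:, k] ** 3).sum() < 0:
            r[:, k] *= -1.0
    if np.linalg.det(r) < 0:
        r[:, 2] *= -1.0
    return r


def gpa(
    cohort: Cohort,
    scale: bool = True,
    robust: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[Cohort, np.ndarray]:
    """Generalized Procrustes alignment of a cohort to an evolving consensus.

    Each configuration is centered and, if ``scale``, divided by its centroid
    size; configurations are then rigidly aligned to the consensus (robust
    IRLS fit by default), the consensus re-estimated as their mean, and the
    loop repeated until the consensus moves less than ``tol`` (Frobenius) or
    ``max_iter`` is reached.  The converged solution is rotated into the
    consensus principal-axes frame so the output is invariant to arbitrary
    similarity transforms of the inputs.

    Returns the aligned cohort (``aligned=True``, ``scaled=scale``) and the
    consensus configuration.  ``cohort.sizes`` (physical sizes) pass through
    unchanged.
    """
    if cohort.n_cases < 2:
        raise ValueError("GPA needs at least two configurations")
    configs = cohort.coords - cohort.coords.mean(axis=1, keepdims=True)
    if scale:
        cs = np.array([centroid_size(x) for x in configs])
        configs = configs / cs[:, None, None]
    align = robust_align if robust else ordinary_align
    consensus = configs[0].copy()
    converged = False
    for _ in range(max_iter):
        aligned = np.stack([align(x, consensus, allow_scale=False)[0] for x in configs])
        new = aligned.mean(axis=0)
        new -= new.mean(axis=0)
        if scale:
            new /= centroid_size(new)
        # anchor the orientation of the new consensus to the previous one:
        # a global rotation is a neutral direction of the robust update and
        # would otherwise let the iteration slide along the rotation orbit
        new, _ = ordinary_align(new, consensus, allow_scale=False)
        new -= new.mean(axis=0)
        if np.linalg.norm(new - consensus) < tol:
            consensus = new
            converged = True
            break
        consensus = new
    aligned = np.stack([align(x, consensus, allow_scale=False)[0] for x in configs])
    configs = aligned
    if not converged:
        warnings.warn(f"GPA did not converge within {max_iter} iterations", RuntimeWarning)
    # deterministic output frame
    rot = _canonical_rotation(consensus - consensus.mean(axis=0))
    consensus = (consensus - consensus.mean(axis=0)) @ rot
    configs = configs @ rot
    configs -= configs.mean(axis=1, keepdims=True)
    out = replace(
        cohort,
        coords=configs,
        aligned=True,
        scaled=scale,
        meta={**cohort.meta, "gpa_converged": converged},
    )
    return out, consensus


# ---------------------------------------------------------------------------
# distance and normals
# ---------------------------------------------------------------------------

def shape_distance(a, b) -> float:
    """Euclidean norm of the coordinate difference between two configurations.

    Both must already live in a common superimposition frame; no
    re-alignment is performed.  This is the tangent-space approximation of
    Procrustes distance appropriate for small shape variation.
    """
    a = as_configuration(a)
    b = as_configuration(b, a.shape[0])
    return float(np.linalg.norm(a - b))


def vertex_normals(config, topo: TemplateTopology) -> np.ndarray:
    """Outward unit vertex normals (area-weighted average of face normals).

    Vertices with no incident face get a zero normal and trigger a warning.
    """
    x = as_configuration(config, topo.n_vertices)
    f = topo.faces
    if f.size == 0:
        warnings.warn("template has no faces; all normals zero", RuntimeWarning)
        return np.zeros_like(x)
    fn = np.cross(x[f[:, 1]] - x[f[:, 0]], x[f[:, 2]] - x[f[:, 0]])  # |fn| = 2 * area
    acc = np.zeros_like(x)
    for k in range(3):
        np.add.at(acc, f[:, k], fn)
    norms = np.linalg.norm(acc, axis=1)
    zero = norms < 1e-300
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} vertices have no incident face (or degenerate "
            "normal); their normals are zero",
            RuntimeWarning,
        )
    out = np.zeros_like(x)
    out[~zero] = acc[~zero] / norms[~zero, None]
    return out
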