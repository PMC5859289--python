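"""Synthetic templates and cohorts with known growth trajectories.

Real dense-correspondence head scans are rarely shareable, so every stage of
the pipeline is exercised against generated data instead: a triangulated
"toy head" (an ellipsoid with exact left–right vertex pairing), and
cross-sectional two-group cohorts whose group mean configurations follow
known smooth functions of age.  Because the generating means and their age
derivatives are available in closed form, expected heads, growth vectors,
dimorphism curves and angle maps all have analytic ground truth.

Scenario bundles mirror the qualitatively distinct ways two groups can
diverge: identical trajectories (``null``), the same growth directions at
1.5× the rate (``rate``), equal rates with growth vectors rotated in the
tangent plane (``direction``), a difference emerging only above an onset age
(``pubertal``), and a constant offset of ten noise standard deviations
(``separated``) for classifier power checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Cohort, TemplateTopology, centroid_size
from .trajectory import GrowthField

__all__ = [
    "GroupTrajectory",
    "NuisanceSpec",
    "TrajectorySpec",
    "make_template",
    "scenario",
    "simulate_cohort",
    "true_mean",
    "true_growth_field",
    "SCENARIOS",
]

SCENARIOS = ("null", "rate", "direction", "pubertal", "separated")


# ---------------------------------------------------------------------------
# toy template
# ---------------------------------------------------------------------------

def make_template(resolution: int = 3, radii=(70.0, 85.0, 95.0)):
    """Triangulated ellipsoid template with exact left–right symmetry.

    A UV-sphere parameterization with ``4 * resolution`` longitudes and
    ``2 * resolution + 1`` latitude rings (plus two poles) is scaled by
    ``radii`` (mm; lateral, depth, vertical).  Longitude ``phi`` and
    ``-phi`` vertices mirror across ``x = 0``, giving an exact symmetry
    pairing; vertices at ``phi`` of 0 and pi (and the poles) form the
    midline.  Returns ``(topology, base_configuration)``.
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    n_lon = 4 * resolution
    n_lat = 2 * resolution + 1
    rx, ry, rz = radii
    verts = [(0.0, 0.0, rz)]
    for i in range(n_lat):
        theta = np.pi * (i + 1) / (n_lat + 1)
        for j in range(n_lon):
            phi = 2.0 * np.pi * j / n_lon
            verts.append((rx * np.sin(theta) * np.sin(phi),
                          ry * np.sin(theta) * np.cos(phi),
                          rz * np.cos(theta)))
    verts.append((0.0, 0.0, -rz))
    coords = np.array(verts)
    north, south = 0, len(verts) - 1

    def ring(i, j):
        return 1 + i * n_lon + (j % n_lon)

    faces = []
    for j in range(n_lon):
        faces.append((north, ring(0, j), ring(0, j + 1)))
        faces.append((south, ring(n_lat - 1, j + 1), ring(n_lat - 1, j)))
    for i in range(n_lat - 1):
        for j in range(n_lon):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j), ring(i + 1, j + 1)
            faces.append((a, c, b))
            faces.append((b, c, d))
    faces = np.array(faces, dtype=np.int64)
    # orient faces outward (positive enclosed volume)
    vol = np.einsum(
        "ij,ij->i",
        coords[faces[:, 0]],
        np.cross(coords[faces[:, 1]], coords[faces[:, 2]]),
    ).sum() / 6.0
    if vol < 0:
        faces = faces[:, [0, 2, 1]]

    pairs = []
    midline = [north, south]
    for i in range(n_lat):
        midline.extend([ring(i, 0), ring(i, n_lon // 2)])
        for j in range(1, n_lon // 2):
            pairs.append((ring(i, j), ring(i, n_lon - j)))  # (x>0 side, x<0 side)
    topo = TemplateTopology(
        n_vertices=len(verts),
        faces=faces,
        symmetry_pairs=np.array(pairs, dtype=np.int64),
        midline_vertices=np.array(sorted(midline), dtype=np.int64),
        reflection_axis="x",
    )
    return topo, coords


# ---------------------------------------------------------------------------
# generating trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupTrajectory:
    """Smooth per-vertex mean trajectory: polynomial in age plus optional ramp.

    ``mean(a) = sum_k coeffs[k] * a**k + max(a - ramp_onset, 0) * ramp_field``.
    """

    coeffs: tuple
    ramp_field: np.ndarray | None = None
    ramp_onset: float = 0.0

    def mean(self, a: float) -> np.ndarray:
        out = np.zeros_like(np.asarray(self.coeffs[0], dtype=float))
        for k, c in enumerate(self.coeffs):
            out += c * a**k
        if self.ramp_field is not None:
            out += max(a - self.ramp_onset, 0.0) * self.ramp_field
        return out

    def derivative(self, a: float) -> np.ndarray:
        out = np.zeros_like(np.asarray(self.coeffs[0], dtype=float))
        for k, c in enumerate(self.coeffs):
            if k >= 1:
                out += k * c * a ** (k - 1)
        if self.ramp_field is not None and a > self.ramp_onset:
            out += self.ramp_field
        return out


@dataclass(frozen=True)
class NuisanceSpec:
    """Ranges of the random similarity transform applied to each raw case.

    Defaults emulate pose variation of calibrated 3D photogrammetry: free
    rotation up to ``rot_deg``, translation up to ``trans_mm`` per axis, and
    no scale nuisance (metric calibration); widen ``scale_range`` to stress
    the scale-removal of GPA.
    """

    rot_deg: float = 20.0
    trans_mm: float = 50.0
    scale_range: tuple = (1.0, 1.0)


@dataclass(frozen=True)
class TrajectorySpec:
    """Full generating model of a two-group cross-sectional cohort."""

    template: TemplateTopology
    trajectories: dict
    noise_sd: float
    nuisance: NuisanceSpec | None = None
    age_range: tuple = (0.5, 18.5)
    age_counts: dict | None = None  # {integer year: count weight} for non-uniform ages
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.trajectories) != 2:
            raise ValueError("exactly two group trajectories required")


def _tangent_rotation(base: np.ndarray, angle_deg: float) -> Rotation:
    """Per-vertex rotation by ``angle_deg`` about a tangential axis.

    The axis at each vertex is ``z_hat x r_hat`` (with ``r_hat`` the outward
    radial direction), falling back to ``x_hat x r_hat`` near the poles, so
    the rotation tilts vectors within/through the local tangent plane while
    preserving their length.
    """
    r_hat = base / np.linalg.norm(base, axis=1, keepdims=True)
    axis = np.cross(np.array([0.0, 0.0, 1.0]), r_hat)
    bad = np.linalg.norm(axis, axis=1) < 1e-8
    if np.any(bad):
        axis[bad] = np.cross(np.array([1.0, 0.0, 0.0]), r_hat[bad])
    axis /= np.linalg.norm(axis, axis=1, keepdims=True)
    return Rotation.from_rotvec(np.radians(angle_deg) * axis)


def scenario(
    name: str,
    resolution: int = 3,
    noise_sd: float | None = None,
    nuisance: NuisanceSpec | None = None,
    seed: int = 0,
    rate_factor: float = 1.5,
    direction_angle_deg: float = 45.0,
    pubertal_onset: float = 12.0,
    separation_factor: float = 10.0,
) -> TrajectorySpec:
    """Build a named scenario's generating spec on a toy template.

    Group A grows radially with mild spatial modulation and a gentle
    deceleration: ``mean_A(a) = X0 + a * V1 - a^2 * V2`` with ``V1 = 0.03 *
    g * X0`` and ``V2 = 0.0006 * g * X0``, where ``g`` varies smoothly over
    the surface.  Group B differs per the scenario (see module docstring).
    ``noise_sd`` defaults to 2% of the template's centroid size.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    topo, base = make_template(resolution)
    size0 = centroid_size(base)
    if noise_sd is None:
        noise_sd = 0.02 * size0
    rz = float(np.abs(base[:, 2]).max())
    modulation = (1.0 + 0.25 * base[:, 2] / rz)[:, None]
    v1 = 0.03 * modulation * base
    v2 = -0.0006 * modulation * base
    traj_a = GroupTrajectory(coeffs=(base, v1, v2))
    if name == "null":
        traj_b = traj_a
    elif name == "rate":
        traj_b = GroupTrajectory(coeffs=(base, rate_factor * v1, rate_factor * v2))
    elif name == "direction":
        rot = _tangent_rotation(base, direction_angle_deg)
        traj_b = GroupTrajectory(coeffs=(base, rot.apply(v1), rot.apply(v2)))
    elif name == "pubertal":
        ramp = 0.02 * base
        traj_b = GroupTrajectory(coeffs=(base, v1, v2), ramp_field=ramp,
                                 ramp_onset=pubertal_onset)
    else:  # separated
        r_hat = base / np.linalg.norm(base, axis=1, keepdims=True)
        offset = separation_factor * noise_sd * r_hat
        traj_b = GroupTrajectory(coeffs=(base + offset, v1, v2))
    return TrajectorySpec(
        template=topo,
        trajectories={"A": traj_a, "B": traj_b},
        noise_sd=float(noise_sd),
        nuisance=nuisance,
        seed=seed,
    )


def _draw_ages(spec: TrajectorySpec, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.age_range
    if spec.age_counts is None:
        return rng.uniform(lo, hi, size=n)
    years = np.array(sorted(spec.age_counts), dtype=float)
    weights = np.array([spec.age_counts[y] for y in sorted(spec.age_counts)], dtype=float)
    weights = weights / weights.sum()
    base_year = rng.choice(years, size=n, p=weights)
    return np.clip(base_year + rng.uniform(0.0, 1.0, size=n), lo, hi)


def simulate_cohort(spec: TrajectorySpec, n_per_group: int, seed: int | None = None):
    """Draw a cross-sectional two-group cohort from a generating spec.

    Each case's configuration is the group mean at its age plus isotropic
    per-vertex Gaussian noise, optionally pushed through a random similarity
    transform (``spec.nuisance``).  Recorded sizes are measured from the
    delivered configurations, as a mesh reader would.

    Returns ``(cohort, truth)`` where ``truth`` is a dict holding the
    generating ``spec``, the drawn ages per case, and the applied nuisance
    transforms; together with :func:`true_mean` / :func:`true_growth_field`
    it determines every target quantity exactly.  The same ``seed``
    reproduces the cohort bit for bit.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_vert = spec.template.n_vertices
    labels = sorted(spec.trajectories)
    coords, ages, groups, sizes, ids, transforms = [], [], [], [], [], []
    for lab in labels:
        traj = spec.trajectories[lab]
        a_g = _draw_ages(spec, n_per_group, rng)
        for j, a in enumerate(a_g):
            x = traj.mean(float(a))
            if spec.noise_sd > 0:
                x = x + rng.normal(0.0, spec.noise_sd, size=(n_vert, 3))
            tf = None
            if spec.nuisance is not None:
                nu = spec.nuisance
                angle = np.radians(nu.rot_deg) * rng.uniform(0.0, 1.0)
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                rot = Rotation.from_rotvec(angle * axis)
                s = rng.uniform(*nu.scale_range)
                t = rng.uniform(-nu.trans_mm, nu.trans_mm, size=3)
                x = s * rot.apply(x) + t
                tf = {"rotation": rot.as_matrix(), "scale": float(s), "translation": t}
            coords.append(x)
            ages.append(float(a))
            groups.append(lab)
            sizes.append(centroid_size(x))
            ids.append(f"{lab}{j:04d}")
            transforms.append(tf)
    cohort = Cohort(
        coords=np.stack(coords),
        ages=np.array(ages),
        groups=np.array(groups),
        sizes=np.array(sizes),
        ids=ids,
        aligned=spec.nuisance is None,
        scaled=False,
    )
    truth = {"spec": spec, "ages": np.array(ages), "groups": np.array(groups),
             "transforms": transforms}
    return cohort, truth


def true_mean(spec: TrajectorySpec, group, a: float) -> np.ndarray:
    """Analytic group mean configuration at age ``a``."""
    return spec.trajectories[group].mean(a)


def true_growth_field(spec: TrajectorySpec, group, a: float) -> GrowthField:
    """Analytic growth vectors (derivative of the group mean) at age ``a``."""
    return GrowthField(vectors=spec.trajectories[group].derivative(a), age=float(a))
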