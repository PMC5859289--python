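"""Configuration primitives: size, symmetry, robust alignment, GPA, normals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.transform import Rotation

from shapegrowth import core
from shapegrowth.core import (
    Cohort,
    TemplateTopology,
    centroid_size,
    gpa,
    ordinary_align,
    robust_align,
    shape_distance,
    symmetrize,
    vertex_normals,
)


def random_rotation(rng):
    return Rotation.random(rng=rng).as_matrix()


# ---------------------------------------------------------------------------
# centroid size
# ---------------------------------------------------------------------------

class TestCentroidSize:
    def test_square_of_side_two(self):
        pts = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], dtype=float)
        assert centroid_size(pts) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_coincident_points_have_zero_size(self):
        assert centroid_size(np.ones((3, 3))) == 0.0

    def test_homogeneous_in_scale(self, rng):
        x = rng.normal(size=(20, 3))
        assert centroid_size(3.7 * x) == pytest.approx(3.7 * centroid_size(x), rel=1e-12)

    def test_rejects_single_vertex(self):
        with pytest.raises(ValueError):
            centroid_size(np.zeros((1, 3)))


# ---------------------------------------------------------------------------
# symmetrization
# ---------------------------------------------------------------------------

def two_point_template():
    return TemplateTopology(
        n_vertices=2,
        faces=np.empty((0, 3), dtype=int),
        symmetry_pairs=np.array([[0, 1]]),
        midline_vertices=np.array([], dtype=int),
        reflection_axis="x",
    )


class TestSymmetrize:
    def test_hand_computed_pair(self):
        topo = two_point_template()
        config = np.array([[1.0, 0, 0], [-2.0, 0, 0]])
        out = symmetrize(config, topo)
        np.testing.assert_allclose(out, [[1.5, 0, 0], [-1.5, 0, 0]], atol=1e-12)

    def test_symmetric_input_is_fixed_point(self, toy_template):
        topo, base = toy_template
        centered = base - base.mean(axis=0)
        np.testing.assert_allclose(symmetrize(base, topo), centered, atol=1e-9)

    def test_idempotent(self, toy_template, rng):
        topo, base = toy_template
        noisy = base + rng.normal(0, 2.0, size=base.shape)
        once = symmetrize(noisy, topo)
        np.testing.assert_allclose(symmetrize(once, topo), once, atol=1e-9)

    def test_output_invariant_under_reflect_relabel(self, toy_template, rng):
        topo, base = toy_template
        noisy = base + rng.normal(0, 2.0, size=base.shape)
        out = symmetrize(noisy, topo)
        np.testing.assert_allclose(core.reflect_relabel(out, topo), out, atol=1e-9)

    def test_commutes_with_reflect_relabel(self, toy_template, rng):
        topo, base = toy_template
        noisy = base - base.mean(axis=0) + rng.normal(0, 2.0, size=base.shape)
        a = symmetrize(core.reflect_relabel(noisy, topo), topo)
        b = symmetrize(noisy, topo)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_size_mismatch_rejected(self, toy_template):
        topo, _ = toy_template
        with pytest.raises(ValueError):
            symmetrize(np.zeros((topo.n_vertices + 1, 3)), topo)


# ---------------------------------------------------------------------------
# template topology validation
# ---------------------------------------------------------------------------

class TestTemplateTopology:
    def test_vertex_in_pair_and_midline_rejected(self):
        with pytest.raises(ValueError, match="exactly one"):
            TemplateTopology(
                n_vertices=2,
                faces=np.empty((0, 3), dtype=int),
                symmetry_pairs=np.array([[0, 1]]),
                midline_vertices=np.array([0]),
            )

    def test_degenerate_face_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            TemplateTopology(
                n_vertices=3,
                faces=np.array([[0, 1, 1]]),
                symmetry_pairs=np.array([[0, 1]]),
                midline_vertices=np.array([2]),
            )


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

class TestRobustAlign:
    def test_exact_recovery_of_rigid_copy(self, toy_template, rng):
        _, base = toy_template
        source = base @ random_rotation(rng).T + np.array([5.0, -3.0, 11.0])
        aligned, _ = robust_align(source, base)
        assert np.linalg.norm(aligned - base) < 1e-8

    def test_matches_closed_form_procrustes_on_clean_data(self, toy_template, rng):
        """Oracle: scipy's orthogonal Procrustes on centered configurations.

        With (numerically) zero residuals the IRLS weights stay uniform, so
        the robust fit must coincide with the closed-form solution.
        """
        _, base = toy_template
        target = base + rng.normal(0, 1e-8, size=base.shape)
        source = base @ random_rotation(rng).T + 7.0
        s0 = source - source.mean(axis=0)
        t0 = target - target.mean(axis=0)
        r, _ = orthogonal_procrustes(s0, t0)
        oracle = s0 @ r + target.mean(axis=0)
        aligned, _ = robust_align(source, target)
        np.testing.assert_allclose(aligned, oracle, atol=1e-6)

    def test_stays_near_least_squares_under_moderate_noise(self, toy_template, rng):
        # reweighting shifts the fit by at most O(noise), never grossly
        _, base = toy_template
        target = base + rng.normal(0, 1.0, size=base.shape)
        source = base @ random_rotation(rng).T + 7.0
        rob, _ = robust_align(source, target)
        ols, _ = ordinary_align(source, target)
        assert np.abs(rob - ols).max() < 0.5

    def test_downweights_gross_outlier(self, toy_template, rng):
        _, base = toy_template
        noise_sd = 0.5
        target = base + rng.normal(0, noise_sd, size=base.shape)
        source = base @ random_rotation(rng).T + 2.0
        corrupted = target.copy()
        corrupted[0] += 50 * noise_sd * np.array([1.0, 1.0, 1.0])
        rob, _ = robust_align(source, corrupted)
        ols, _ = ordinary_align(source, corrupted)
        keep = np.arange(1, base.shape[0])  # trimmed residual excludes the outlier
        r_rob = np.linalg.norm(rob[keep] - corrupted[keep])
        r_ols = np.linalg.norm(ols[keep] - corrupted[keep])
        assert r_rob < r_ols

    def test_scaling_recovered_when_allowed(self, toy_template, rng):
        _, base = toy_template
        source = 0.4 * base @ random_rotation(rng).T - 8.0
        aligned, params = robust_align(source, base, allow_scale=True)
        assert np.linalg.norm(aligned - base) < 1e-7
        assert params["scale"] == pytest.approx(2.5, rel=1e-9)

    def test_degenerate_source_rejected(self, toy_template):
        _, base = toy_template
        with pytest.raises(ValueError, match="degenerate"):
            robust_align(np.zeros_like(base), base)


# ---------------------------------------------------------------------------
# generalized Procrustes alignment
# ---------------------------------------------------------------------------

def make_cohort(coords, ages=None):
    n = coords.shape[0]
    return Cohort(
        coords=coords,
        ages=np.linspace(1, 10, n) if ages is None else ages,
        groups=np.array(["A"] * (n // 2) + ["B"] * (n - n // 2)),
        sizes=np.array([centroid_size(x) for x in coords]),
        ids=[f"c{i}" for i in range(n)],
    )


class TestGPA:
    @pytest.mark.parametrize("scale", [True, False])
    def test_identical_configs_under_similarity_collapse(self, toy_template, rng, scale):
        _, base = toy_template
        coords = []
        for _ in range(8):
            s = rng.uniform(0.8, 1.25) if scale else 1.0
            coords.append(s * base @ random_rotation(rng).T + rng.uniform(-50, 50, 3))
        aligned, consensus = gpa(make_cohort(np.stack(coords)), scale=scale, robust=True)
        spread = np.abs(aligned.coords - aligned.coords[0]).max()
        assert spread < 1e-6
        assert np.abs(consensus.mean(axis=0)).max() < 1e-9

    def test_unit_sizes_when_scaling(self, toy_template, rng):
        _, base = toy_template
        coords = np.stack([base + rng.normal(0, 2.0, base.shape) for _ in range(10)])
        aligned, _ = gpa(make_cohort(coords), scale=True)
        for x in aligned.coords:
            assert abs(centroid_size(x) - 1.0) < 1e-9
            assert np.abs(x.mean(axis=0)).max() < 1e-9

    def test_sizes_conserved_without_scaling(self, toy_template, rng):
        _, base = toy_template
        coords = np.stack([base + rng.normal(0, 2.0, base.shape) for _ in range(6)])
        cohort = make_cohort(coords)
        sizes_in = [centroid_size(x) for x in coords]
        aligned, _ = gpa(cohort, scale=False)
        sizes_out = [centroid_size(x) for x in aligned.coords]
        np.testing.assert_allclose(sizes_out, sizes_in, rtol=1e-10)

    @pytest.mark.parametrize("robust", [True, False])
    def test_invariant_to_input_similarity_transforms(self, toy_template, rng, robust):
        _, base = toy_template
        coords = np.stack([base + rng.normal(0, 2.0, base.shape) for _ in range(10)])
        cohort = make_cohort(coords)
        a1, c1 = gpa(cohort, scale=True, robust=robust)
        moved = np.stack([
            rng.uniform(0.7, 1.4) * x @ random_rotation(rng).T + rng.uniform(-80, 80, 3)
            for x in coords
        ])
        a2, c2 = gpa(make_cohort(moved), scale=True, robust=robust)
        assert np.abs(a1.coords - a2.coords).max() < 1e-6
        assert np.abs(c1 - c2).max() < 1e-6


# ---------------------------------------------------------------------------
# shape distance
# ---------------------------------------------------------------------------

class TestShapeDistance:
    def test_single_vertex_displacement(self):
        a = np.zeros((5, 3))
        b = a.copy()
        b[2, 0] = 0.3
        assert shape_distance(a, b) == pytest.approx(0.3, abs=1e-15)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            shape_distance(np.zeros((4, 3)), np.zeros((5, 3)))

    @settings(deadline=None, max_examples=30)
    @given(
        arrays(np.float64, (6, 3), elements=st.floats(-100, 100)),
        arrays(np.float64, (6, 3), elements=st.floats(-100, 100)),
        arrays(np.float64, (6, 3), elements=st.floats(-100, 100)),
    )
    def test_is_a_metric(self, x, y, z):
        dxy, dyx = shape_distance(x, y), shape_distance(y, x)
        assert dxy >= 0
        assert dxy == dyx
        assert shape_distance(x, x) == 0
        assert shape_distance(x, z) <= dxy + shape_distance(y, z) + 1e-9


# ---------------------------------------------------------------------------
# vertex normals
# ---------------------------------------------------------------------------

class TestVertexNormals:
    def test_sphere_normals_are_radial(self):
        from shapegrowth.synthetic import make_template

        topo, base = make_template(4, radii=(1.0, 1.0, 1.0))
        normals = vertex_normals(base, topo)
        radial = base / np.linalg.norm(base, axis=1, keepdims=True)
        cosines = np.einsum("ij,ij->i", normals, radial)
        assert cosines.min() > 0.99

    def test_unit_rows_on_closed_mesh(self, toy_template):
        topo, base = toy_template
        normals = vertex_normals(base, topo)
        np.testing.assert_allclose(np.linalg.norm(normals, axis=1), 1.0, atol=1e-9)

    def test_flat_patch_normals_along_z(self):
        # unit square in z=0 split into two triangles, plus one isolated vertex
        verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [5, 5, 5.0]])
        topo = TemplateTopology(
            n_vertices=5,
            faces=np.array([[0, 1, 2], [0, 2, 3]]),
            symmetry_pairs=np.empty((0, 2), dtype=int),
            midline_vertices=np.arange(5),
            reflection_axis="x",
        )
        with pytest.warns(RuntimeWarning, match="no incident face"):
            normals = vertex_normals(verts, topo)
        np.testing.assert_allclose(normals[:4], [[0, 0, 1.0]] * 4, atol=1e-12)
        np.testing.assert_allclose(normals[4], 0.0)
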