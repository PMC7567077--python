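import numpy as np
import pandas as pd
import pytest

from nicheshift.niche_space import (
    GridDensity,
    fit_species_axis,
    grid_density,
    project,
    range_background_env,
    silverman_1d,
)
from nicheshift.preprocess import EnvMatrix


def _env(X, cols=None):
    X = np.asarray(X, dtype=float)
    cols = cols or [f"v{i}" for i in range(X.shape[1])]
    return EnvMatrix(X, pd.RangeIndex(len(X)), cols)


class TestSpeciesAxis:
    def test_separated_clouds_have_disjoint_iqrs(self, rng):
        a = rng.normal(0, 1, size=(200, 3))
        b = rng.normal(0, 1, size=(200, 3)) + [4, -4, 2]
        axis = fit_species_axis(_env(a), _env(b), n_axes=3)
        sa = project(_env(a), axis)
        sb = project(_env(b), axis)
        assert np.percentile(sa, 75) < np.percentile(sb, 25)
        # sign convention: native projects below non-native
        assert sa.mean() < sb.mean()

    def test_identical_classes_fall_back_to_pc1(self, rng):
        X = _env(rng.normal(size=(50, 4)))
        with pytest.warns(UserWarning, match="identical class centroids"):
            axis = fit_species_axis(X, X, n_axes=4)
        e1 = np.zeros(4)
        e1[0] = 1
        assert np.array_equal(axis.bca_vector, e1)

    def test_bca_vector_unit_norm(self, rng):
        a = _env(rng.normal(size=(40, 6)))
        b = _env(rng.normal(size=(30, 6)) + 0.5)
        axis = fit_species_axis(a, b, n_axes=5)
        assert np.linalg.norm(axis.bca_vector) == pytest.approx(1.0)

    def test_zero_variance_variable_dropped(self, rng):
        a = np.c_[rng.normal(size=(40, 2)), np.full(40, 3.0)]
        b = np.c_[rng.normal(size=(40, 2)) + 1, np.full(40, 3.0)]
        with pytest.warns(UserWarning, match="zero-variance"):
            axis = fit_species_axis(_env(a), _env(b), n_axes=2)
        assert axis.dropped_columns == ["v2"]
        # projection still works on the full-width matrix
        assert len(project(_env(a), axis)) == 40


class TestProjection:
    def test_pooled_mean_projects_to_zero(self, rng):
        a = _env(rng.normal(size=(60, 4)))
        b = _env(rng.normal(size=(40, 4)) + 2)
        axis = fit_species_axis(a, b, n_axes=4)
        pooled_mean = np.vstack([a.values, b.values]).mean(axis=0, keepdims=True)
        assert project(pooled_mean, axis)[0] == pytest.approx(0.0, abs=1e-10)

    def test_projection_deterministic(self, rng):
        a = _env(rng.normal(size=(30, 5)))
        b = _env(rng.normal(size=(30, 5)) + 1)
        axis = fit_species_axis(a, b, n_axes=5)
        assert np.array_equal(project(a, axis), project(a, axis))

    def test_unit_step_along_axis_scores_one(self, rng):
        a = _env(rng.normal(size=(80, 4)))
        b = _env(rng.normal(size=(80, 4)) + 1.5)
        axis = fit_species_axis(a, b, n_axes=4)
        # a point displaced 1 SD along the axis direction in standardised space
        x0 = np.vstack([a.values, b.values]).mean(axis=0)
        x1 = x0 + axis.sds * axis.direction
        scores = project(np.vstack([x0, x1]), axis)
        assert scores[1] - scores[0] == pytest.approx(1.0)

    def test_column_mismatch_rejected(self, rng):
        a = _env(rng.normal(size=(30, 4)))
        b = _env(rng.normal(size=(30, 4)) + 1)
        axis = fit_species_axis(a, b, n_axes=3)
        with pytest.raises(ValueError, match="columns"):
            project(rng.normal(size=(5, 7)), axis)


class TestGridDensity:
    def test_occurrences_equal_background_give_flat_occupancy(self, rng):
        s = rng.normal(size=1000)
        g = grid_density(s, s, n_bins=100)
        occupied = g.z[g.z > 0]
        assert occupied.max() / occupied.min() < 3

    def test_densities_sum_to_one(self, rng):
        g = grid_density(rng.normal(size=200), rng.uniform(-4, 4, size=500))
        for v in (g.o, g.e, g.z):
            assert v.sum() == pytest.approx(1.0)

    def test_corner_occurrences_concentrate_occupancy(self, rng):
        bg = rng.uniform(0, 10, size=2000)
        occ = rng.normal(9.8, 0.05, size=200)
        g = grid_density(occ, bg, n_bins=100)
        zs = np.sort(g.z)[::-1]
        assert np.searchsorted(np.cumsum(zs), 0.95) + 1 < 20

    def test_duplicating_occurrences_leaves_z_unchanged(self, rng):
        s = rng.normal(size=300)
        bg = rng.uniform(-4, 4, size=400)
        g1 = grid_density(s, bg, bounds=(-4, 4))
        g2 = grid_density(np.repeat(s, 2), bg, bounds=(-4, 4))
        # doubling n shrinks the Silverman bandwidth; pin it for the check
        h = silverman_1d(s)
        g1 = grid_density(s, bg, bounds=(-4, 4), bandwidth=h)
        g2 = grid_density(np.repeat(s, 2), bg, bounds=(-4, 4), bandwidth=h)
        assert np.allclose(g1.z, g2.z)

    def test_availability_correction_divides_by_relative_availability(self, rng):
        # same occurrence density everywhere, half the availability on the right
        occ = rng.uniform(0, 2, size=4000)
        bg = np.concatenate([rng.uniform(0, 1, 2000), rng.uniform(1, 2, 1000)])
        g = grid_density(occ, bg, n_bins=20, bandwidth=0.05)
        left = g.z[2:8].mean()
        right = g.z[12:18].mean()
        assert right / left == pytest.approx(2.0, rel=0.2)

    def test_common_bounds_shared_between_ranges(self, rng):
        s1, s2 = rng.normal(size=100), rng.normal(3, 1, size=100)
        bg = rng.uniform(-5, 8, size=800)
        g1 = grid_density(s1, bg, bounds=(-5, 8))
        g2 = grid_density(s2, bg, bounds=(-5, 8))
        assert np.array_equal(g1.edges, g2.edges)

    def test_z_zero_where_availability_zero(self, rng):
        occ = rng.normal(5, 1, size=300)
        bg = rng.uniform(0, 4, size=500)  # background stops at 4
        g = grid_density(occ, bg, bounds=(0, 10))
        assert (g.z[g.mids > 4.01] == 0).all()

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            grid_density(np.full(50, 1.0), np.linspace(0, 1, 50))

    def test_invariants_enforced(self):
        edges = np.linspace(0, 1, 4)
        with pytest.raises(ValueError, match="sum to 1"):
            GridDensity(edges, np.array([0.5, 0.2, 0.2]), np.full(3, 1 / 3), np.full(3, 1 / 3))
        with pytest.raises(ValueError, match="z must be 0"):
            GridDensity(
                edges,
                np.full(3, 1 / 3),
                np.array([0.5, 0.5, 0.0]),
                np.array([0.3, 0.3, 0.4]),
            )


def test_hull_background_subsets_raster(small_stack):
    pts = np.array([[2, 20], [12, 20], [7, 28], [7, 14]], dtype=float)
    hull_env = range_background_env(pts, small_stack, mode="hull")
    all_env = range_background_env(pts, small_stack, mode="raster")
    assert 0 < len(hull_env) < len(all_env)
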