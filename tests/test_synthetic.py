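import json

import numpy as np
import pandas as pd
import pytest

from nicheshift.synthetic import (
    RangePolygons,
    VirtualSpeciesTruth,
    generate_climate_stack,
    generate_polygon_map,
    generate_virtual_species,
    write_fixture,
    _window_cells,
)
from nicheshift.grids import read_stack


class TestClimateStack:
    def test_construction_17_layers_no_nodata(self):
        st = generate_climate_stack(17, 50, 50, correlation=0.3, seed=1)
        assert st.n_layers == 17 and st.n_rows == 50 and st.n_cols == 50
        assert st.valid_mask().all()
        assert st.layer_names[:3] == ["bio1", "bio3", "bio4"]  # bio2 excluded

    def test_deterministic_for_fixed_seed(self):
        a = generate_climate_stack(17, 50, 50, correlation=0.3, seed=1)
        b = generate_climate_stack(17, 50, 50, correlation=0.3, seed=1)
        assert np.array_equal(a.values, b.values)
        c = generate_climate_stack(17, 50, 50, correlation=0.3, seed=2)
        assert not np.array_equal(a.values, c.values)

    def test_zero_correlation_layers_nearly_uncorrelated(self):
        st = generate_climate_stack(17, 50, 50, correlation=0.0, seed=2)
        env, _, _ = st.env_table()
        C = np.corrcoef(env.T)
        iu = np.triu_indices(17, 1)
        assert np.abs(C[iu]).mean() < 0.25

    def test_requested_correlation_roughly_achieved(self):
        st = generate_climate_stack(10, 40, 40, correlation=0.5, seed=3)
        env, _, _ = st.env_table()
        C = np.corrcoef(env.T)
        iu = np.triu_indices(10, 1)
        assert abs(C[iu].mean() - 0.5) < 0.15

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="degenerate grid"):
            generate_climate_stack(3, 1, 50)


class TestVirtualSpecies:
    def _truth(self, stack, shift=0.0, texp=0.0, seed=5):
        k = stack.n_layers
        return VirtualSpeciesTruth(
            niche_center=np.zeros(k),
            niche_breadth=np.ones(k),
            shift_delta=np.full(k, shift),
            target_expansion=texp,
            seed=seed,
        )

    def test_row_counts_and_statuses(self, small_stack):
        t = self._truth(small_stack)
        occ = generate_virtual_species(
            small_stack, t, (0, 14, 0, 30), (16, 30, 0, 30), 200, 100
        )
        assert len(occ) == 300
        assert (occ["status"] == "native").sum() == 200
        assert (occ["status"] == "nonnative").sum() == 100

    def test_deterministic_given_seed(self, small_stack):
        t = self._truth(small_stack)
        a = generate_virtual_species(small_stack, t, (0, 14, 0, 30), (16, 30, 0, 30), 50, 50)
        b = generate_virtual_species(small_stack, t, (0, 14, 0, 30), (16, 30, 0, 30), 50, 50)
        pd.testing.assert_frame_equal(a, b)

    def test_full_expansion_puts_every_point_outside_native_envelope(self, cohort_stack):
        t = self._truth(cohort_stack, texp=1.0)
        nat_w, non_w = (2, 23, 2, 48), (27, 48, 2, 48)
        occ = generate_virtual_species(cohort_stack, t, nat_w, non_w, 50, 50)
        env_all, _, _ = cohort_stack.env_table()
        mu, sd = env_all.mean(0), env_all.std(0)
        nat_env, _, _ = _window_cells(cohort_stack, nat_w)
        z_nat = (nat_env - mu) / sd
        lo, hi = z_nat.min(0), z_nat.max(0)
        non = occ[occ["status"] == "nonnative"]
        z = (cohort_stack.values_at(non["lon"].to_numpy(), non["lat"].to_numpy()) - mu) / sd
        assert (((z < lo) | (z > hi)).any(axis=1)).all()

    def test_no_shift_no_expansion_keeps_env_means_close(self, cohort_stack, cohort_geometry):
        nat_w, non_w, center, _ = cohort_geometry
        t = VirtualSpeciesTruth(center, np.ones(17), np.zeros(17), 0.0, seed=3)
        occ = generate_virtual_species(cohort_stack, t, nat_w, non_w, 200, 100)
        env = cohort_stack.values_at(occ["lon"].to_numpy(), occ["lat"].to_numpy())
        diff = np.abs(env[:200].mean(0) - env[200:].mean(0)) / env.std(0)
        assert diff.mean() < 0.5

    def test_env_at_points_within_layer_ranges(self, small_stack):
        t = self._truth(small_stack, shift=1.0, texp=0.3)
        occ = generate_virtual_species(small_stack, t, (0, 14, 0, 30), (16, 30, 0, 30), 30, 30)
        env = small_stack.values_at(occ["lon"].to_numpy(), occ["lat"].to_numpy())
        lo = np.nanmin(small_stack.values, axis=(1, 2))
        hi = np.nanmax(small_stack.values, axis=(1, 2))
        assert (env >= lo).all() and (env <= hi).all()

    def test_overlapping_windows_rejected(self, small_stack):
        t = self._truth(small_stack)
        with pytest.raises(ValueError, match="disjoint"):
            generate_virtual_species(small_stack, t, (0, 20, 0, 30), (15, 30, 0, 30), 50, 50)

    def test_minimum_counts_enforced(self, small_stack):
        t = self._truth(small_stack)
        with pytest.raises(ValueError, match="at least 10"):
            generate_virtual_species(small_stack, t, (0, 14, 0, 30), (16, 30, 0, 30), 5, 50)


class TestPolygonMap:
    def test_single_polygon_unit_square(self):
        rp = generate_polygon_map(1, 1, (0, 1, 0, 1))
        assert len(rp.polygon_ids) == 1
        assert np.allclose(rp.centroids[0], (0.5, 0.5))

    def test_two_by_one_centroids(self):
        rp = generate_polygon_map(2, 1, (0, 2, 0, 1))
        assert np.allclose(sorted(map(tuple, rp.centroids)), [(0.5, 0.5), (1.5, 0.5)])
        d = np.linalg.norm(rp.centroids[0] - rp.centroids[1])
        assert d == pytest.approx(1.0)

    def test_three_by_three_unique_ids(self):
        rp = generate_polygon_map(3, 3, (-10, 20, -5, 25))
        assert len(rp.polygon_ids) == 9
        assert len(set(rp.polygon_ids)) == 9

    def test_empty_extent_rejected(self):
        with pytest.raises(ValueError, match="empty extent"):
            generate_polygon_map(2, 2, (0, 0, 0, 1))


class TestFixtureIO:
    def _fixture(self, tmp_path, small_stack, seed=9):
        t = VirtualSpeciesTruth(np.zeros(5), np.ones(5), np.zeros(5), 0.0, seed=seed)
        occ = generate_virtual_species(small_stack, t, (0, 14, 0, 30), (16, 30, 0, 30), 20, 20)
        rp = generate_polygon_map(3, 3, (0, 30, 0, 30))
        return write_fixture(tmp_path, small_stack, occ, rp, t)

    def test_roundtrip_reproduces_stack_exactly(self, tmp_path, small_stack):
        self._fixture(tmp_path, small_stack)
        back = read_stack(tmp_path)
        order = [small_stack.layer_names.index(n) for n in back.layer_names]
        assert np.array_equal(back.values, small_stack.values[order])

    def test_manifest_row_count(self, tmp_path, small_stack):
        manifest = self._fixture(tmp_path, small_stack)
        assert len(manifest) == small_stack.n_layers + 3

    def test_rerun_same_seed_identical_checksums(self, tmp_path, small_stack):
        m1 = self._fixture(tmp_path / "a", small_stack)
        m2 = self._fixture(tmp_path / "b", small_stack)
        assert m1 == m2

    def test_polygons_roundtrip_with_recomputed_centroids(self, tmp_path, small_stack):
        self._fixture(tmp_path, small_stack)
        gj = json.loads((tmp_path / "polygons.geojson").read_text())
        rp = RangePolygons.from_geojson(gj)
        assert len(rp.polygon_ids) == 9
        assert np.allclose(sorted(rp.centroids[:, 0]), sorted(np.repeat([5.0, 15.0, 25.0], 3)))
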