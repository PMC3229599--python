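"""Distribution descriptors, fit tests, overlap, subsampling, model choice."""

import numpy as np
import pytest
from scipy import stats as sps

from paleophylo import (ClimateGrid, HabitatDistribution, distribution_stats,
                        haversine_km, overlap_index, select_best_model,
                        subsample_stability, t_test_distributions)
from paleophylo.envelopes import fit_bioclim, project_envelope
from paleophylo.habitat_stats import DistributionStats
from paleophylo.variables import VariableRegistry


def toy_grid(n=100, seed=0):
    rng = np.random.default_rng(seed)
    reg = VariableRegistry.from_codes(["BIO1", "BIO12"])
    return ClimateGrid(np.arange(n), rng.uniform(-110, -90, n),
                       rng.uniform(25, 45, n),
                       np.column_stack([rng.normal(12, 6, n),
                                        rng.normal(900, 250, n)]), reg)


def dist_of(grid, ids, name="d"):
    return HabitatDistribution(name, 0.0, frozenset(int(i) for i in ids),
                               grid.label)


class TestDescriptors:
    def test_single_point(self):
        grid = toy_grid()
        st = distribution_stats(dist_of(grid, [3]), grid)
        assert st.center_lon == pytest.approx(grid.lon[3])
        assert np.isnan(st.dispersion_km)
        assert st.areal_extent_km2 == 2500.0

    def test_symmetric_quad_centers_at_origin_offset(self):
        reg = VariableRegistry.from_codes(["BIO1"])
        lon = np.array([-0.5, 0.5, -0.5, 0.5])
        lat = np.array([-0.5, -0.5, 0.5, 0.5])
        grid = ClimateGrid(np.arange(4), lon, lat, np.zeros((4, 1)), reg)
        st = distribution_stats(dist_of(grid, range(4)), grid)
        assert st.center_lon == pytest.approx(0.0)
        assert st.center_lat == pytest.approx(0.0)

    def test_dispersion_matches_loop_oracle(self):
        grid = toy_grid(seed=5)
        ids = np.arange(50)
        st = distribution_stats(dist_of(grid, ids), grid)
        c_lon, c_lat = grid.lon[ids].mean(), grid.lat[ids].mean()
        dists = [haversine_km(grid.lon[i], grid.lat[i], c_lon, c_lat)
                 for i in ids]
        assert st.dispersion_km == pytest.approx(np.std(dists, ddof=1))

    def test_empty_distribution_flagged_not_error(self):
        grid = toy_grid()
        st = distribution_stats(dist_of(grid, []), grid)
        assert st.is_empty and st.areal_extent_km2 == 0.0

    def test_longitude_translation_equivariance(self):
        grid = toy_grid(seed=2)
        ids = np.arange(30)
        st0 = distribution_stats(dist_of(grid, ids), grid)
        shifted = ClimateGrid(grid.point_ids, grid.lon + 10.0, grid.lat,
                              grid.values, grid.registry)
        st1 = distribution_stats(dist_of(shifted, ids), shifted)
        assert st1.center_lon == pytest.approx(st0.center_lon + 10.0)


class TestTTest:
    def test_identical_distributions(self):
        a = DistributionStats(-100.0, 35.0, 120.0, 50, 50 * 2500.0)
        t, p = t_test_distributions(a, a)
        assert t == 0.0 and p == 1.0

    def test_hand_computed_statistic(self):
        # d = 10 km, s = 10 km both, n = 100 both -> t = 10 / sqrt(2) = 7.071
        lat_for_10km = 10.0 / (np.pi / 180.0 * 6371.0)
        a = DistributionStats(0.0, 0.0, 10.0, 100, 0.0)
        b = DistributionStats(0.0, lat_for_10km, 10.0, 100, 0.0)
        t, _ = t_test_distributions(a, b)
        assert t == pytest.approx(7.071, abs=2e-3)

    def test_matches_scipy_welch_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            sa, sb = rng.uniform(5, 200, 2)
            na, nb = rng.integers(3, 400, 2)
            dlat = rng.uniform(0.01, 3.0)
            a = DistributionStats(0.0, 0.0, sa, int(na), 0.0)
            b = DistributionStats(0.0, dlat, sb, int(nb), 0.0)
            t, p = t_test_distributions(a, b)
            d = haversine_km(0.0, 0.0, 0.0, dlat)
            # scipy's summary-statistics Welch test on means d vs 0
            t_ref, p_ref = sps.ttest_ind_from_stats(
                d, sa, int(na), 0.0, sb, int(nb), equal_var=False)
            assert t == pytest.approx(abs(t_ref), rel=1e-9)
            assert p == pytest.approx(p_ref, rel=1e-9)

    def test_symmetry_in_arguments(self):
        a = DistributionStats(0.0, 0.0, 50.0, 30, 0.0)
        b = DistributionStats(1.0, 1.0, 120.0, 200, 0.0)
        assert t_test_distributions(a, b)[1] == pytest.approx(
            t_test_distributions(b, a)[1])

    def test_empty_input_rejected(self):
        a = DistributionStats(0.0, 0.0, 10.0, 10, 0.0)
        empty = DistributionStats(np.nan, np.nan, np.nan, 0, 0.0)
        with pytest.raises(ValueError):
            t_test_distributions(a, empty)


class TestOverlap:
    def test_identical_sets(self):
        grid = toy_grid()
        a = dist_of(grid, range(10))
        assert overlap_index(a, a) == 1.0

    def test_disjoint_and_empty(self):
        grid = toy_grid()
        assert overlap_index(dist_of(grid, range(10)),
                             dist_of(grid, range(10, 20))) == 0.0
        assert overlap_index(dist_of(grid, []), dist_of(grid, [])) == 0.0

    def test_half_shared(self):
        grid = toy_grid()
        a = dist_of(grid, range(10))
        b = dist_of(grid, range(5, 15))
        assert overlap_index(a, b) == 0.5

    def test_symmetric_and_monotone(self):
        grid = toy_grid()
        a = dist_of(grid, range(10))
        for k in range(1, 10):
            b = dist_of(grid, range(k))
            assert overlap_index(a, b) == overlap_index(b, a)
        shares = [overlap_index(a, dist_of(grid, range(k))) for k in (2, 5, 8)]
        # growing shared subset of fixed a -> growing overlap
        assert shares == sorted(shares)


class TestSubsampling:
    def test_replicate_count_and_determinism(self, small_bundle):
        b = small_bundle
        species = b.tree.tip_names[0]
        ids = b.occurrences[species]
        rep1 = subsample_stability(ids, b.modern, reps=20, seed=42)
        rep2 = subsample_stability(ids, b.modern, reps=20, seed=42)
        assert len(rep1) == 20
        assert rep1.equals(rep2)

    def test_full_hull_models_contain_their_training_points(self, small_bundle):
        b = small_bundle
        species = b.tree.tip_names[1]
        ids = b.occurrences[species]
        rep = subsample_stability(ids, b.modern, method="bioclim100",
                                  fraction=0.5, reps=10, seed=1)
        # a min/max hull always re-includes every training point
        assert (rep["n_model"] >= int(round(0.5 * len(ids)))).all()

    def test_tiny_fraction_rejected(self, small_bundle):
        b = small_bundle
        ids = list(b.occurrences[b.tree.tip_names[0]])[:8]
        with pytest.raises(ValueError):
            subsample_stability(ids, b.modern, fraction=0.01, reps=2, seed=0)


class TestModelSelection:
    def test_exact_envelope_species_ranks_its_variant_first(self):
        grid = toy_grid(n=400, seed=9)
        env = fit_bioclim(grid.values[:150], (0, 100))
        occ = project_envelope(env, grid, "sp").member_ids
        ranking = select_best_model({"sp": occ}, grid)
        assert ranking.iloc[0]["variant"] == "bioclim100"
        assert ranking.iloc[0]["mean_overlap"] == 1.0

    def test_deterministic(self, small_bundle):
        b = small_bundle
        occ = {s: b.occurrences[s] for s in b.tree.tip_names}
        r1 = select_best_model(occ, b.modern)
        r2 = select_best_model(occ, b.modern)
        assert r1.equals(r2)
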