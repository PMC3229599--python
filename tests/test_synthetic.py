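"""Structure and determinism of the synthetic-data generators."""

import numpy as np
import pytest
from scipy import stats as sps

from paleophylo import (SyntheticScenario, ancestral_reconstruct, generate,
                        make_end_members, make_isotope_curve, make_ranges,
                        project_envelope, weight_from_isotope)
from paleophylo.synthetic import (make_fossils, make_tree_and_envelopes,
                                  simulate_bm_tips, simulate_ou_tips)
from paleophylo.pipeline import fossil_consistency


@pytest.fixture(scope="module")
def scenario():
    return SyntheticScenario(seed=13, n_points=400, n_slices=41, n_species=5)


class TestIsotopeCurve:
    def test_sample_count_and_monotone_ages(self, scenario):
        s = make_isotope_curve(scenario)
        assert s.n_samples == scenario.n_slices
        assert np.all(np.diff(s.ages_kya) > 0)
        assert s.ages_kya[0] == 0.0
        assert s.ages_kya[-1] == scenario.max_age_kya

    def test_anchor_weights_by_construction(self, scenario):
        s = make_isotope_curve(scenario)
        assert weight_from_isotope(s, s.modern_anchor_age).w == 0.0
        assert weight_from_isotope(s, s.glacial_anchor_age).w == 1.0
        assert abs(s.glacial_anchor_age - 21.0) < 5.0

    def test_glacial_cycles_present(self, scenario):
        s = make_isotope_curve(scenario)
        ws = np.array([weight_from_isotope(s, a).w for a in s.ages_kya])
        assert ws.max() > 1.0            # a glacial deeper than the anchor
        assert np.any((ws < 0.2) & (s.ages_kya > 100))  # later interglacials


class TestEndMembers:
    def test_mean_cooling_matches_target(self, scenario):
        modern, lgm = make_end_members(scenario)
        cooling = modern.mean_of("BIO1") - lgm.mean_of("BIO1")
        assert cooling == pytest.approx(scenario.glacial_cooling_c, abs=0.2)

    def test_precipitation_nonnegative_and_points_shared(self, scenario):
        modern, lgm = make_end_members(scenario)
        for g in (modern, lgm):
            precip = np.asarray(g.registry.precipitation_mask())
            assert np.nanmin(g.values[:, precip]) >= 0.0
        assert modern.same_points(lgm)

    def test_derived_variables_internally_consistent(self, scenario):
        modern, _ = make_end_members(scenario)
        bio5, bio6, bio7 = (modern.column(c) for c in ("BIO5", "BIO6", "BIO7"))
        bio2, bio3 = modern.column("BIO2"), modern.column("BIO3")
        assert np.allclose(bio7, bio5 - bio6)
        assert np.allclose(bio3, 100.0 * bio2 / bio7)

    def test_temperature_declines_with_latitude(self, scenario):
        modern, _ = make_end_members(scenario)
        r = sps.pearsonr(modern.lat, modern.column("BIO1"))[0]
        assert r < -0.9

    def test_ice_band_masks_high_latitudes(self):
        sc = SyntheticScenario(seed=13, n_points=400, ice_band=True)
        _, lgm = make_end_members(sc)
        iced = np.any(np.isnan(lgm.values), axis=1)
        assert iced.any()
        assert lgm.lat[iced].min() > lgm.lat[~iced].mean()


class TestTreeAndTraits:
    def test_ultrametric_with_requested_depth(self, scenario):
        modern, _ = make_end_members(scenario)
        tree, _, _ = make_tree_and_envelopes(scenario, modern)
        assert tree.is_ultrametric(tol=1e-9)
        assert tree.height == pytest.approx(scenario.tree_depth_my)
        assert tree.n_tips == scenario.n_species

    def test_zero_rate_keeps_tips_at_root(self):
        sc = SyntheticScenario(seed=21, n_points=400, n_species=4,
                               bm_rate_scale=0.0)
        modern, _ = make_end_members(sc)
        tree, envs, node_vals = make_tree_and_envelopes(sc, modern)
        root_lo = node_vals[("BIO1", "min")][0]
        for env in envs.values():
            assert env.lower_[0] == pytest.approx(root_lo)

    def test_reconstruction_error_shrinks_with_rate(self, scenario):
        modern, _ = make_end_members(scenario)
        errors = []
        for rate in (0.3, 0.03):
            sc = SyntheticScenario(seed=17, n_points=400, n_species=8,
                                   bm_rate_scale=rate)
            tree, envs, node_vals = make_tree_and_envelopes(sc, modern)
            tips = {n: float(envs[n].lower_[0]) for n in tree.tip_names}
            rec = ancestral_reconstruct(tree, tips)
            errors.append(abs(rec.value_at_node(0) - node_vals[("BIO1", "min")][0]))
        assert errors[1] < errors[0]


class TestRangesAndFossils:
    def test_noise_free_ranges_equal_projection(self, scenario):
        modern, _ = make_end_members(scenario)
        tree, envs, _ = make_tree_and_envelopes(scenario, modern)
        occ = make_ranges(modern, envs, occupancy_noise=0.0)
        for name, env in envs.items():
            expected = project_envelope(env, modern, name).member_ids
            assert set(occ[name].tolist()) == expected

    def test_occupancy_noise_within_binomial_bounds(self, scenario):
        modern, _ = make_end_members(scenario)
        tree, envs, _ = make_tree_and_envelopes(scenario, modern)
        name = tree.tip_names[0]
        n_suit = project_envelope(envs[name], modern, name).n_points
        occ = make_ranges(modern, {name: envs[name]}, occupancy_noise=0.5,
                          rng=np.random.default_rng(3))
        lo, hi = sps.binom.ppf([0.005, 0.995], n_suit, 0.5)
        assert lo <= len(occ[name]) <= hi

    def test_generated_fossils_all_consistent(self, small_bundle):
        from paleophylo.workflow import fit_tip_envelopes
        from paleophylo import build_timeseries, reconstruct_all
        b = small_bundle
        recon = reconstruct_all(b.tree, fit_tip_envelopes(b),
                                b.modern.registry.codes)
        ts = build_timeseries(recon, b.modern, b.lgm, b.isotopes, mode="both")
        union = ts.genus_union()
        fossils = make_fossils(ts.ages_kya, union, ts.grid, n_fossils=41, seed=5)
        assert len(fossils) == 41
        v = fossil_consistency(fossils, ts.ages_kya, union, ts.grid)
        assert (v["verdict"] == "consistent").all()
        # a fossil far north of the whole domain must fail the check
        moved = fossils.head(1).assign(lat=fossils["lat"].iloc[0] + 15.0)
        assert fossil_consistency(moved, ts.ages_kya, union,
                                  ts.grid)["verdict"].iloc[0] == "inconsistent"


class TestSimulators:
    def test_bm_marginal_variance(self, tree_factory):
        tree = tree_factory(2, seed=2, depth=4.0)
        draws = np.array([list(simulate_bm_tips(tree, rate=2.0, rng=s).values())
                          for s in range(400)])
        # marginal tip variance = rate^2 * depth
        assert np.var(draws[:, 0]) == pytest.approx(4.0 * 4.0, rel=0.3)

    def test_strong_ou_shrinks_to_optimum(self, tree_factory):
        tree = tree_factory(6, seed=3, depth=10.0)
        vals = np.array(list(simulate_ou_tips(tree, theta=5.0, sigma=1.0,
                                              optimum=2.0, root=50.0,
                                              rng=1).values()))
        assert np.all(np.abs(vals - 2.0) < 3.0)


class TestDeterminism:
    def test_bundle_reproducible_from_seed(self):
        sc = SyntheticScenario(seed=99, n_points=300, n_slices=11, n_species=4)
        b1, b2 = generate(sc), generate(sc)
        assert np.array_equal(b1.isotopes.delta18o, b2.isotopes.delta18o)
        assert np.array_equal(b1.modern.values, b2.modern.values)
        assert b1.tree.as_newick() == b2.tree.as_newick()
        for s in b1.occurrences:
            assert np.array_equal(b1.occurrences[s], b2.occurrences[s])
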