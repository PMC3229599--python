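"""Rectilinear and ellipsoidal climate envelopes."""

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.base import clone

from paleophylo import (BioclimEnvelope, MahalanobisEnvelope, ClimateGrid,
                        fit_bioclim, fit_ellipsoid, project_envelope)
from paleophylo.envelopes import envelope_from_json, envelope_to_json
from paleophylo.variables import VariableRegistry


def percentile_oracle(col, q):
    """Sort-and-linearly-interpolate percentile, written from scratch."""
    s = np.sort(col)
    pos = q / 100.0 * (len(s) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return s[lo] + (pos - lo) * (s[hi] - s[lo])


class TestBioclim:
    def test_single_training_point_degenerates_to_it(self):
        x = np.array([[1.0, 2.0, 3.0]])
        env = fit_bioclim(x, (5, 95))
        assert np.array_equal(env.lower_, x[0])
        assert np.array_equal(env.upper_, x[0])
        assert env.predict(x)[0]

    def test_integer_lattice_percentiles(self):
        vals = np.arange(21.0).reshape(-1, 1)  # 0..20
        env = fit_bioclim(vals, (5, 95))
        assert env.lower_[0] == pytest.approx(1.0)
        assert env.upper_[0] == pytest.approx(19.0)

    def test_bounds_match_independent_percentile_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(200, 3)) * [1.0, 10.0, 0.1]
        env = fit_bioclim(X, (5, 95))
        for j in range(3):
            assert env.lower_[j] == pytest.approx(percentile_oracle(X[:, j], 5))
            assert env.upper_[j] == pytest.approx(percentile_oracle(X[:, j], 95))

    def test_bounds_are_inclusive(self):
        env = BioclimEnvelope.from_bounds([0, 0, 0], [1, 1, 1])
        assert env.predict([[0.0, 1.0, 0.5]])[0]
        assert not env.predict([[0.0, 1.0001, 0.5]])[0]

    def test_missing_values_never_suitable(self):
        env = BioclimEnvelope.from_bounds([0.0], [1.0])
        assert not env.predict([[np.nan]])[0]

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            fit_bioclim(np.empty((0, 3)))

    def test_rect_membership_affine_invariant(self):
        rng = np.random.default_rng(5)
        X_train = rng.normal(size=(50, 4))
        X_query = rng.normal(size=(200, 4))
        a = np.array([2.0, 0.5, 10.0, 1.0])   # positive scales
        b = np.array([-3.0, 7.0, 0.0, 100.0])
        m0 = fit_bioclim(X_train, (5, 95)).predict(X_query)
        m1 = fit_bioclim(X_train * a + b, (5, 95)).predict(X_query * a + b)
        assert np.array_equal(m0, m1)

    def test_json_round_trip(self, tmp_path):
        env = fit_bioclim(np.random.default_rng(0).normal(size=(30, 5)))
        path = tmp_path / "env.json"
        envelope_to_json(env, path)
        back = envelope_from_json(path)
        assert np.allclose(back.lower_, env.lower_)
        assert np.allclose(back.upper_, env.upper_)

    def test_sklearn_clone_contract(self):
        env = BioclimEnvelope(percentile_low=2.5, percentile_high=97.5)
        assert clone(env).get_params() == env.get_params()


class TestEllipsoid:
    def test_constant_training_regularized(self):
        X = np.tile([1.0, 2.0], (100, 1))
        env = fit_ellipsoid(X)
        assert np.allclose(env.location_, [1.0, 2.0])
        assert np.allclose(env.scatter_, 1e-8 * np.eye(2))

    def test_center_and_scatter_recovered_monte_carlo(self):
        rng = np.random.default_rng(99)
        X = rng.standard_normal((5000, 2))
        env = fit_ellipsoid(X)
        assert np.all(np.abs(env.location_) < 0.1)
        assert np.all(np.abs(env.scatter_ - np.eye(2)) < 0.15)
        assert np.allclose(env.location_, X.mean(axis=0))

    def test_center_has_p_one(self):
        env = fit_ellipsoid(np.random.default_rng(1).normal(size=(50, 3)))
        ok, p = (env.predict([env.location_]), env.score_samples([env.location_]))
        assert p[0] == pytest.approx(1.0)
        assert ok[0]

    def test_chi_square_tail_one_dimensional(self):
        # variance 1, squared distance 3.841 -> p ~ 0.05 -> unsuitable at 0.1
        env = MahalanobisEnvelope(p_threshold=0.1)
        env.location_ = np.array([0.0])
        env.scatter_ = np.array([[1.0]])
        env.precision_ = np.array([[1.0]])
        env.n_features_in_ = 1
        x = np.array([[np.sqrt(3.841)]])
        assert env.score_samples(x)[0] == pytest.approx(
            sps.chi2.sf(3.841, 1), abs=1e-12)
        assert env.score_samples(x)[0] == pytest.approx(0.05, abs=5e-4)
        assert not env.predict(x)[0]

    def test_threshold_monotone_membership(self):
        rng = np.random.default_rng(17)
        X_train = rng.normal(size=(100, 3))
        X_query = rng.normal(size=(500, 3)) * 1.5
        members = []
        for thr in (0.1, 0.2, 0.3, 0.4, 0.5):
            env = fit_ellipsoid(X_train, p_threshold=thr)
            members.append(set(np.flatnonzero(env.predict(X_query))))
        for tight, loose in zip(members[1:], members[:-1]):
            assert tight <= loose


class TestProjection:
    @pytest.fixture
    def grid(self):
        rng = np.random.default_rng(23)
        reg = VariableRegistry.from_codes(["BIO1", "BIO12"])
        return ClimateGrid(np.arange(500), rng.uniform(-120, -70, 500),
                           rng.uniform(20, 50, 500),
                           np.column_stack([rng.normal(10, 8, 500),
                                            rng.normal(800, 300, 500)]), reg)

    def test_projection_equals_brute_force_loop(self, grid):
        rng = np.random.default_rng(29)
        env = fit_bioclim(np.column_stack([rng.normal(10, 4, 40),
                                           rng.normal(800, 150, 40)]), (5, 95))
        dist = project_envelope(env, grid, "x")
        expected = set()
        for i in range(grid.n_points):  # per-point oracle loop
            row = grid.values[i]
            if np.all(row >= env.lower_) and np.all(row <= env.upper_):
                expected.add(int(grid.point_ids[i]))
        assert dist.member_ids == expected

    def test_all_points_suitable_under_their_own_hull(self, grid):
        env = fit_bioclim(grid.values, (0, 100))
        dist = project_envelope(env, grid, "x")
        assert dist.member_ids == set(grid.point_ids.tolist())

    def test_impossible_bounds_give_empty_distribution(self, grid):
        env = BioclimEnvelope.from_bounds([1e6, 1e6], [1e6 + 1, 1e6 + 1])
        assert project_envelope(env, grid, "x").is_empty

    def test_trimmed_envelope_nested_in_full_envelope(self, grid):
        rng = np.random.default_rng(31)
        train = np.column_stack([rng.normal(10, 6, 80),
                                 rng.normal(800, 250, 80)])
        m95 = project_envelope(fit_bioclim(train, (5, 95)), grid, "x").member_ids
        m100 = project_envelope(fit_bioclim(train, (0, 100)), grid, "x").member_ids
        assert m95 <= m100

    def test_generated_range_refits_to_generating_bounds(self, small_bundle):
        """Occurrences thresholded from a known envelope refit close to it."""
        b = small_bundle
        species = b.tree.tip_names[0]
        env_true = b.tip_envelopes[species]
        ids = b.occurrences[species]
        X = b.modern.values[b.modern.index_of_ids(ids)]
        refit = fit_bioclim(X, (0, 100))
        # min/max refit stays inside the generating box
        assert np.all(refit.lower_ >= env_true.lower_ - 1e-9)
        assert np.all(refit.upper_ <= env_true.upper_ + 1e-9)
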