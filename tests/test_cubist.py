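"""Rule-tree tests: hand-worked induction examples, exhaustive-search split
oracle, partition properties, and serialization round trips."""

import numpy as np
import pytest

from ecorestore.cubist import CubistModel, best_split, fit_cubist_layer, fit_tree


def brute_force_best_split(X, y, min_leaf):
    """Exhaustive SDR search over every feature and midpoint threshold."""
    n = len(y)
    parent_sd = y.std()
    best = None
    for k in range(X.shape[1]):
        for thr in np.unique(
            (np.sort(np.unique(X[:, k]))[:-1] + np.sort(np.unique(X[:, k]))[1:]) / 2
        ):
            left = X[:, k] <= thr
            nl, nr = left.sum(), n - left.sum()
            if nl < min_leaf or nr < min_leaf:
                continue
            sdr = parent_sd - (nl * y[left].std() + nr * y[~left].std()) / n
            if best is None or sdr > best[0] + 1e-15:
                best = (sdr, k, thr)
    return best


class TestFitTree:
    def test_four_point_hand_example(self):
        # brute-force SDR picks the 2.5 split; leaf OLS gives y=x left,
        # y=7+x right
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([1.0, 2.0, 10.0, 11.0])
        model = fit_tree(X, y, min_leaf=1, max_rules=2, feature_dim=4)
        assert len(model.rules) == 2
        assert model.split_stats[0]["threshold"] == pytest.approx(2.5)
        left, right = sorted(model.rules, key=lambda r: r.conditions[0][1])
        np.testing.assert_allclose(left.coefficients, [0.0, 1.0], atol=1e-9)
        np.testing.assert_allclose(right.coefficients, [7.0, 1.0], atol=1e-9)
        assert model.predict(np.array([3.5])) == pytest.approx(10.5, abs=1e-9)

    def test_constant_target_single_intercept_rule(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        y = np.full(10, 5.0)
        model = fit_tree(X, y, min_leaf=1, max_rules=8)
        assert len(model.rules) == 1
        assert model.predict(np.array([123.0])) == pytest.approx(5.0)

    def test_max_rules_one_equals_global_ols(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(size=50)
        model = fit_tree(X, y, min_leaf=5, max_rules=1)
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(50), X]), y, rcond=None
        )
        for x in rng.normal(size=(20, 3)):
            assert abs(
                model.predict(x) - (coef[0] + x @ coef[1:])
            ) < 1e-10

    def test_small_sample_falls_back_to_global_model(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 2.0])
        model = fit_tree(X, y, min_leaf=20, max_rules=14)
        assert len(model.rules) == 1

    def test_boundary_value_routes_left(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0.0, 0.0, 10.0, 10.0])
        model = fit_tree(X, y, min_leaf=1, max_rules=2)
        thr = model.split_stats[0]["threshold"]
        left = [r for r in model.rules if r.conditions[0][1] == thr][0]
        assert left.matches(np.array([thr]))

    @pytest.mark.parametrize("seed", range(10))
    def test_root_split_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 200))
        d = int(rng.integers(1, 4))
        X = np.round(rng.normal(size=(n, d)), 1)  # duplicates likely
        y = rng.normal(size=n) + X[:, 0] ** 2
        min_leaf = 5
        want = brute_force_best_split(X, y, min_leaf)
        got = best_split(X, y, min_leaf)
        assert (got is None) == (want is None)
        if got is not None:
            assert got[1] == want[1]
            assert got[2] == pytest.approx(want[2])
            assert got[0] == pytest.approx(want[0])

    def test_monotone_fit_quality(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 4))
        y = np.sin(X[:, 0] * 2) + X[:, 1] + rng.normal(scale=0.1, size=300)
        rmse = {}
        for mr in (1, 14):
            model = fit_tree(X, y, min_leaf=10, max_rules=mr)
            rmse[mr] = np.sqrt(np.mean((model.predict_rows(X) - y) ** 2))
        assert rmse[14] <= rmse[1] + 1e-12

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(120, 3))
        y = X[:, 0] * 2 + rng.normal(size=120)
        m1 = fit_tree(X, y, min_leaf=10, max_rules=6)
        perm = rng.permutation(120)
        m2 = fit_tree(X[perm], y[perm], min_leaf=10, max_rules=6)
        assert len(m1.rules) == len(m2.rules)
        probe = rng.normal(size=(50, 3))
        np.testing.assert_allclose(
            m1.predict_rows(probe), m2.predict_rows(probe), atol=1e-8
        )

    def test_missing_values_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="missing"):
            fit_tree(X, np.array([1.0, 2.0]), min_leaf=1)


class TestPartitionProperty:
    @pytest.mark.parametrize("seed", range(5))
    def test_every_point_matches_exactly_one_rule(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(200, 3))
        y = X[:, 0] + np.abs(X[:, 1]) + rng.normal(scale=0.2, size=200)
        model = fit_tree(X, y, min_leaf=10, max_rules=8)
        for x in rng.normal(size=(100, 3)) * 2:
            matches = sum(r.matches(x) for r in model.rules)
            assert matches == 1

    def test_indicator_block_sums_to_at_most_one(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 2))
        y = X[:, 0] ** 2 + rng.normal(scale=0.1, size=200)
        model = fit_tree(X, y, min_leaf=10, max_rules=10, feature_dim=8)
        # only 6 indicator slots for up to 10 rules: sums are 0 or 1
        F = model.featurize_rows(rng.normal(size=(100, 2)))
        sums = F[:, :-2].sum(axis=1)
        assert set(np.round(sums).astype(int)) <= {0, 1}


class TestRuleFeatures:
    def make_two_rule_model(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([1.0, 2.0, 10.0, 11.0])
        return fit_tree(X, y, min_leaf=1, max_rules=2, feature_dim=4)

    def test_layout_indicator_then_predictions(self):
        model = self.make_two_rule_model()
        F = model.rule_features(np.array([1.5]))
        assert F.shape == (4,)
        assert set(F[:2]) <= {0.0, 1.0} and F[:2].sum() == 1.0
        # last two slots are the standardized local and global predictions
        local = (model.predict(np.array([1.5])) - model.target_mean) / model.target_std
        assert F[2] == pytest.approx(local)

    def test_zero_padding_when_fewer_rules_than_slots(self):
        model = self.make_two_rule_model()
        model.feature_dim = 6
        model._indicator_rules = [0, 1]
        F = model.rule_features(np.array([3.0]))
        assert F.shape == (6,)
        assert F[2] == 0.0 and F[3] == 0.0  # unused indicator slots

    def test_featurize_windows_shape_and_row_independence(self):
        model = self.make_two_rule_model()
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 5, size=(5, 2, 1))
        F = model.featurize_windows(X)
        assert F.shape == (5, 2, 4)
        perm = np.array([3, 1, 4, 0, 2])
        np.testing.assert_array_equal(model.featurize_windows(X[perm]), F[perm])

    def test_prediction_slots_consistent_with_predict(self):
        model = self.make_two_rule_model()
        xs = np.array([[1.0], [2.2], [3.7]])
        F = model.featurize_rows(xs)
        for i, x in enumerate(xs):
            assert F[i, -2] == pytest.approx(
                (model.predict(x) - model.target_mean) / model.target_std
            )


class TestFitCubistLayer:
    def test_flattening_counts_and_determinism(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 30, 2))
        y = rng.normal(size=10)
        m1 = fit_cubist_layer(X, y, min_leaf=20, max_rules=4, feature_dim=6)
        m2 = fit_cubist_layer(X, y, min_leaf=20, max_rules=4, feature_dim=6)
        assert sum(r.coverage for r in m1.rules) == 300
        assert m1.to_dict() == m2.to_dict()


class TestSerialization:
    def test_json_round_trip_reproduces_predictions(self, tmp_path):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(150, 3))
        y = X[:, 0] - X[:, 2] ** 2 + rng.normal(scale=0.1, size=150)
        model = fit_tree(X, y, min_leaf=10, max_rules=6)
        path = tmp_path / "cubist.json"
        model.to_json(path)
        loaded = CubistModel.from_json(path)
        probe = rng.normal(size=(80, 3))
        np.testing.assert_array_equal(
            model.predict_rows(probe), loaded.predict_rows(probe)
        )
        np.testing.assert_array_equal(
            model.featurize_rows(probe), loaded.featurize_rows(probe)
        )
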