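import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dffs_qsar import (
    ADMETTable,
    ContingencyTable2x2,
    RegressorSpec,
    compute_attributions,
    fit_cascade_forest,
    fit_regressor,
    global_importance,
    phi_association_matrix,
    phi_coefficient,
)
from dffs_qsar.interpret import AttributionMatrix
from dffs_qsar._treeshap import tree_shap_values, _sklearn_tree_arrays

from oracles import brute_force_shapley, phi_by_hand


class TestPhiCoefficient:
    def test_worked_example(self):
        res = phi_coefficient(ContingencyTable2x2(n11=40, n10=10, n01=10, n00=40))
        assert res.phi == pytest.approx(0.6)
        assert res.chi2 == pytest.approx(36.0)
        assert res.stars == "***"

    def test_independence_gives_zero(self):
        res = phi_coefficient(ContingencyTable2x2(25, 25, 25, 25))
        assert res.phi == 0.0

    def test_perfect_association(self):
        res = phi_coefficient(ContingencyTable2x2(n11=30, n10=0, n01=0, n00=30))
        assert res.phi == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            phi_coefficient(ContingencyTable2x2(n11=10, n10=5, n01=0, n00=0))

    @given(st.tuples(*[st.integers(1, 200)] * 4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_chi2_identity_and_hand_formula(self, cells):
        n11, n10, n01, n00 = cells
        t = ContingencyTable2x2(n11, n10, n01, n00)
        res = phi_coefficient(t)
        assert res.phi == pytest.approx(phi_by_hand(n11, n10, n01, n00), rel=1e-12)
        assert res.chi2 == pytest.approx(t.n * res.phi**2, rel=1e-12)
        assert -1.0 <= res.phi <= 1.0

    def test_label_swap_negates_phi(self, rng):
        for _ in range(50):
            a = rng.integers(0, 2, 100)
            b = rng.integers(0, 2, 100)
            t = ContingencyTable2x2.from_labels(a, b)
            t_swapped = ContingencyTable2x2.from_labels(1 - a, b)
            try:
                res, res_s = phi_coefficient(t), phi_coefficient(t_swapped)
            except ValueError:
                continue
            assert res_s.phi == pytest.approx(-res.phi, rel=1e-12, abs=1e-12)


class TestPhiMatrix:
    def test_identical_properties_have_unit_phi(self, rng):
        a = rng.integers(0, 2, 200)
        cols = np.column_stack([a, a, rng.integers(0, 2, 200),
                                rng.integers(0, 2, 200), rng.integers(0, 2, 200)])
        table = ADMETTable([f"c{i}" for i in range(200)], cols)
        res = phi_association_matrix(table)
        assert res.phi.iloc[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(res.phi.to_numpy()), 1.0)

    def test_independent_properties_near_zero(self, rng):
        cols = rng.integers(0, 2, size=(10000, 5))
        table = ADMETTable([f"c{i}" for i in range(10000)], cols)
        res = phi_association_matrix(table)
        off = res.phi.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) <= 0.05

    def test_symmetry(self, small_dataset):
        _, _, admet, _ = small_dataset
        res = phi_association_matrix(admet)
        assert np.allclose(res.phi.to_numpy(), res.phi.to_numpy().T, equal_nan=True)

    def test_constant_property_reported_undefined(self, rng):
        cols = rng.integers(0, 2, size=(100, 5))
        cols[:, 2] = 1
        table = ADMETTable([f"c{i}" for i in range(100)], cols)
        res = phi_association_matrix(table)
        assert "hERG" in res.undefined
        assert np.isnan(res.phi.iloc[2, 0])


class TestAttributions:
    @pytest.fixture(scope="class")
    def regression_data(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(250, 8))
        y = (
            2.0 * X[:, 0]
            - 1.0 * X[:, 1]
            + np.sin(X[:, 2])
            + 0.1 * rng.normal(size=250)
        )
        return X, y

    @pytest.mark.parametrize(
        "family", ["bagged_forest", "boosted_trees", "hist_boosted_trees"]
    )
    def test_local_accuracy_every_family(self, regression_data, family):
        X, y = regression_data
        model = fit_regressor(RegressorSpec(family, seed=0), X, y)
        attr = compute_attributions(model, X[:60])
        total = attr.attributions.sum(axis=1) + attr.base_value
        assert np.allclose(total, model.predict(X[:60]), atol=1e-6)

    def test_local_accuracy_single_layer_cascade(self, regression_data):
        X, y = regression_data
        model = fit_cascade_forest(
            X, y, layer_spec={"n_estimators_per_forest": 15}, max_layers=1, seed=0
        )
        attr = compute_attributions(model, X[:30])
        total = attr.attributions.sum(axis=1) + attr.base_value
        assert np.allclose(total, model.predict(X[:30]), atol=1e-6)

    def test_brute_force_shapley_equivalence(self, rng):
        from sklearn.tree import DecisionTreeRegressor

        for trial in range(10):
            X = rng.normal(size=(60, 3))
            y = X[:, 0] + 0.5 * X[:, 1] * X[:, 2] + 0.1 * rng.normal(size=60)
            tree = DecisionTreeRegressor(max_depth=3, random_state=trial).fit(X, y)
            arrays = _sklearn_tree_arrays(tree)
            Xq = rng.normal(size=(4, 3))
            phi, _ = tree_shap_values(*arrays, Xq, 3)
            for i in range(4):
                assert np.allclose(
                    phi[i], brute_force_shapley(arrays, Xq[i], 3), atol=1e-10
                )

    def test_agrees_with_native_boosting_attributions(self, regression_data):
        # dual route: the in-package recursion on the extracted trees must
        # agree with the boosting library's own attribution predictor on the
        # very same model (to the library's float32 output precision)
        import xgboost as xgb

        X, y = regression_data
        model = fit_regressor(RegressorSpec("boosted_trees", seed=0), X, y)
        attr = compute_attributions(model, X[:50])
        native = model.get_booster().predict(
            xgb.DMatrix(X[:50]), pred_contribs=True
        )
        assert np.allclose(attr.attributions, native[:, :-1], atol=1e-4)
        assert attr.base_value == pytest.approx(float(native[0, -1]), abs=1e-4)

    def test_deeper_tree_local_accuracy_exact(self, regression_data):
        from sklearn.tree import DecisionTreeRegressor

        X, y = regression_data
        tree = DecisionTreeRegressor(max_depth=5, random_state=0).fit(X, y)
        attr = compute_attributions(tree, X[:40])
        total = attr.attributions.sum(axis=1) + attr.base_value
        assert np.allclose(total, tree.predict(X[:40]), atol=1e-10)

    def test_unused_descriptor_gets_zero_attribution(self, rng):
        X = rng.normal(size=(200, 3))
        X[:, 2] = rng.normal(size=200)
        y = 2.0 * X[:, 0]  # only feature 0 matters, exactly
        from sklearn.tree import DecisionTreeRegressor

        tree = DecisionTreeRegressor(max_depth=4, random_state=0).fit(X, y)
        used = set(tree.tree_.feature[tree.tree_.feature >= 0])
        attr = compute_attributions(tree, X[:50], check_tol=1e-8)
        for j in range(3):
            if j not in used:
                assert np.allclose(attr.attributions[:, j], 0.0)

    def test_unsupported_model_rejected(self, regression_data):
        from sklearn.svm import SVR

        X, y = regression_data
        model = SVR().fit(X, y)
        with pytest.raises(TypeError, match="not defined"):
            compute_attributions(model, X[:5])


class TestGlobalImportance:
    def test_all_zero_attributions(self):
        a = AttributionMatrix(["c1", "c2"], ["d1", "d2"], np.zeros((2, 2)), 5.0)
        ranking, export = global_importance(a)
        assert ranking.descriptor_names == ["d1", "d2"]
        assert np.all(ranking.mean_abs_attribution == 0.0)
        assert len(export) == 4

    def test_dominant_column_ranked_first(self):
        attr = np.zeros((4, 3))
        attr[:, 1] = [1.0, -1.0, 1.0, -1.0]
        a = AttributionMatrix(
            [f"c{i}" for i in range(4)], ["a", "b", "c"], attr, 0.0
        )
        ranking, _ = global_importance(a)
        assert ranking.descriptor_names[0] == "b"
        assert ranking.mean_abs_attribution[0] == pytest.approx(1.0)

    def test_stronger_planted_effect_ranks_higher(self):
        # F1 drives the target with twice the effect of F2
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(400, 4))
            y = 2.0 * X[:, 0] + 1.0 * X[:, 1] + 0.2 * rng.normal(size=400)
            model = fit_regressor(
                RegressorSpec("hist_boosted_trees", seed=seed), X, y
            )
            attr = compute_attributions(model, X[:150])
            ranking, _ = global_importance(attr)
            f1 = ranking.mean_abs_attribution[ranking.descriptor_names.index("f0")]
            f2 = ranking.mean_abs_attribution[ranking.descriptor_names.index("f1")]
            hits += f1 > f2
        assert hits == 10
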