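import numpy as np
import pytest

from dffs_qsar import (
    ConfusionCounts,
    StackingConfig,
    compute_auc,
    evaluate_classification,
    fit_stacking,
    gate_by_activity,
    metrics_from_confusion,
    predict_stacking,
)
from dffs_qsar.admet import _stratified_folds
from dffs_qsar.data_io import DescriptorMatrix

from oracles import loop_classification_metrics, pairwise_auc


class TestGate:
    def test_inclusive_keeps_boundary(self):
        preds = {"a": 5.9, "b": 6.0, "c": 7.2}
        gate = gate_by_activity(preds, inclusive=True)
        assert gate.n_retained == 2 and gate.n_rejected == 1

    def test_exclusive_drops_boundary(self):
        preds = {"a": 5.9, "b": 6.0, "c": 7.2}
        gate = gate_by_activity(preds, inclusive=False)
        assert gate.retained_ids == ["c"]

    def test_empty_input_ok(self):
        gate = gate_by_activity({})
        assert gate.n_retained == 0 and gate.n_rejected == 0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            gate_by_activity({"a": float("nan")})


class TestClassificationMetrics:
    def test_worked_example(self):
        m = metrics_from_confusion(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert m.accuracy == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)
        assert m.fpr == pytest.approx(1 / 6)

    def test_all_positive_predictions(self):
        y = np.array([1, 1, 0, 0])
        m, _ = evaluate_classification(y, np.ones(4, dtype=int))
        assert m.accuracy == pytest.approx(0.5)
        assert m.precision == pytest.approx(0.5)
        assert m.recall == pytest.approx(1.0)
        assert m.f1 == pytest.approx(2 / 3)

    def test_perfect_prediction(self):
        y = np.array([1, 0, 1, 0])
        m, counts = evaluate_classification(y, y, scores=y.astype(float))
        assert (m.accuracy, m.precision, m.recall, m.f1, m.fpr) == (1, 1, 1, 1, 0)
        assert m.auc == 1.0
        assert counts.n == 4

    def test_matches_loop_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 60))
            y = rng.integers(0, 2, n)
            yhat = rng.integers(0, 2, n)
            m, c = evaluate_classification(y, yhat)
            acc, prec, rec, f1, fpr = loop_classification_metrics(
                c.tp, c.fp, c.tn, c.fn
            )
            assert m.accuracy == pytest.approx(acc, rel=1e-12)
            assert m.precision == pytest.approx(prec, rel=1e-12)
            assert m.recall == pytest.approx(rec, rel=1e-12)
            assert m.f1 == pytest.approx(f1, rel=1e-12)
            assert m.fpr == pytest.approx(fpr, rel=1e-12)

    def test_zero_denominator_warns_and_reports_zero(self):
        y = np.array([0, 0, 0, 1])
        with pytest.warns(UserWarning, match="precision"):
            m, _ = evaluate_classification(y, np.zeros(4, dtype=int))
        assert m.precision == 0.0


class TestAUC:
    def test_worked_example(self):
        assert compute_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert compute_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert compute_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            scores = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            assert compute_auc(y, scores) == pytest.approx(
                pairwise_auc(y.tolist(), scores.tolist()), abs=1e-12
            )


class TestStratifiedFolds:
    def test_row_order_equivariance(self, rng):
        n = 120
        y = rng.integers(0, 2, n)
        ids = [f"c{i:03d}" for i in range(n)]
        folds = _stratified_folds(y, 5, seed=3, ids=ids)
        perm = rng.permutation(n)
        folds_perm = _stratified_folds(y[perm], 5, seed=3, ids=[ids[i] for i in perm])
        assert np.array_equal(folds_perm, folds[perm])

    def test_stratification_balanced(self, rng):
        y = np.r_[np.ones(40, dtype=int), np.zeros(160, dtype=int)]
        folds = _stratified_folds(y, 5, seed=0)
        for f in range(5):
            assert np.sum(y[folds == f]) == 8  # 40 positives dealt evenly


class TestStacking:
    @pytest.fixture(scope="class")
    def separable(self):
        rng = np.random.default_rng(17)
        n = 300
        values = rng.normal(size=(n, 6))
        z = values[:, 0] + values[:, 1] + 0.4 * rng.normal(size=n)
        y = (z > 0).astype(int)
        m = DescriptorMatrix(
            [f"c{i}" for i in range(n)], [f"d{j}" for j in range(6)], values
        )
        return m, y

    def test_meta_feature_count_equals_base_count(self, separable):
        m, y = separable
        cfg = StackingConfig(property="HOB", base_learners=("knn", "boosted_trees"),
                             folds=3, seed=0)
        model = fit_stacking(cfg, m, y)
        assert model.oof_meta_features.shape == (m.n_compounds, 2)

    def test_probabilities_bounded_and_labels_thresholded(self, separable):
        m, y = separable
        cfg = StackingConfig(property="MN", folds=3, seed=0)
        model = fit_stacking(cfg, m, y)
        proba, labels = predict_stacking(model, m)
        assert np.all((proba >= 0) & (proba <= 1))
        assert np.array_equal(labels, (proba >= 0.5).astype(int))

    def test_deterministic_under_seed(self, separable):
        m, y = separable
        cfg = StackingConfig(property="MN", folds=3, seed=9)
        p1 = fit_stacking(cfg, m, y).predict_proba(m)
        p2 = fit_stacking(cfg, m, y).predict_proba(m)
        assert np.array_equal(p1, p2)

    def test_out_of_fold_meta_features_ignore_own_row(self, separable):
        # the meta-feature for row i must come from base models whose
        # training folds exclude i: recompute one fold's model by hand
        m, y = separable
        cfg = StackingConfig(property="MN", base_learners=("knn", "bagged_forest"),
                             folds=3, seed=4)
        model = fit_stacking(cfg, m, y)
        folds = _stratified_folds(y, 3, seed=cfg.seed, ids=list(m.compound_ids))
        from dffs_qsar._seeds import child_seed
        from dffs_qsar.admet import _make_base

        f = 0
        tr = np.flatnonzero(folds != f)
        va = np.flatnonzero(folds == f)
        base = _make_base("knn", child_seed(cfg.seed, "knn:oof0"))
        base.fit(m.values[tr], y[tr])
        expected = base.predict_proba(m.values[va])[:, 1]
        assert np.allclose(model.oof_meta_features[va, 0], expected)

    def test_row_shuffle_permutes_meta_features(self, separable):
        m, y = separable
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n_compounds)
        m_perm = DescriptorMatrix(
            [m.compound_ids[i] for i in perm],
            list(m.descriptor_names),
            m.values[perm],
        )
        cfg = StackingConfig(property="MN", base_learners=("knn", "bagged_forest"),
                             folds=3, seed=4)
        meta = fit_stacking(cfg, m, y).oof_meta_features
        meta_perm = fit_stacking(cfg, m_perm, y[perm]).oof_meta_features
        assert np.allclose(meta_perm, meta[perm], atol=1e-10)

    def test_single_class_rejected(self, separable):
        m, _ = separable
        cfg = StackingConfig(property="MN", folds=3)
        with pytest.raises(ValueError, match="both classes"):
            fit_stacking(cfg, m, np.ones(m.n_compounds, dtype=int))

    def test_learns_separable_structure(self, separable):
        m, y = separable
        cfg = StackingConfig(property="Caco-2",
                             base_learners=("boosted_trees", "hist_boosted_trees"),
                             folds=3, seed=1)
        model = fit_stacking(cfg, m, y)
        rng = np.random.default_rng(99)
        values = rng.normal(size=(200, 6))
        z = values[:, 0] + values[:, 1] + 0.4 * rng.normal(size=200)
        y_new = (z > 0).astype(int)
        auc = compute_auc(y_new, model.predict_proba(values))
        assert auc >= 0.9
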