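"""Classification stack: SMOTE, split/scaling, reduction, grid search, evaluation."""

import numpy as np
import pytest

import locomo as lm
from locomo.errors import ConfigError, DomainError
from locomo.modeling import DEFAULT_GRIDS


def make_table(rng, counts: dict[str, int], p: int = 6, shift: float = 0.0) -> lm.CohortTable:
    X, y, ids = [], [], []
    for j, (label, n) in enumerate(sorted(counts.items())):
        X.append(rng.normal(loc=j * shift, size=(n, p)))
        y.extend([label] * n)
        ids.extend(f"{label}_{i}" for i in range(n))
    return lm.CohortTable(np.vstack(X), np.array(y), ids)


@pytest.fixture
def imbalanced_table(rng):
    return make_table(rng, {"NonLS": 47, "Stage1": 29, "Stage2": 49, "Young": 49})


class TestSmote:
    def test_equalises_all_classes_at_majority_count(self, imbalanced_table):
        out = lm.smote_balance(imbalanced_table, k=5, seed=0)
        assert out.class_counts() == {g: 49 for g in ("NonLS", "Stage1", "Stage2", "Young")}

    def test_minority_class_grows_from_29_to_49(self, imbalanced_table):
        out = lm.smote_balance(imbalanced_table, k=5, seed=0)
        assert out.class_counts()["Stage1"] == 49

    def test_original_rows_preserved_verbatim(self, imbalanced_table):
        out = lm.smote_balance(imbalanced_table, k=5, seed=0)
        n = len(imbalanced_table)
        np.testing.assert_array_equal(out.features[:n], imbalanced_table.features)
        np.testing.assert_array_equal(out.labels[:n], imbalanced_table.labels)

    def test_already_balanced_table_returned_unchanged(self, rng):
        table = make_table(rng, {"A": 10, "B": 10})
        assert lm.smote_balance(table, k=3, seed=0) is table

    def test_deterministic_under_seed(self, imbalanced_table):
        a = lm.smote_balance(imbalanced_table, k=5, seed=3)
        b = lm.smote_balance(imbalanced_table, k=5, seed=3)
        np.testing.assert_array_equal(a.features, b.features)

    def test_synthetic_points_interpolate_between_parents(self, rng):
        """With one class on a line, every synthetic row must stay on that
        segment (convex combination of two same-class neighbours)."""
        v = np.array([1.0, -2.0, 0.5, 3.0])
        line = np.linspace(0, 1, 8)[:, None] * v  # 8 collinear minority points
        X = np.vstack([line, rng.normal(10.0, 1.0, size=(20, 4))])
        y = np.array(["mino"] * 8 + ["majo"] * 20)
        table = lm.CohortTable(X, y, [str(i) for i in range(28)])
        out = lm.smote_balance(table, k=3, seed=0)
        synth = out.features[28:]
        assert (out.labels[28:] == "mino").all()
        # stays on the span of v and inside the class extent
        coords = synth @ v / (v @ v)
        np.testing.assert_allclose(synth, coords[:, None] * v, atol=1e-9)
        assert coords.min() >= -1e-9 and coords.max() <= 1.0 + 1e-9

    def test_class_smaller_than_k_rejected(self, rng):
        table = make_table(rng, {"A": 4, "B": 10})
        with pytest.raises(ConfigError, match="smaller k"):
            lm.smote_balance(table, k=5, seed=0)


class TestSplit:
    def test_test_row_count_is_ceiling_of_fraction(self, rng):
        table = make_table(rng, {"A": 5, "B": 5})
        train, test = lm.split(table, lm.PipelineConfig(test_fraction=0.2))
        assert len(test) == 2 and len(train) == 8

    def test_balanced_196_rows_give_40_test_rows_10_per_class(self, rng):
        table = make_table(rng, {c: 49 for c in "ABCD"})
        train, test = lm.split(table)
        assert len(test) == 40
        assert all(v == 10 for v in test.class_counts().values())
        assert set(train.ids).isdisjoint(test.ids)

    def test_same_seed_gives_identical_partition(self, rng):
        table = make_table(rng, {"A": 20, "B": 20})
        t1 = lm.split(table)
        t2 = lm.split(table)
        assert t1[0].ids == t2[0].ids and t1[1].ids == t2[1].ids

    def test_singleton_class_rejected(self, rng):
        table = make_table(rng, {"A": 1, "B": 10})
        with pytest.raises(ConfigError):
            lm.split(table)


class TestZscore:
    def test_train_statistics_only(self):
        train = lm.CohortTable(np.array([[1.0], [3.0]]), np.array(["a", "b"]), ["1", "2"])
        test = lm.CohortTable(np.array([[5.0]]), np.array(["a"]), ["3"])
        train_s, test_s, scaler = lm.zscore(train, test)
        np.testing.assert_allclose(train_s.features.ravel(), [-1.0, 1.0])
        np.testing.assert_allclose(test_s.features.ravel(), [3.0])  # (5-2)/1
        assert scaler.mean_[0] == 2.0

    def test_train_columns_centred_after_transform(self, rng):
        table = make_table(rng, {"A": 30, "B": 30})
        train, test = lm.split(table)
        train_s, _, _ = lm.zscore(train, test)
        np.testing.assert_allclose(train_s.features.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(train_s.features.std(axis=0), 1.0, atol=1e-12)

    def test_constant_columns_dropped_with_warning(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        table = lm.CohortTable(X, np.array(["a", "b"] * 10), [str(i) for i in range(20)],
                               feature_names=["f0", "f1", "f2"])
        train, test = lm.split(table)
        with pytest.warns(UserWarning, match="f1"):
            train_s, _, _ = lm.zscore(train, test)
        assert train_s.feature_names == ["f0", "f2"]

    def test_all_constant_matrix_rejected(self):
        t = lm.CohortTable(np.ones((4, 2)), np.array(["a", "a", "b", "b"]), list("abcd"))
        with pytest.raises(DomainError):
            lm.zscore(t, t)

    def test_leakage_contract_test_rows_do_not_influence_transforms(self, rng):
        """Perturbing the held-out rows must leave every fitted transform
        (scaler, PCA components, MI ranking) bit-identical."""
        table = make_table(rng, {"A": 30, "B": 30}, p=8, shift=2.0)
        train, test = lm.split(table)
        perturbed = lm.CohortTable(
            test.features + rng.normal(size=test.features.shape), test.labels, test.ids
        )
        _, _, scaler1 = lm.zscore(train, test)
        _, _, scaler2 = lm.zscore(train, perturbed)
        np.testing.assert_array_equal(scaler1.mean_, scaler2.mean_)
        np.testing.assert_array_equal(scaler1.scale_, scaler2.scale_)
        tr1, _, pca1 = lm.pca_reduce(*lm.zscore(train, test)[:2], 0.95)
        tr2, _, pca2 = lm.pca_reduce(*lm.zscore(train, perturbed)[:2], 0.95)
        np.testing.assert_array_equal(pca1.components_, pca2.components_)
        _, _, mi1 = lm.select_k_best_mi(train, test, k=4, seed=0)
        _, _, mi2 = lm.select_k_best_mi(train, perturbed, k=4, seed=0)
        np.testing.assert_array_equal(mi1, mi2)


class TestPca:
    def test_full_variance_retains_full_rank(self, rng):
        table = make_table(rng, {"A": 20, "B": 20}, p=5)
        train, test = lm.split(table)
        _, _, pca = lm.pca_reduce(train, test, 1.0)
        assert pca.n_components_ == 5

    def test_three_dim_subspace_recovered(self, rng):
        basis = rng.normal(size=(3, 10))
        coords = rng.normal(size=(60, 3)) * np.array([5.0, 3.0, 2.0])
        X = coords @ basis + 1e-4 * rng.normal(size=(60, 10))
        table = lm.CohortTable(X, np.array(["a", "b"] * 30), [str(i) for i in range(60)])
        train, test = lm.split(table)
        _, _, pca = lm.pca_reduce(train, test, 0.99)
        assert pca.n_components_ == 3

    def test_reconstruction_error_decreases_with_components(self, rng):
        X = rng.normal(size=(40, 8)) @ rng.normal(size=(8, 8))
        table = lm.CohortTable(X, np.array(["a", "b"] * 20), [str(i) for i in range(40)])
        train, test = lm.split(table)
        errors = []
        for k in (1, 3, 5, 8):
            tr, _, pca = lm.pca_reduce(train, test, k)
            recon = pca.inverse_transform(tr.features)
            errors.append(np.sum((recon - train.features) ** 2))
        assert errors == sorted(errors, reverse=True)
        assert errors[-1] == pytest.approx(0.0, abs=1e-18)

    def test_components_orthonormal(self, rng):
        table = make_table(rng, {"A": 30, "B": 30}, p=6)
        train, test = lm.split(table)
        _, _, pca = lm.pca_reduce(train, test, 0.95)
        gram = pca.components_ @ pca.components_.T
        np.testing.assert_allclose(gram, np.eye(pca.n_components_), atol=1e-10)

    def test_invalid_variance_rejected(self, rng):
        table = make_table(rng, {"A": 10, "B": 10})
        train, test = lm.split(table)
        with pytest.raises(ConfigError):
            lm.pca_reduce(train, test, 1.5)


class TestSelectKBestMi:
    def test_label_copy_ranks_first(self, rng):
        y = np.array(["a"] * 25 + ["b"] * 25)
        X = rng.normal(size=(50, 5))
        X[:, 2] = (y == "a").astype(float)  # the label itself as a feature
        table = lm.CohortTable(X, y, [str(i) for i in range(50)])
        train, test = lm.split(table)
        _, _, scores = lm.select_k_best_mi(train, test, k=1, seed=0)
        assert int(np.argmax(scores)) == 2

    def test_noise_scores_below_informative_feature(self, rng):
        y = np.array(["a"] * 30 + ["b"] * 30)
        X = rng.normal(size=(60, 4))
        X[:, 0] += 4.0 * (y == "a")
        table = lm.CohortTable(X, y, [str(i) for i in range(60)])
        train, test = lm.split(table)
        _, _, scores = lm.select_k_best_mi(train, test, k=2, seed=0)
        assert scores[0] > max(scores[1:])

    def test_k_equal_p_is_identity(self, rng):
        table = make_table(rng, {"A": 15, "B": 15}, p=4)
        train, test = lm.split(table)
        tr, te, _ = lm.select_k_best_mi(train, test, k=4, seed=0)
        np.testing.assert_array_equal(tr.features, train.features)
        np.testing.assert_array_equal(te.features, test.features)

    def test_k_out_of_range_rejected(self, rng):
        table = make_table(rng, {"A": 10, "B": 10}, p=4)
        train, test = lm.split(table)
        with pytest.raises(ConfigError):
            lm.select_k_best_mi(train, test, k=5, seed=0)


class TestGridSearch:
    def test_single_point_grid_returns_that_point(self, rng):
        table = make_table(rng, {"A": 20, "B": 20}, shift=3.0)
        _, best = lm.grid_search_train(table, "KNN", {"n_neighbors": [3]}, cv_folds=3)
        assert best == {"n_neighbors": 3}

    def test_linear_svm_separates_separable_classes(self, rng):
        table = make_table(rng, {"A": 25, "B": 25}, shift=10.0)
        model, _ = lm.grid_search_train(table, "SVM-lin", {"C": [1.0]}, cv_folds=5)
        assert lm.evaluate(model, table).accuracy == 1.0

    @pytest.mark.parametrize(
        "family,winner",
        [
            ("SVM-rbf", {"C": 10, "gamma": 0.001}),
            ("KNN", {"n_neighbors": 5, "weights": "distance"}),
            ("DT", {"criterion": "entropy", "max_depth": 12}),
            ("RF", {"bootstrap": False, "max_depth": None, "min_samples_leaf": 2,
                    "min_samples_split": 2, "n_estimators": 50}),
            ("GB", {"learning_rate": 0.01, "max_depth": 5, "min_samples_leaf": 1,
                    "min_samples_split": 10, "n_estimators": 600}),
            ("LR", {"C": 0.1, "penalty": "l2"}),
        ],
    )
    def test_reported_winners_are_representable_grid_points(self, family, winner):
        """Every published winning configuration is a point of the search grid."""
        grid = DEFAULT_GRIDS[family]
        for key, value in winner.items():
            assert value in grid[key], (family, key)

    def test_empty_grid_rejected(self, rng):
        table = make_table(rng, {"A": 10, "B": 10})
        with pytest.raises(ConfigError):
            lm.grid_search_train(table, "KNN", {"n_neighbors": []})

    def test_unknown_family_rejected(self, rng):
        table = make_table(rng, {"A": 10, "B": 10})
        with pytest.raises(ConfigError):
            lm.grid_search_train(table, "CNN", {"x": [1]})


class TestMlp:
    def test_default_funnel_widths(self, rng):
        table = make_table(rng, {"A": 20, "B": 20}, shift=5.0)
        model = lm.mlp_train(table, lm.MlpSpec(epochs=20), seed=0)
        assert tuple(model.hidden_layer_sizes) == (512, 256, 128, 64, 32)

    def test_separable_four_class_blobs_classified(self, rng):
        table = make_table(rng, {"A": 30, "B": 30, "C": 30, "D": 30}, p=6, shift=8.0)
        train, test = lm.split(table)
        model = lm.mlp_train(train, lm.MlpSpec(epochs=100, early_stopping=False), seed=0)
        assert lm.evaluate(model, test).accuracy >= 0.95

    def test_strong_l2_shrinks_weights(self, rng):
        table = make_table(rng, {"A": 25, "B": 25}, shift=4.0)
        spec = lm.MlpSpec(hidden_layers=(16, 8), epochs=80, early_stopping=False)
        free = lm.mlp_train(table, spec, seed=0)
        import dataclasses
        heavy = lm.mlp_train(table, dataclasses.replace(spec, l2=100.0), seed=0)
        norm = lambda m: sum(np.sum(w**2) for w in m.coefs_)
        assert norm(heavy) < norm(free)


class TestEvaluate:
    class FixedPredictor:
        def __init__(self, predictions):
            self.predictions = np.asarray(predictions)

        def predict(self, X):
            return self.predictions

    def test_perfect_predictions(self):
        y = np.array(["a", "b", "c"] * 5)
        test = lm.CohortTable(np.zeros((15, 2)), y, [str(i) for i in range(15)])
        report = lm.evaluate(self.FixedPredictor(y), test)
        assert report.accuracy == report.precision == report.recall == report.f1 == 1.0
        assert np.trace(report.confusion) == 15

    def test_three_class_confusion_matrix_against_hand_computation(self):
        """Confusion [[5,0,0],[1,4,0],[0,2,3]]: accuracy 12/15, weighted
        precision 5/6, recall 0.8, F1 (10/11 + 8/11 + 3/4)/3."""
        y_true = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        y_pred = np.array(["a"] * 5 + ["a"] + ["b"] * 4 + ["b"] * 2 + ["c"] * 3)
        test = lm.CohortTable(np.zeros((15, 2)), y_true, [str(i) for i in range(15)])
        report = lm.evaluate(self.FixedPredictor(y_pred), test)
        assert report.accuracy == pytest.approx(12 / 15)
        assert report.precision == pytest.approx((5 / 6 + 4 / 6 + 1.0) / 3)
        assert report.recall == pytest.approx((1.0 + 0.8 + 0.6) / 3)
        f1s = [10 / 11, 2 * (4 / 6 * 0.8) / (4 / 6 + 0.8), 2 * 0.6 / 1.6]
        assert report.f1 == pytest.approx(np.mean(f1s))
        np.testing.assert_array_equal(report.confusion, [[5, 0, 0], [1, 4, 0], [0, 2, 3]])

    def test_constant_predictor_on_balanced_classes(self):
        y = np.array(["a", "b", "c", "d"] * 5)
        test = lm.CohortTable(np.zeros((20, 2)), y, [str(i) for i in range(20)])
        report = lm.evaluate(self.FixedPredictor(np.array(["a"] * 20)), test)
        assert report.accuracy == 0.25

    def test_row_sums_match_per_class_test_counts(self, rng):
        table = make_table(rng, {"A": 20, "B": 16}, shift=5.0)
        train, test = lm.split(table)
        model, _ = lm.grid_search_train(train, "KNN", {"n_neighbors": [3]}, cv_folds=3)
        report = lm.evaluate(model, test)
        counts = test.class_counts()
        for cls, row in zip(report.classes, report.confusion):
            assert row.sum() == counts.get(cls, 0)


class TestRunClassification:
    def test_paper_order_balances_before_split(self, imbalanced_table):
        reports = lm.run_classification(
            imbalanced_table,
            lm.PipelineConfig(paper_order=True, pca_variance=0.95),
            models=["KNN"],
            seed=0,
        )
        assert "KNN" in reports

    def test_mi_route_selects_top_features(self, rng):
        table = make_table(rng, {"A": 30, "B": 30}, p=10, shift=3.0)
        reports = lm.run_classification(
            table,
            lm.PipelineConfig(pca_variance=None, select_k=4, smote_enabled=False),
            models=["LR"],
            seed=0,
        )
        assert reports["LR"].accuracy >= 0.9
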