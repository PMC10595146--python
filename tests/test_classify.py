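"""Dataset split, features, RF/SVM training, grid search, AND-ensemble."""

import numpy as np
import pytest

import flytrap as ft
from flytrap.classify import (
    DEFAULT_RF_GRID, ClassifierBundle, svm_dual_coefficients,
)
from flytrap.core import FlytrapError, SingleClassError


def _toy_dataset(n_per_class=50, seed=0, gap=120):
    """Linearly separable crops: dark patches vs light patches."""
    rng = np.random.default_rng(seed)
    crops, labels = [], []
    for label, base in (("olive_fly", 40), ("other_fly", 40 + gap)):
        for _ in range(n_per_class):
            patch = rng.integers(base, base + 30, (32, 32, 3)).astype(np.uint8)
            crops.append(patch)
            labels.append(label)
    return ft.LabelledDataset(crops=crops, labels3=labels)


class TestSplit:
    @pytest.mark.parametrize("total,expected", [
        (501, (451, 50)),
        (368, (332, 36)),
        (611, (550, 61)),
        (10, (9, 1)),
        (0, (0, 0)),
    ])
    def test_floor_arithmetic(self, total, expected):
        assert ft.split_counts([total], val_fraction=0.1) == [expected]

    def test_split_dataset_sizes_and_partitions(self):
        ds = _toy_dataset(55)
        train, val = ft.split_dataset(ds, val_fraction=0.1, seed=1)
        assert len(train) == 100 and len(val) == 10
        assert train.partition == "train" and val.partition == "validation"
        # stratified: 5 validation samples per class
        assert val.labels3.count("olive_fly") == 5

    def test_split_membership_seeded(self):
        ds = _toy_dataset(30)
        a = ft.split_dataset(ds, seed=7)[1]
        b = ft.split_dataset(ds, seed=7)[1]
        c = ft.split_dataset(ds, seed=8)[1]
        assert all(np.array_equal(x, y) for x, y in zip(a.crops, b.crops))
        assert not all(np.array_equal(x, y) for x, y in zip(a.crops, c.crops))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            ft.split_counts([10], val_fraction=0.0)


class TestFeaturize:
    def test_zero_patch_gives_zero_vector(self):
        vec = ft.featurize(np.zeros((32, 32, 3), np.uint8))
        assert vec.shape == (3072,)
        assert not vec.any()

    def test_deterministic_and_scaled(self):
        patch = np.full((32, 32, 3), 255, np.uint8)
        a, b = ft.featurize(patch), ft.featurize(patch)
        assert np.array_equal(a, b)
        assert a.max() == 1.0

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="32x32x3"):
            ft.featurize(np.zeros((16, 16, 3), np.uint8))


class TestTrainRF:
    def test_separable_data_perfect_training_accuracy(self):
        ds = _toy_dataset()
        rf = ft.train_rf(ds, ft.RFConfig(seed=0))
        X = np.stack([ft.featurize(c) for c in ds.crops])
        assert (rf.predict(X) == np.asarray(ds.labels2)).all()

    def test_seeded_determinism(self):
        ds = _toy_dataset(gap=40)
        X = np.stack([ft.featurize(c) for c in ds.crops])
        a = ft.train_rf(ds, ft.RFConfig(seed=5)).predict(X)
        b = ft.train_rf(ds, ft.RFConfig(seed=5)).predict(X)
        assert (a == b).all()

    def test_single_estimator_equals_its_tree(self):
        ds = _toy_dataset(gap=40)
        rf = ft.train_rf(ds, ft.RFConfig(n_estimators=1, seed=2))
        X = np.stack([ft.featurize(c) for c in ds.crops])
        tree_vote = rf.estimators_[0].predict(X).astype(int)
        assert (rf.predict(X) == rf.classes_[tree_vote]).all()

    def test_single_class_labels_rejected(self):
        ds = ft.LabelledDataset(
            crops=[np.zeros((32, 32, 3), np.uint8)] * 4,
            labels3=["olive_fly"] * 4)
        with pytest.raises(SingleClassError, match="others"):
            ft.train_rf(ds)


class TestTrainSVM:
    def test_two_point_minimal_case(self):
        ds = ft.LabelledDataset(
            crops=[np.full((32, 32, 3), 20, np.uint8),
                   np.full((32, 32, 3), 220, np.uint8)],
            labels3=["olive_fly", "other_fly"])
        svm = ft.train_svm(ds, ft.SVMConfig(kernel="linear", C=1.0))
        X = np.stack([ft.featurize(c) for c in ds.crops])
        assert list(svm.predict(X)) == ["olive_fly", "others"]
        _, residual = svm_dual_coefficients(svm)
        assert abs(residual) < 1e-6

    def test_xor_pattern_with_polynomial_kernel(self):
        """The classical non-linearly-separable case: 4 points, XOR labels."""
        def patch(left, right):
            p = np.empty((32, 32, 3), np.uint8)
            p[:, :16] = left
            p[:, 16:] = right
            return p

        crops = [patch(50, 50), patch(200, 200), patch(50, 200),
                 patch(200, 50)]
        labels = ["olive_fly", "olive_fly", "other_fly", "other_fly"]
        ds = ft.LabelledDataset(crops=crops, labels3=labels)
        svm = ft.train_svm(ds, ft.SVMConfig(kernel="poly", C=10.0, gamma=1.0,
                                            degree=3))
        X = np.stack([ft.featurize(c) for c in crops])
        assert (svm.predict(X) == np.asarray(ds.labels2)).all()

    def test_dual_constraints_hold(self, bundle):
        alphas, residual = svm_dual_coefficients(bundle.svm)
        C = bundle.svm_config.C
        assert alphas.min() >= -1e-9
        assert alphas.max() <= C + 1e-9
        assert abs(residual) < 1e-6

    def test_non_finite_features_rejected(self):
        ds = _toy_dataset(5)
        with pytest.raises(ValueError, match="finite"):
            ft.train_svm(ft.LabelledDataset(
                crops=[np.full((32, 32, 3), np.nan)] + ds.crops[1:],
                labels3=ds.labels3))

    def test_single_class_rejected(self):
        ds = ft.LabelledDataset(
            crops=[np.zeros((32, 32, 3), np.uint8)] * 3,
            labels3=["other_fly"] * 3)
        with pytest.raises(SingleClassError):
            ft.train_svm(ds)


class TestGridSearch:
    def test_grid_of_size_one_returns_it(self):
        ds = _toy_dataset(20)
        best, table = ft.grid_search_cv(
            ds, "rf", {"n_estimators": [3], "max_depth": [5],
                       "min_samples_split": [2]}, k=2, seed=0)
        assert best == {"n_estimators": 3, "max_depth": 5,
                        "min_samples_split": 2}
        assert len(table) == 2  # 1 grid point x 2 folds

    def test_cv_table_bookkeeping(self):
        ds = _toy_dataset(15)
        grid = {"n_estimators": [1, 3], "max_depth": [2, 5],
                "min_samples_split": [2]}
        _, table = ft.grid_search_cv(ds, "rf", grid, k=3, seed=0)
        assert len(table) == 4 * 3
        assert set(table["fold"]) == {0, 1, 2}

    def test_winner_is_argmax_of_mean_accuracy(self):
        ds = _toy_dataset(25, gap=40)
        grid = {"n_estimators": [1, 3, 10], "max_depth": [20],
                "min_samples_split": [5]}
        best, table = ft.grid_search_cv(ds, "rf", grid, k=3, seed=1)
        means = table.groupby("n_estimators")["accuracy"].mean()
        assert means[best["n_estimators"]] == means.max()

    def test_tie_broken_toward_simpler_model(self):
        ds = _toy_dataset(20)  # fully separable: everything scores 1.0
        grid = {"n_estimators": [50, 3, 10], "max_depth": [20],
                "min_samples_split": [2]}
        best, _ = ft.grid_search_cv(ds, "rf", grid, k=2, seed=0)
        assert best["n_estimators"] == 3

    def test_small_class_fold_impossible(self):
        ds = ft.LabelledDataset(
            crops=[np.zeros((32, 32, 3), np.uint8)] * 6
            + [np.full((32, 32, 3), 200, np.uint8)] * 2,
            labels3=["olive_fly"] * 6 + ["other_fly"] * 2)
        with pytest.raises(FlytrapError, match="stratified"):
            ft.grid_search_cv(ds, "rf", DEFAULT_RF_GRID, k=5)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError, match="k"):
            ft.grid_search_cv(_toy_dataset(5), "rf", None, k=1)


class _StubTree:
    """Trees predict encoded class indices, unlike the forest."""

    def __init__(self, encoded):
        self._encoded = np.array(encoded)

    def predict(self, X):
        return self._encoded


class _StubRF:
    """Minimal forest: predicts a fixed vote sequence."""

    def __init__(self, votes):
        self.classes_ = np.array(["olive_fly", "others"])
        self._votes = np.array(votes)
        self.estimators_ = [
            _StubTree([0 if v == "olive_fly" else 1 for v in votes])]

    def predict(self, X):
        return self._votes


class _StubSVM:
    def __init__(self, votes):
        self.classes_ = np.array(["olive_fly", "others"])
        self._votes = np.array(votes)

    def predict(self, X):
        return self._votes

    def decision_function(self, X):
        return np.where(self._votes == "olive_fly", -1.0, 1.0)


class TestEnsemble:
    def test_and_rule_truth_table(self):
        """fly iff RF says fly AND SVM says fly."""
        rf_votes = ["olive_fly", "olive_fly", "others", "others"]
        svm_votes = ["olive_fly", "others", "olive_fly", "others"]
        stub = ClassifierBundle(rf=_StubRF(rf_votes), svm=_StubSVM(svm_votes))
        crops = [np.zeros((32, 32, 3), np.uint8)] * 4
        out = ft.ensemble_predict(stub, crops)
        assert list(out["ensemble"]) == ["olive_fly", "others", "others",
                                         "others"]
        assert list(out["rf_vote"]) != list(out["ensemble"])

    def test_rf_score_is_positive_tree_fraction(self):
        stub = ClassifierBundle(rf=_StubRF(["olive_fly", "others"]),
                                svm=_StubSVM(["olive_fly", "others"]))
        out = ft.ensemble_predict(stub, [np.zeros((32, 32, 3), np.uint8)] * 2)
        assert list(out["rf_score"]) == [1.0, 0.0]

    def test_set_inclusion_on_real_models(self, bundle, crop_dataset):
        votes = bundle.predict(crop_dataset.crops[:300])
        ens = votes["ensemble"] == "olive_fly"
        rf = votes["rf_vote"] == "olive_fly"
        svm = votes["svm_vote"] == "olive_fly"
        assert (ens <= (rf & svm)).all()

    def test_empty_input(self, bundle):
        assert len(bundle.predict([])) == 0


class TestBundlePersistence:
    def test_round_trip_predictions_identical(self, bundle, crop_dataset,
                                              tmp_path):
        path = tmp_path / "bundle.joblib"
        bundle.save(path)
        loaded = ClassifierBundle.load(path)
        batch = crop_dataset.crops[:100]
        a = bundle.predict(batch)
        b = loaded.predict(batch)
        assert a.equals(b)
        assert loaded.feature_pipeline == bundle.feature_pipeline

    def test_wrong_archive_rejected(self, tmp_path):
        import joblib
        path = tmp_path / "junk.joblib"
        joblib.dump({"schema": "other"}, path)
        with pytest.raises(FlytrapError, match="not a classifier bundle"):
            ClassifierBundle.load(path)


class TestParameterRecovery:
    def test_deployed_hyperparameters_recover_synthetic_classes(self, bundle,
                                                                split):
        """Default generator separation: both models >= 0.90 validation
        accuracy with the deployed hyperparameters."""
        _, val = split
        votes = bundle.predict(val.crops)
        y = np.asarray(val.labels2)
        assert (votes["rf_vote"].to_numpy() == y).mean() >= 0.90
        assert (votes["svm_vote"].to_numpy() == y).mean() >= 0.90
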