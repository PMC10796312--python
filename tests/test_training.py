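"""Splitting, early stopping, cross-validation and ensembling."""

import numpy as np
import pytest

from conftest import small_training_spec
from petnodule.augment import AugmentationPlan, ClassPlan
from petnodule.training import (CVResult, EnsembleModel, FoldSplit,
                                TrainConfig, build_ensemble, cross_validate,
                                repeat_cv, stratified_split, train_model)


def _toy_data(n=24, side=9, seed=0):
    """Tiny volumes whose centre intensity carries the class signal."""
    rng = np.random.default_rng(seed)
    tensors, labels = [], []
    for i in range(n):
        y = i % 2
        t = rng.normal(0.0, 0.1, size=(side, side, side))
        t[3:6, 3:6, 3:6] += 2.0 * y
        tensors.append(t)
        labels.append(y)
    return tensors, np.array(labels)


class TestStratifiedSplit:
    def test_study_cohort_partition_sizes(self):
        ids = [f"s{i}" for i in range(113)]
        labels = ["malignant"] * 51 + ["benign"] * 62
        split = stratified_split(ids, labels, seed=0)
        assert sorted(split.sizes(), reverse=True) == [23, 23, 23, 22, 22]

    def test_per_partition_class_counts_within_one_of_proportional(self):
        ids = [f"s{i}" for i in range(113)]
        labels = ["malignant"] * 51 + ["benign"] * 62
        split = stratified_split(ids, labels, seed=1)
        for k in range(5):
            part = split.partition_ids(k)
            n_mal = sum(labels[ids.index(s)] == "malignant" for s in part)
            assert abs(n_mal - 51 / 5) <= 1
            assert abs((len(part) - n_mal) - 62 / 5) <= 1

    def test_ten_subjects_give_five_balanced_pairs(self):
        ids = list("abcdefghij")
        labels = ["malignant"] * 5 + ["benign"] * 5
        split = stratified_split(ids, labels, seed=2)
        assert split.sizes() == [2, 2, 2, 2, 2]
        for k in range(5):
            part = split.partition_ids(k)
            assert sum(labels[ids.index(s)] == "malignant" for s in part) == 1

    def test_same_seed_reproduces_assignment(self):
        ids = [f"s{i}" for i in range(40)]
        labels = (["malignant"] * 18 + ["benign"] * 22)
        a = stratified_split(ids, labels, seed=7)
        b = stratified_split(ids, labels, seed=7)
        assert a.assignment == b.assignment

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            stratified_split(list("abcdefgh"),
                             ["malignant"] * 4 + ["benign"] * 4)

    def test_partitions_disjoint_and_exhaustive(self):
        ids = [f"s{i}" for i in range(33)]
        labels = ["malignant"] * 14 + ["benign"] * 19
        split = stratified_split(ids, labels, seed=3)
        seen = [s for k in range(5) for s in split.partition_ids(k)]
        assert sorted(seen) == sorted(ids)


class TestTrainModel:
    def test_constant_validation_loss_stops_after_patience(self):
        """With a vanishing learning rate the validation loss never
        improves after the first epoch, so training runs exactly
        1 + patience epochs."""
        tensors, labels = _toy_data()
        cfg = TrainConfig(learning_rate=1e-30, batch_size=8, l2_lambda=0.0,
                          max_epochs=50, patience=4, seed=0)
        model = train_model(small_training_spec(), tensors[:16], labels[:16],
                            tensors[16:], labels[16:], cfg)
        assert len(model.history["val_loss"]) == 1 + cfg.patience
        assert model.best_epoch == 0

    def test_training_loss_decreases_on_separable_data(self):
        tensors, labels = _toy_data()
        cfg = TrainConfig(learning_rate=0.01, batch_size=8, l2_lambda=0.0,
                          max_epochs=20, patience=19, seed=0)
        model = train_model(small_training_spec(), tensors[:16], labels[:16],
                            tensors[16:], labels[16:], cfg)
        assert model.history["train_loss"][-1] < \
            model.history["train_loss"][0]

    def test_identical_seeds_give_identical_histories(self):
        tensors, labels = _toy_data()
        cfg = TrainConfig(learning_rate=0.01, batch_size=8, l2_lambda=0.001,
                          max_epochs=6, patience=5, seed=3)
        runs = [train_model(small_training_spec(0.001), tensors[:16],
                            labels[:16], tensors[16:], labels[16:], cfg)
                for _ in range(2)]
        assert runs[0].history == runs[1].history
        for w0, w1 in zip(runs[0].network.get_weights(),
                          runs[1].network.get_weights()):
            np.testing.assert_array_equal(w0, w1)

    def test_restored_parameters_achieve_recorded_best_loss(self):
        tensors, labels = _toy_data()
        cfg = TrainConfig(learning_rate=0.02, batch_size=8, l2_lambda=0.0,
                          max_epochs=15, patience=14, seed=1)
        model = train_model(small_training_spec(), tensors[:16], labels[:16],
                            tensors[16:], labels[16:], cfg)
        assert model.history["val_loss"][model.best_epoch] == \
            min(model.history["val_loss"])

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            train_model(small_training_spec(), [], [], [], [], TrainConfig())


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def toy_cv(self):
        tensors, labels = _toy_data(n=25)
        ids = [f"s{i:02d}" for i in range(25)]
        split = stratified_split(ids, labels, seed=0)
        cfg = TrainConfig(learning_rate=0.01, batch_size=8, l2_lambda=0.0,
                          max_epochs=10, patience=9, seed=0)
        cv = cross_validate(small_training_spec(), tensors, labels, ids,
                            split, cfg)
        return cv, split, ids

    def test_four_folds_with_original_validation_counts(self, toy_cv):
        cv, split, _ = toy_cv
        assert len(cv.fold_aucs) == 4
        for k, val_ids in zip(split.cv_partitions, cv.fold_val_ids):
            assert sorted(val_ids) == sorted(split.partition_ids(k))

    def test_no_test_subject_enters_any_fold(self, toy_cv):
        cv, split, _ = toy_cv
        test = set(split.test_ids)
        for _fold, train_ids, val_ids in split.cv_folds():
            assert test.isdisjoint(train_ids)
            assert test.isdisjoint(val_ids)

    def test_signal_recovered_on_separable_toy_data(self, toy_cv):
        cv, _, _ = toy_cv
        assert cv.mean_auc > 0.8

    def test_mean_is_arithmetic_mean_of_folds(self):
        r = CVResult(fold_aucs=[0.79, 0.90, 0.88, 0.98], models=[None] * 4,
                     fold_val_ids=[[]] * 4)
        assert r.mean_auc == pytest.approx(0.8875)

    def test_augmentation_grows_training_not_validation(self):
        tensors, labels = _toy_data(n=20, side=9)
        ids = [f"s{i:02d}" for i in range(20)]
        split = stratified_split(ids, labels, seed=0)
        cfg = TrainConfig(learning_rate=0.01, batch_size=8, l2_lambda=0.0,
                          max_epochs=3, patience=2, seed=0)
        plan = AugmentationPlan(minority=ClassPlan(1, 1, {0.1: 1}),
                                majority=ClassPlan(1, 1, {0.1: 1}), seed=0)
        cv = cross_validate(small_training_spec(), tensors, labels, ids,
                            split, cfg, augment_plan=plan)
        per_subject = 1 + plan.minority.total  # classes share this plan
        assert cv.fold_train_sizes == [12 * per_subject] * 4
        assert all(len(v) == 4 for v in cv.fold_val_ids)


class TestRepeatCV:
    def test_single_iteration_equals_cross_validate(self):
        tensors, labels = _toy_data(n=20)
        ids = [f"s{i:02d}" for i in range(20)]
        split = stratified_split(ids, labels, seed=0)
        cfg = TrainConfig(learning_rate=0.01, batch_size=8, l2_lambda=0.0,
                          max_epochs=4, patience=3, seed=5)
        single = cross_validate(small_training_spec(), tensors, labels, ids,
                                split, cfg)
        rep = repeat_cv(small_training_spec(), tensors, labels, ids, split,
                        cfg, iterations=1)
        assert rep["mean_auc"] == pytest.approx(single.mean_auc)
        assert rep["sd_auc"] == 0.0


class _StubModel:
    def __init__(self, value):
        self.value = value
        self.norm_stats = None

    def predict_proba(self, x, **kw):
        return np.full(len(x), self.value)


def _split_with_sizes(sizes):
    assignment = {}
    i = 0
    for k, n in enumerate(sizes):
        for _ in range(n):
            assignment[f"s{i}"] = k
            i += 1
    return FoldSplit(assignment=assignment)


class TestEnsemble:
    def test_weights_proportional_to_training_sizes(self):
        # CV partitions of sizes 23, 23, 22, 22 -> train sizes 67,67,68,68
        split = _split_with_sizes([23, 23, 22, 22, 23])
        ens = build_ensemble([_StubModel(0.5)] * 4, split)
        np.testing.assert_allclose(
            ens.weights, np.array([67, 67, 68, 68]) / 270)
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_identical_models_equal_single_model(self):
        split = _split_with_sizes([5, 5, 5, 5, 5])
        ens = build_ensemble([_StubModel(0.73)] * 4, split)
        x = np.zeros((3, 40, 40, 40))
        np.testing.assert_allclose(ens.predict_proba(x), 0.73)

    def test_one_hot_fold_probabilities_average_to_quarter(self):
        split = _split_with_sizes([5, 5, 5, 5, 5])
        models = [_StubModel(v) for v in (1.0, 0.0, 0.0, 0.0)]
        ens = build_ensemble(models, split)
        np.testing.assert_allclose(ens.predict_proba(np.zeros((2, 4, 4, 4))),
                                   0.25)

    def test_wrong_model_count_rejected(self):
        split = _split_with_sizes([5, 5, 5, 5, 5])
        with pytest.raises(ValueError):
            build_ensemble([_StubModel(0.5)] * 3, split)
        with pytest.raises(ValueError):
            EnsembleModel(fold_models=[_StubModel(0.5)] * 4,
                          weights=np.array([0.5, 0.5, 0.25, 0.25]))
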