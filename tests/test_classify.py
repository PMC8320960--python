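"""Ensemble voting, stacking, ROC/AUC and cross-validation mechanics."""

from __future__ import annotations

import numpy as np
import pytest
from oracles import auc_pair_oracle

from mcclassify.classify import (
    EnsembleClassifier,
    StackedClassifier,
    cross_validate,
    ensemble_vote,
    make_base_learners,
    roc_auc,
)


def separable_data(rng: np.random.Generator, n=60, gap=6.0):
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 2)) + np.column_stack([y * gap, y * gap])
    idx = rng.permutation(n)
    return X[idx], y[idx]


class TestEnsembleVote:
    def test_eight_of_nine_is_89_percent(self):
        frac = ensemble_vote([1, 1, 1, 1, 1, 1, 1, 1, 0])
        assert frac == pytest.approx(8 / 9)
        assert round(100 * frac) == 89

    def test_extremes(self):
        assert ensemble_vote([0] * 9) == 0.0
        assert ensemble_vote([1] * 9) == 1.0

    def test_permutation_symmetric(self, rng):
        votes = np.array([1, 0, 1, 1, 0, 1, 0, 0, 1])
        base = ensemble_vote(votes)
        for _ in range(5):
            assert ensemble_vote(rng.permutation(votes)) == base

    def test_wrong_vote_count_rejected(self):
        with pytest.raises(ValueError):
            ensemble_vote([1, 0, 1])


class TestLearners:
    def test_nine_base_learners(self):
        assert len(make_base_learners(10)) == 9

    def test_separable_data_fits_perfectly(self, rng):
        X, y = separable_data(rng)
        model = StackedClassifier(random_state=1).fit(X, y)
        assert (model.predict(X) == y).all()
        model2 = EnsembleClassifier(random_state=1).fit(X, y)
        assert (model2.predict(X) == y).all()

    def test_meta_feature_matrix_shape(self, rng):
        X, y = separable_data(rng, n=40)
        model = StackedClassifier(random_state=1).fit(X, y)
        assert model.meta_features_.shape == (40, 9)

    def test_single_class_training_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.zeros(20, dtype=int)
        with pytest.raises(ValueError):
            StackedClassifier().fit(X, y)
        with pytest.raises(ValueError):
            EnsembleClassifier().fit(X, y)

    def test_adaboost_meta_works(self, rng):
        X, y = separable_data(rng)
        model = StackedClassifier(meta="adaboost", random_state=1).fit(X, y)
        assert (model.predict(X) == y).mean() > 0.9


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_worked_example_pair_counts(self):
        assert roc_auc([0.9, 0.8, 0.7, 0.4], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.9, 0.8, 0.7, 0.4], [1, 0, 1, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_pair_counting_oracle(self, trial):
        rng = np.random.default_rng(700 + trial)
        n = int(rng.integers(6, 30))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.uniform(size=n), 1)  # provoke ties
        assert roc_auc(scores, labels) == pytest.approx(
            auc_pair_oracle(scores, labels)
        )


class _ConstantModel:
    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.ones(len(X), dtype=int)

    def decision_function(self, X):
        return np.full(len(X), 0.5)


class TestCrossValidate:
    def test_constant_classifier_on_balanced_table(self, rng):
        X = rng.normal(size=(50, 3))
        y = np.repeat([0, 1], 25)
        report = cross_validate(X, y, lambda seed: _ConstantModel(),
                                seeds=range(1, 6))
        assert report.accuracy_mean == pytest.approx(50.0)
        assert report.accuracy_std == pytest.approx(0.0)
        assert report.auc_mean == pytest.approx(0.5)

    def test_loocv_fits_once_per_sample(self, rng):
        fits = []

        class Counting(_ConstantModel):
            def fit(self, X, y):
                fits.append(len(X))
                return self

        X = rng.normal(size=(12, 2))
        y = np.repeat([0, 1], 6)
        report = cross_validate(X, y, lambda seed: Counting(), scheme="loocv")
        assert len(fits) == 12
        assert all(n == 11 for n in fits)
        assert report.n_samples == 12

    def test_each_observation_tested_once_per_seed(self, rng):
        tested = []

        class Tracking(_ConstantModel):
            def predict(self, X):
                tested.append(len(X))
                return np.ones(len(X), dtype=int)

        X = rng.normal(size=(40, 2))
        y = np.repeat([0, 1], 20)
        cross_validate(X, y, lambda seed: Tracking(), seeds=[1, 2])
        assert sum(tested) == 2 * 40

    def test_fixed_seed_reproducible(self, rng):
        X, y = separable_data(rng, n=40, gap=2.0)
        r1 = cross_validate(X, y,
                            lambda seed: StackedClassifier(random_state=seed),
                            seeds=[1, 2])
        r2 = cross_validate(X, y,
                            lambda seed: StackedClassifier(random_state=seed),
                            seeds=[1, 2])
        assert r1.to_dict() == r2.to_dict()

    def test_permuted_labels_score_near_chance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 4))
        y = rng.permutation(np.repeat([0, 1], 100))
        report = cross_validate(
            X, y, lambda seed: StackedClassifier(random_state=seed), seeds=[1]
        )
        assert 40.0 <= report.accuracy_mean <= 60.0

    def test_small_class_reduces_folds_with_warning(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([1] * 4 + [0] * 16)
        with pytest.warns(UserWarning):
            report = cross_validate(X, y, lambda seed: _ConstantModel(),
                                    seeds=[1])
        assert report.n_samples == 20
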