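"""Base learners, majority-vote ensemble, stacked generalization, CV.

Nine base classifiers vote benign/malignant: k-nearest neighbours (k=5),
a multilayer perceptron ((n_features + n_classes)/2 hidden units,
learning rate 0.3, validation-based stopping after 20 non-improving
epochs), a pruned decision tree, a random forest, a Gaussian naive Bayes,
and four support-vector machines (RBF, sigmoid, linear and polynomial
kernels).  Beyond these printed settings all hyper-parameters stay at
library defaults.  Features are z-scored inside each learner's pipeline
for the scale-sensitive models (kNN, SVM, MLP), so scaling is always
fitted on training data only.

Two combiners are provided:

* **majority-vote ensemble** - the malignancy estimate is the fraction of
  the nine votes that say malignant (8 of 9 votes = 88.9%), thresholded
  at 1/2 (a tie is impossible with an odd count);
* **stacked generalization** - a meta-classifier (naive Bayes by default,
  AdaBoost optionally) is trained on the base learners' *out-of-fold*
  predictions, produced by an internal stratified 5-fold split of the
  training data so the meta-learner never sees resubstitution outputs.

Evaluation is stratified 10-fold cross-validation repeated over seeds
1..10 (the seed shuffles the fold assignment; every observation is tested
exactly once per seed run) or leave-one-out, reporting classification
accuracy (%) and the area under the ROC curve (Az) as mean +/- std over
the seed runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, cross_val_predict
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "BASE_LEARNER_NAMES",
    "EvalReport",
    "make_base_learners",
    "ensemble_vote",
    "EnsembleClassifier",
    "StackedClassifier",
    "roc_auc",
    "cross_validate",
]

N_BASE_LEARNERS = 9
BASE_LEARNER_NAMES = (
    "knn",
    "mlp",
    "tree",
    "random_forest",
    "naive_bayes",
    "svm_rbf",
    "svm_sigmoid",
    "svm_linear",
    "svm_poly",
)


def _scaled(est) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


class _ValidationStoppedMLP(MLPClassifier):
    """MLP whose validation-based stopping degrades gracefully.

    The stratified validation split needs at least one sample per class;
    on very small training folds the early stopping is skipped and the
    network simply trains for ``max_iter`` epochs.
    """

    def fit(self, X, y):
        n_val = int(len(X) * self.validation_fraction)
        classes, counts = np.unique(y, return_counts=True)
        if self.early_stopping and (n_val < len(classes) or counts.min() < 2):
            self.early_stopping = False
            try:
                return super().fit(X, y)
            finally:
                self.early_stopping = True
        return super().fit(X, y)


def make_base_learners(n_features: int, random_state: int = 0) -> dict:
    """The nine base learners with the paper-printed hyper-parameters."""
    hidden = max(1, math.ceil((n_features + 2) / 2))
    return {
        "knn": _scaled(KNeighborsClassifier(n_neighbors=5)),
        "mlp": _scaled(
            _ValidationStoppedMLP(
                hidden_layer_sizes=(hidden,),
                solver="sgd",
                learning_rate_init=0.3,
                momentum=0.2,
                early_stopping=True,
                n_iter_no_change=20,
                max_iter=300,
                random_state=random_state,
            )
        ),
        "tree": DecisionTreeClassifier(random_state=random_state),
        "random_forest": RandomForestClassifier(random_state=random_state),
        "naive_bayes": GaussianNB(),
        "svm_rbf": _scaled(SVC(kernel="rbf", random_state=random_state)),
        "svm_sigmoid": _scaled(SVC(kernel="sigmoid", random_state=random_state)),
        "svm_linear": _scaled(SVC(kernel="linear", random_state=random_state)),
        "svm_poly": _scaled(SVC(kernel="poly", random_state=random_state)),
    }


def ensemble_vote(predictions) -> float:
    """Malignancy estimate: fraction of the nine binary votes for malignant."""
    votes = np.asarray(predictions)
    if votes.ndim != 1 or votes.size != N_BASE_LEARNERS:
        raise ValueError(f"expected exactly {N_BASE_LEARNERS} votes")
    if not np.isin(votes, (0, 1)).all():
        raise ValueError("votes must be binary (0 = benign, 1 = malignant)")
    return float(votes.sum() / N_BASE_LEARNERS)


def _check_two_classes(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")


class EnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Majority vote of the nine base learners.

    ``decision_function`` returns the malignancy fraction in [0, 1];
    ``predict`` thresholds it at 1/2.
    """

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        _check_two_classes(y)
        self.classes_ = np.unique(y)
        self.learners_ = make_base_learners(X.shape[1], self.random_state)
        for est in self.learners_.values():
            est.fit(X, y)
        return self

    def _votes(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return np.column_stack(
            [est.predict(X) for est in self.learners_.values()]
        )

    def decision_function(self, X) -> np.ndarray:
        votes = self._votes(X) == self.classes_[1]
        return np.array([ensemble_vote(v.astype(int)) for v in votes])

    def predict(self, X) -> np.ndarray:
        frac = self.decision_function(X)
        return np.where(frac > 0.5, self.classes_[1], self.classes_[0])


class StackedClassifier(BaseEstimator, ClassifierMixin):
    """Stacked generalization over the nine base learners.

    Meta-features are the base learners' predictions on held-out portions
    of an internal stratified 5-fold split of the training data (stored as
    ``meta_features_``, shape ``(n_train, 9)``); the meta-learner (naive
    Bayes or AdaBoost) is fitted on them, and the base learners are then
    refitted on the full training set for prediction time.
    """

    def __init__(self, meta: str = "naive_bayes", random_state: int = 0,
                 inner_folds: int = 5):
        self.meta = meta
        self.random_state = random_state
        self.inner_folds = inner_folds

    def _make_meta(self):
        if self.meta in ("naive_bayes", "nb"):
            return GaussianNB()
        if self.meta in ("adaboost", "ada"):
            return AdaBoostClassifier(random_state=self.random_state)
        raise ValueError(f"unknown meta-learner {self.meta!r}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        _check_two_classes(y)
        self.classes_ = np.unique(y)
        self.learners_ = make_base_learners(X.shape[1], self.random_state)
        folds = min(self.inner_folds, int(np.bincount(
            np.searchsorted(self.classes_, y)).min()))
        cv = StratifiedKFold(
            n_splits=max(2, folds), shuffle=True, random_state=self.random_state
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            meta_X = np.column_stack([
                cross_val_predict(clone(est), X, y, cv=cv, method="predict")
                for est in self.learners_.values()
            ])
        self.meta_features_ = (meta_X == self.classes_[1]).astype(float)
        self.meta_learner_ = self._make_meta()
        self.meta_learner_.fit(self.meta_features_, y)
        for est in self.learners_.values():
            est.fit(X, y)
        return self

    def _meta_input(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        preds = np.column_stack(
            [est.predict(X) for est in self.learners_.values()]
        )
        return (preds == self.classes_[1]).astype(float)

    def predict(self, X) -> np.ndarray:
        return self.meta_learner_.predict(self._meta_input(X))

    def predict_proba(self, X) -> np.ndarray:
        return self.meta_learner_.predict_proba(self._meta_input(X))

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (trapezoidal; ties get half credit).

    Equals the normalised Mann-Whitney rank-sum statistic: the fraction of
    (positive, negative) score pairs ranked concordantly.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined: both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


@dataclass
class EvalReport:
    """Cross-validated accuracy (%) and AUC, mean +/- std over seed runs."""

    scheme: str
    accuracy_mean: float
    accuracy_std: float
    auc_mean: float
    auc_std: float
    per_seed: list[dict] = field(default_factory=list)
    n_samples: int = 0

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_std": self.accuracy_std,
            "auc_mean": self.auc_mean,
            "auc_std": self.auc_std,
            "per_seed": self.per_seed,
            "n_samples": self.n_samples,
        }


def _single_run(X, y, model_factory, cv, seed: int) -> tuple[float, float]:
    preds = np.empty(y.size, dtype=y.dtype)
    scores = np.empty(y.size, dtype=np.float64)
    tested = np.zeros(y.size, dtype=bool)
    for train_idx, test_idx in cv.split(X, y):
        model = model_factory(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[train_idx], y[train_idx])
            preds[test_idx] = model.predict(X[test_idx])
            if hasattr(model, "decision_function"):
                scores[test_idx] = model.decision_function(X[test_idx])
            elif hasattr(model, "predict_proba"):
                scores[test_idx] = model.predict_proba(X[test_idx])[:, 1]
            else:
                scores[test_idx] = (preds[test_idx] == np.unique(y)[1]).astype(float)
        tested[test_idx] = True
    assert tested.all(), "every observation must be tested exactly once"
    accuracy = 100.0 * float(np.mean(preds == y))
    auc = roc_auc(scores, y)
    return accuracy, auc


def cross_validate(
    X,
    y,
    model_factory,
    scheme: str = "10fold",
    seeds=range(1, 11),
    n_folds: int = 10,
) -> EvalReport:
    """Stratified k-fold over several seeds, or a single LOOCV run.

    ``model_factory(seed)`` must return a fresh unfitted classifier; the
    seed also shuffles the fold assignment, and the report aggregates
    accuracy/AUC over all seed runs.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    _check_two_classes(y)
    runs: list[dict] = []
    if scheme == "loocv":
        acc, auc = _single_run(X, y, model_factory, LeaveOneOut(), seed=1)
        runs.append({"seed": 1, "accuracy": acc, "auc": auc})
    elif scheme == "10fold":
        min_class = int(np.bincount(np.searchsorted(np.unique(y), y)).min())
        folds = n_folds
        if min_class < n_folds:
            warnings.warn(
                f"smallest class has {min_class} members; using {min_class} folds"
            )
            folds = max(2, min_class)
        for seed in seeds:
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            acc, auc = _single_run(X, y, model_factory, cv, seed)
            runs.append({"seed": int(seed), "accuracy": acc, "auc": auc})
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    accs = np.array([r["accuracy"] for r in runs])
    aucs = np.array([r["auc"] for r in runs])
    return EvalReport(
        scheme=scheme,
        accuracy_mean=float(accs.mean()),
        accuracy_std=float(accs.std()),
        auc_mean=float(aucs.mean()),
        auc_std=float(aucs.std()),
        per_seed=runs,
        n_samples=int(y.size),
    )
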