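"""Four-class emotion decoding from (arousal, valence) features.

The primary classifier is a small feed-forward network with the fixed
topology 2 inputs - 3 hidden - 3 hidden - 4 outputs (tanh hidden units,
softmax output, full-batch L-BFGS training), evaluated with stratified
k-fold cross-validation.  A maximum-margin linear classifier (linear-kernel
SVM) serves as the comparison model: arousal/valence emotion classes are
typically not linearly separable, so the network should retain an edge on
non-linear layouts.  Chance level for the balanced four-class task is 25%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .synth import EMOTIONS

HIDDEN_LAYERS = (3, 3)
FEATURE_ORDER = ["arousal", "valence"]


@dataclass
class CVResult:
    """Cross-validation outcome for one classifier on one feature set.

    ``fold_accuracies`` concatenates all repeats (``folds * repeats``
    entries).  ``confusion`` is the 4x4 true-by-predicted count matrix
    accumulated over the folds of the first repeat, so its total equals
    ``n_instances``.
    """

    fold_accuracies: np.ndarray
    confusion: np.ndarray
    classifier_tag: str
    n_instances: int
    folds: int
    repeats: int
    seed: int
    classes: tuple[str, ...] = EMOTIONS

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, dtype=float)
        self.confusion = np.asarray(self.confusion, dtype=int)
        if np.any(self.fold_accuracies < 0) or np.any(self.fold_accuracies > 1):
            raise ValueError("fold accuracies must lie in [0, 1]")
        if self.confusion.sum() != self.n_instances:
            raise ValueError("confusion total must equal n_instances")

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier_tag,
            "mean_accuracy": self.mean_accuracy,
            "fold_accuracies": self.fold_accuracies.tolist(),
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
            "n_instances": self.n_instances,
            "folds": self.folds,
            "repeats": self.repeats,
            "seed": self.seed,
        }


@dataclass
class ComparisonReport:
    """Paired fold-wise comparison of two cross-validated models."""

    mean_difference: float
    p_value: float
    alpha: float
    n_folds: int
    effect_size: float
    exact: bool

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def _extract_xy(features) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(features, pd.DataFrame):
        X = features[FEATURE_ORDER].to_numpy(dtype=float)
        y = features["emotion"].to_numpy()
    else:
        X, y = features
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
    return X, y


def _check_classes(y: np.ndarray, folds: int) -> None:
    labels, counts = np.unique(y, return_counts=True)
    for lab, cnt in zip(labels, counts):
        if cnt < folds:
            raise ValueError(
                f"class {lab!r} has {cnt} instances, fewer than {folds} folds"
            )


def _cross_validate(make_clf, X, y, folds, repeats, seed, tag) -> CVResult:
    _check_classes(y, folds)
    classes = tuple(sorted(np.unique(y), key=lambda e: (
        EMOTIONS.index(e) if e in EMOTIONS else len(EMOTIONS), e)))
    accs: list[float] = []
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for train, test in skf.split(X, y):
            clf = make_clf(seed + r)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X[train], y[train])
            pred = clf.predict(X[test])
            accs.append(float(np.mean(pred == y[test])))
            if r == 0:
                confusion += confusion_matrix(y[test], pred, labels=list(classes))
    return CVResult(
        fold_accuracies=np.array(accs), confusion=confusion, classifier_tag=tag,
        n_instances=len(y), folds=folds, repeats=repeats, seed=seed, classes=classes,
    )


def train_eval_ann(
    features, folds: int = 10, repeats: int = 1, seed: int = 0,
    max_iter: int = 2000,
) -> CVResult:
    """Stratified k-fold CV of the fixed 2-3-3-4 network.

    ``features`` is an epoch feature table (columns ``arousal``, ``valence``,
    ``emotion``) or an ``(X, y)`` pair.  Folds are stratified, disjoint and
    exhaustive; ``repeats`` re-draws the fold assignment and averages.
    Deterministic under a fixed seed.
    """
    X, y = _extract_xy(features)

    def make(s: int) -> MLPClassifier:
        return MLPClassifier(
            hidden_layer_sizes=HIDDEN_LAYERS,
            activation="tanh",
            solver="lbfgs",
            max_iter=max_iter,
            tol=1e-6,
            random_state=s,
        )

    return _cross_validate(make, X, y, folds, repeats, seed, "ann")


def train_eval_linear_svm(
    features, folds: int = 10, repeats: int = 1, seed: int = 0, C: float = 1.0
) -> CVResult:
    """Stratified k-fold CV of a maximum-margin linear classifier."""
    X, y = _extract_xy(features)

    def make(s: int) -> SVC:
        return SVC(kernel="linear", C=C, random_state=s)

    return _cross_validate(make, X, y, folds, repeats, seed, "linear_svm")


def permute_labels(features, seed: int = 0):
    """Return a copy with emotion labels randomly permuted (signal-free
    control retaining the class balance)."""
    rng = np.random.default_rng(seed)
    if isinstance(features, pd.DataFrame):
        out = features.copy()
        out["emotion"] = rng.permutation(out["emotion"].to_numpy())
        return out
    X, y = features
    return np.asarray(X), rng.permutation(np.asarray(y))


def compare_models(
    a: CVResult, b: CVResult, alpha: float = 0.05, max_exact: int = 20,
    n_permutations: int = 10_000, seed: int = 0,
) -> ComparisonReport:
    """Paired sign-flip permutation test on per-fold accuracy differences.

    With k paired folds the null distribution is the mean difference under
    all 2^k sign assignments (enumerated exactly for k <= ``max_exact``,
    sampled otherwise); the two-sided p-value is the fraction of assignments
    whose |mean| is at least the observed |mean|.
    """
    if len(a.fold_accuracies) != len(b.fold_accuracies):
        raise ValueError("models must have the same number of folds to compare")
    d = a.fold_accuracies - b.fold_accuracies
    k = len(d)
    obs = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if k > 1 else 0.0
    effect = obs / sd if sd > 0 else (0.0 if obs == 0 else np.inf)

    if np.allclose(d, 0):
        return ComparisonReport(0.0, 1.0, alpha, k, 0.0, exact=True)

    absd = np.abs(d)
    if k <= max_exact:
        signs = np.array(list(product((-1.0, 1.0), repeat=k)))
        exact = True
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((-1.0, 1.0), size=(n_permutations, k))
        signs[0] = 1.0  # include the identity assignment
        exact = False
    null_means = signs @ absd / k
    p = float(np.mean(np.abs(null_means) >= abs(obs) - 1e-12))
    return ComparisonReport(obs, p, alpha, k, effect, exact=exact)
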