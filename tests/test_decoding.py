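"""Emotion decoding: CV mechanics, classifier contracts, model comparison."""

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold

from eegaffect.decoding import (
    compare_models,
    permute_labels,
    train_eval_ann,
    train_eval_linear_svm,
)
from eegaffect.synth import EMOTIONS


def gaussian_clusters(n_per=60, sep=10.0, sigma=1.0, seed=0):
    """Four well-separated clusters, one per emotion (nearest-centroid
    oracle is near-perfect at sep = 10 sigma)."""
    rng = np.random.default_rng(seed)
    centers = [(0, 0), (sep, 0), (0, sep), (sep, sep)]
    X = np.vstack([rng.normal(c, sigma, size=(n_per, 2)) for c in centers])
    y = np.repeat(EMOTIONS, n_per)
    return X, y


def xor_layout(n_per=120, sigma=0.15, seed=0):
    """Antipodal-pair layout: every class is two opposite clusters, so all
    class centroids coincide at the origin and no linear rule separates
    them, while the regions remain simple for a small non-linear model."""
    rng = np.random.default_rng(seed)
    centers = {
        "happy": [(1, 1), (-1, -1)],
        "sad": [(1, -1), (-1, 1)],
        "angry": [(2.5, 0), (-2.5, 0)],
        "fear": [(0, 2.5), (0, -2.5)],
    }
    X, y = [], []
    for emo, cs in centers.items():
        for c in cs:
            X.append(rng.normal(c, sigma, size=(n_per // 2, 2)))
            y.append(np.full(n_per // 2, emo))
    return np.vstack(X), np.concatenate(y)


def test_stratified_folds_preserve_class_proportions():
    """Per-fold class counts deviate from the global proportion by at most
    one instance, for several seeds."""
    _, y = gaussian_clusters(n_per=53)  # deliberately not divisible by 10
    for seed in range(5):
        skf = StratifiedKFold(10, shuffle=True, random_state=seed)
        for _, test in skf.split(np.zeros((len(y), 2)), y):
            counts = {e: np.sum(y[test] == e) for e in EMOTIONS}
            for e in EMOTIONS:
                expected = 53 / 10
                assert abs(counts[e] - expected) <= 1.0


def test_separable_clusters_near_perfect_both_models():
    Xy = gaussian_clusters()
    for fn in (train_eval_ann, train_eval_linear_svm):
        res = fn(Xy, folds=10, seed=0)
        assert res.mean_accuracy >= 0.95


def test_confusion_matrix_accounts_for_every_instance():
    Xy = gaussian_clusters(n_per=30)
    res = train_eval_ann(Xy, folds=10, seed=0)
    assert res.confusion.sum() == res.n_instances == 120
    assert np.all(res.confusion.sum(axis=1) == 30)  # row sums = class counts
    assert np.isclose(res.mean_accuracy,
                      np.trace(res.confusion) / res.n_instances, atol=1e-12)


def test_label_permutation_is_chance_level():
    """Signal-free features: median accuracy over 3 fold draws near 25%."""
    X, y = gaussian_clusters(n_per=100)
    Xp, yp = permute_labels((X, y), seed=1)
    res = train_eval_ann((Xp, yp), folds=10, repeats=3, seed=0)
    fold_means = res.fold_accuracies.reshape(3, 10).mean(axis=1)
    assert 0.15 <= np.median(fold_means) <= 0.35


def test_nonlinear_layout_ann_beats_linear_svm():
    """On the XOR-style layout the network exceeds the best linear rule by
    a wide margin (linear stays at or below 0.60)."""
    Xy = xor_layout(seed=2)
    ann = train_eval_ann(Xy, folds=10, seed=0)
    svm = train_eval_linear_svm(Xy, folds=10, seed=0)
    assert svm.mean_accuracy <= 0.60
    assert ann.mean_accuracy - svm.mean_accuracy >= 0.15


def test_planted_affect_signal_beats_permuted_labels(truth, device):
    """Features from recordings with distinct planted per-emotion affect
    decode strictly better than their label-permuted copies (10 seeds)."""
    from eegaffect.features import compute_affect, epoch_affect, normalize_affect
    from eegaffect.preprocessing import band_power
    from eegaffect.protocol import StimulusEvent, StimulusSchedule
    from eegaffect.synth import NoiseSpec, generate_recording

    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        order = rng.permutation(np.repeat(EMOTIONS, 3))
        events, t = [], 0.0
        for i, emo in enumerate(order):
            events.append(StimulusEvent(t + 5.0, 10.0, str(emo), "NM1", "male", f"s{i}"))
            t += 15.0
        sched = StimulusSchedule("EG01", "EG", 1, events=events)
        rec = generate_recording(sched, truth, device, NoiseSpec(background_uv=0.3),
                                 seed=seed)
        affect = compute_affect(band_power(rec, "alpha"), band_power(rec, "beta"),
                                None, "EG01", "EG", 1)
        feats = normalize_affect(epoch_affect(affect, sched))
        real = train_eval_ann(feats, folds=10, seed=seed)
        perm = train_eval_ann(permute_labels(feats, seed=seed), folds=10, seed=seed)
        wins += real.mean_accuracy > perm.mean_accuracy
    assert wins == 10


def test_class_smaller_than_fold_count_rejected():
    X, y = gaussian_clusters(n_per=5)
    with pytest.raises(ValueError, match="angry"):
        train_eval_ann((X, y), folds=10)


def test_cv_deterministic_under_seed():
    Xy = xor_layout(n_per=40, seed=0)
    a = train_eval_ann(Xy, folds=5, seed=3)
    b = train_eval_ann(Xy, folds=5, seed=3)
    assert np.array_equal(a.fold_accuracies, b.fold_accuracies)


class TestCompareModels:
    def test_identical_results_p_one(self):
        res = train_eval_linear_svm(gaussian_clusters(n_per=30), folds=5, seed=0)
        rep = compare_models(res, res)
        assert rep.p_value == 1.0 and rep.mean_difference == 0.0

    def test_constant_shift_significant(self):
        """Accuracies shifted by +0.2 in every fold: the exact sign-flip
        test rejects (p = 2/2^10 for 10 concordant folds)."""
        import copy

        a = train_eval_linear_svm(gaussian_clusters(n_per=40, sigma=4.0), folds=10,
                                  seed=0)
        b = copy.deepcopy(a)
        b.fold_accuracies = np.clip(a.fold_accuracies - 0.2, 0, 1)
        rep = compare_models(a, b, alpha=0.05)
        assert rep.significant
        assert rep.exact

    def test_exact_p_matches_enumeration(self):
        """Oracle: brute-force enumeration of all 2^k sign flips."""
        from itertools import product

        rng = np.random.default_rng(4)
        d = rng.normal(0.05, 0.1, size=8)
        a = _fake_result(0.5 + d)
        b = _fake_result(np.full(8, 0.5))
        rep = compare_models(a, b)
        absd = np.abs(d)
        null = [np.mean(np.array(s) * absd) for s in product((-1, 1), repeat=8)]
        p_oracle = np.mean(np.abs(null) >= abs(np.mean(d)) - 1e-12)
        assert np.isclose(rep.p_value, p_oracle, atol=1e-12)

    def test_unequal_fold_counts_rejected(self):
        a = _fake_result(np.full(10, 0.5))
        b = _fake_result(np.full(8, 0.5))
        with pytest.raises(ValueError, match="folds"):
            compare_models(a, b)

    def test_type_one_error_near_alpha(self):
        """Independent chance-level fold accuracies: rejection rate over
        200 simulations is close to alpha."""
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(200):
            a = _fake_result(rng.normal(0.25, 0.05, size=10))
            b = _fake_result(rng.normal(0.25, 0.05, size=10))
            rejections += compare_models(a, b, alpha=0.05).significant
        assert 0.01 <= rejections / 200 <= 0.10


def _fake_result(fold_accuracies):
    from eegaffect.decoding import CVResult

    fold_accuracies = np.clip(np.asarray(fold_accuracies, dtype=float), 0, 1)
    k = len(fold_accuracies)
    return CVResult(
        fold_accuracies=fold_accuracies,
        confusion=np.eye(4, dtype=int),
        classifier_tag="ann",
        n_instances=4,
        folds=k,
        repeats=1,
        seed=0,
    )
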