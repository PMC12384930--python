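"""Metrics and statistical validation: PRF, OvR AUC, bootstrap, DeLong, kappa."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from capscan.evaluation import (
    _auc_rank,
    bootstrap_ci,
    classification_report,
    cohen_kappa_reliability,
    delong_test,
    evaluate,
    roc_auc_ovr,
)


def _trapezoid_auc(y, scores):
    """Geometric oracle: trapezoid integration of the empirical ROC curve."""
    order = np.argsort(-scores, kind="stable")
    y = np.asarray(y)[order]
    scores_sorted = np.asarray(scores)[order]
    p, n = y.sum(), (1 - y).sum()
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and scores_sorted[j] == scores_sorted[i]:
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        tpr.append(tp / p)
        fpr.append(fp / n)
        i = j
    return float(np.trapezoid(tpr, fpr))


class TestClassificationReport:
    def test_perfect_prediction(self, rng):
        y = rng.integers(0, 3, 100)
        rep = classification_report(y, y, 3)
        assert np.allclose(rep.precision, 1) and np.allclose(rep.recall, 1)
        assert np.array_equal(np.diag(rep.confusion), rep.support)

    def test_printed_toy_counts(self):
        rep = classification_report([1, 1, 0, 0], [1, 0, 0, 0], 2)
        assert rep.precision[1] == 1.0
        assert rep.recall[1] == 0.5

    def test_matches_brute_force_pair_counts(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 5))
            y = rng.integers(0, k, 60)
            p = rng.integers(0, k, 60)
            rep = classification_report(y, p, k)
            for c in range(k):
                tp = int(np.sum((y == c) & (p == c)))
                fp = int(np.sum((y != c) & (p == c)))
                fn = int(np.sum((y == c) & (p != c)))
                assert rep.precision[c] == (tp / (tp + fp) if tp + fp else 0.0)
                assert rep.recall[c] == (tp / (tp + fn) if tp + fn else 0.0)

    def test_accuracy_equals_confusion_trace(self, rng):
        y = rng.integers(0, 4, 200)
        p = rng.integers(0, 4, 200)
        rep = classification_report(y, p, 4)
        assert rep.accuracy == rep.confusion.trace() / rep.confusion.sum()


class TestRocAuc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        assert np.allclose(roc_auc_ovr(y, probs), 1.0)

    def test_null_scores_near_half(self, rng):
        n = 4000
        y = rng.integers(0, 2, n)
        probs = rng.random((n, 2))
        probs /= probs.sum(1, keepdims=True)
        auc = roc_auc_ovr(y, probs)
        assert np.all(np.abs(auc - 0.5) < 0.05)

    def test_equals_trapezoid_oracle(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 80)
            s = np.round(rng.random(80), 2)  # ties included
            if y.min() == y.max():
                continue
            assert abs(_auc_rank(y, s) - _trapezoid_auc(y, s)) < 1e-10

    def test_invariant_to_monotone_transform(self, rng):
        y = rng.integers(0, 2, 100)
        s = rng.standard_normal(100)
        assert abs(_auc_rank(y, s) - _auc_rank(y, np.exp(s))) < 1e-12

    def test_agreement_with_sklearn(self, rng):
        y = rng.integers(0, 3, 200)
        probs = rng.random((200, 3))
        probs /= probs.sum(1, keepdims=True)
        ours = roc_auc_ovr(y, probs)
        ref = [roc_auc_score((y == k).astype(int), probs[:, k]) for k in range(3)]
        assert np.allclose(ours, ref, atol=1e-12)


class TestBootstrap:
    def test_constant_metric_degenerate_interval(self, rng):
        y = rng.integers(0, 2, 50)
        lo, hi = bootstrap_ci(lambda yy, ss: 0.7, y, rng.random(50), n_boot=200, seed=0)
        assert lo == hi == 0.7

    def test_same_seed_identical_interval(self, rng):
        y = rng.integers(0, 2, 100)
        s = rng.standard_normal(100) + y
        args = dict(n_boot=300, seed=11)
        assert bootstrap_ci(_auc_rank, y, s, **args) == bootstrap_ci(_auc_rank, y, s, **args)

    def test_interval_width_shrinks_with_n(self, rng):
        widths = []
        for n in (200, 3200):
            y = (np.arange(n) % 2).astype(int)
            s = rng.standard_normal(n) + y
            lo, hi = bootstrap_ci(_auc_rank, y, s, n_boot=300, seed=5)
            widths.append(hi - lo)
        # sqrt(16) = 4x smaller sample error; allow slack for randomness
        assert widths[1] < widths[0] / 2

    def test_too_few_resamples_raises(self, rng):
        with pytest.raises(ValueError):
            bootstrap_ci(_auc_rank, np.array([0, 1]), np.array([0.1, 0.9]), n_boot=50)


class TestDeLong:
    def test_identical_scores_z_zero_p_one(self, rng):
        y = rng.integers(0, 2, 100)
        s = rng.standard_normal(100)
        auc_a, auc_b, z, p = delong_test(y, s, s)
        assert auc_a == auc_b and z == 0.0 and p == 1.0

    def test_placement_auc_matches_rank_auc(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 120)
            if y.min() == y.max():
                continue
            s = np.round(rng.standard_normal(120), 1)
            auc_a, _, _, _ = delong_test(y, s, rng.standard_normal(120))
            assert abs(auc_a - _auc_rank(y, s)) < 1e-10

    def test_power_against_noise(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 500)
            informative = rng.standard_normal(500) + 1.5 * y
            noise = rng.standard_normal(500)
            *_, p = delong_test(y, informative, noise)
            hits += p < 0.01
        assert hits >= 95

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            delong_test(np.zeros(10, dtype=int), np.arange(10), np.arange(10))


class TestKappa:
    def test_perfect_agreement(self, rng):
        y = rng.integers(0, 3, 60)
        kappa, label = cohen_kappa_reliability(y, y)
        assert kappa == 1.0 and label == "High"

    def test_independent_labels_near_zero(self, rng):
        y1 = rng.integers(0, 4, 20000)
        y2 = rng.integers(0, 4, 20000)
        kappa, label = cohen_kappa_reliability(y1, y2)
        assert abs(kappa) < 0.03 and label == "Review needed"

    def test_printed_agreement_table(self):
        y1 = ["a"] * 45 + ["b"] * 45 + ["a"] * 5 + ["b"] * 5
        y2 = ["a"] * 45 + ["b"] * 45 + ["b"] * 5 + ["a"] * 5
        kappa, label = cohen_kappa_reliability(np.array(y1), np.array(y2))
        assert kappa == pytest.approx(0.8)
        assert label == "Review needed"

    def test_kappa_bounded_by_observed_agreement(self, rng):
        for _ in range(20):
            y1 = rng.integers(0, 3, 100)
            y2 = rng.integers(0, 3, 100)
            kappa, _ = cohen_kappa_reliability(y1, y2)
            assert kappa <= np.mean(y1 == y2) + 1e-12


class TestEvaluate:
    def test_full_report_structure(self, rng):
        y = rng.integers(0, 3, 150)
        logits = rng.standard_normal((150, 3))
        logits[np.arange(150), y] += 2.0
        probs = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        rep = evaluate(y, probs, n_boot=150, seed=0)
        assert rep.auc is not None and len(rep.auc) == 3
        for (lo, hi), point in zip(rep.auc_ci, rep.auc):
            assert lo <= point <= hi
        assert rep.kappa is not None and rep.reliability in ("High", "Review needed")
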