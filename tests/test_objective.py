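"""Class weights, weighted cross-entropy and AS/F1 evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import accuracy_score, log_loss, precision_recall_fscore_support

from cmsfl.network import CosineHeadParams
from cmsfl.objective import (
    cosine_class_weights,
    evaluate,
    frequency_class_weights,
    softmax_wcce_with_grad,
    uniform_class_weights,
    weighted_cce,
    weighted_cce_grad,
)


class TestCosineWeights:
    def test_identical_class_vectors_give_uniform(self, rng):
        head = CosineHeadParams(np.tile(rng.random(4), (3, 1)), scale=5.0)
        w = cosine_class_weights(rng.random(4) + 0.1, head)
        np.testing.assert_allclose(w.omega, 1 / 3, atol=1e-12)

    def test_vanishing_scale_gives_uniform(self, rng):
        head = CosineHeadParams(rng.random((4, 5)) + 0.1, scale=1e-9)
        w = cosine_class_weights(rng.random(5) + 0.1, head)
        np.testing.assert_allclose(w.omega, 0.25, atol=1e-8)

    def test_softmax_of_unit_and_zero_cosine(self):
        """Feature e1 against class vectors e1 and e2: cosines (1, 0),
        scale 1 -> softmax (0.7311, 0.2689)."""
        head = CosineHeadParams(np.array([[1.0, 0.0], [0.0, 1.0]]), scale=1.0)
        w = cosine_class_weights(np.array([1.0, 0.0]), head)
        np.testing.assert_allclose(w.omega, [0.7310586, 0.2689414], atol=1e-6)

    def test_invariant_to_positive_rescaling(self, rng):
        vecs = rng.random((3, 6)) + 0.1
        f = rng.random(6) + 0.1
        a = cosine_class_weights(f, CosineHeadParams(vecs, scale=3.0))
        b = cosine_class_weights(
            7.3 * f, CosineHeadParams(vecs * rng.uniform(0.5, 2, (3, 1)), scale=3.0)
        )
        np.testing.assert_allclose(a.omega, b.omega, atol=1e-10)

    def test_zero_feature_rejected(self, rng):
        head = CosineHeadParams(rng.random((2, 3)) + 0.1, scale=1.0)
        with pytest.raises(ValueError, match="nonzero"):
            cosine_class_weights(np.zeros(3), head)


class TestFrequencyWeights:
    def test_balanced_gives_ones(self):
        w = frequency_class_weights(np.repeat([0, 1, 2], 10), 3)
        np.testing.assert_allclose(w.omega, 1.0)

    def test_binary_30_10(self):
        labels = np.r_[np.zeros(30, int), np.ones(10, int)]
        np.testing.assert_allclose(
            frequency_class_weights(labels, 2).omega, [0.5, 1.5]
        )

    def test_three_class_10_10_20(self):
        labels = np.r_[np.zeros(10, int), np.ones(10, int), np.full(20, 2)]
        np.testing.assert_allclose(
            frequency_class_weights(labels, 3).omega, [1.2, 1.2, 0.6]
        )

    def test_empty_class_suggests_uniform(self):
        with pytest.raises(ValueError, match="uniform"):
            frequency_class_weights(np.zeros(5, int), 2)


class TestWeightedCCE:
    def test_perfect_predictions_give_zero(self):
        t = np.eye(3)
        assert weighted_cce(t, t, uniform_class_weights(3)) == pytest.approx(0.0)

    def test_uniform_predictions_give_log_j(self):
        p = np.full((5, 4), 0.25)
        t = np.eye(4)[np.array([0, 1, 2, 3, 0])]
        assert weighted_cce(p, t, uniform_class_weights(4)) == pytest.approx(
            np.log(4), abs=1e-12
        )

    def test_hand_weighted_case(self):
        p = np.array([[0.2, 0.8]])
        t = np.array([[0.0, 1.0]])
        w = uniform_class_weights(2)
        w.omega = np.array([0.5, 1.5])
        assert weighted_cce(p, t, w) == pytest.approx(1.5 * -np.log(0.8), abs=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_unit_weights_reduce_to_plain_cross_entropy(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(4), size=6)
        labels = rng.integers(0, 4, size=6)
        t = np.eye(4)[labels]
        ours = weighted_cce(p, t, uniform_class_weights(4))
        ref = log_loss(labels, p, labels=np.arange(4))
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            weighted_cce(np.array([[0.5, 0.6]]), np.array([[1.0, 0.0]]),
                         uniform_class_weights(2))

    def test_gradient_matches_central_differences(self, rng):
        p = rng.dirichlet(np.ones(3), size=4)
        t = np.eye(3)[rng.integers(0, 3, 4)]
        w = uniform_class_weights(3)
        w.omega = np.array([0.5, 1.0, 1.5])
        g = weighted_cce_grad(p, t, w)
        eps = 1e-7
        for i in range(4):
            for j in range(3):
                pp, pm = p.copy(), p.copy()
                pp[i, j] += eps
                pm[i, j] -= eps
                # renormalization skipped: probing the raw partial derivative
                num = (
                    -(w.omega * t * np.log(np.maximum(pp, 1e-12))).sum() / 4
                    + (w.omega * t * np.log(np.maximum(pm, 1e-12))).sum() / 4
                ) / (2 * eps)
                assert num == pytest.approx(g[i, j], abs=1e-4)

    def test_fused_score_gradient(self, rng):
        scores = rng.normal(0, 1, (5, 3))
        labels = rng.integers(0, 3, 5)
        w = uniform_class_weights(3)
        w.omega = np.array([0.7, 1.0, 1.3])
        loss, g = softmax_wcce_with_grad(scores, labels, w)
        eps = 1e-6
        for i in range(5):
            for j in range(3):
                sp, sm = scores.copy(), scores.copy()
                sp[i, j] += eps
                sm[i, j] -= eps
                lp, _ = softmax_wcce_with_grad(sp, labels, w)
                lm, _ = softmax_wcce_with_grad(sm, labels, w)
                assert (lp - lm) / (2 * eps) == pytest.approx(g[i, j], abs=1e-5)


class TestEvaluate:
    def test_perfect_classifier(self):
        y = np.array([0, 1, 2, 1, 0])
        rep = evaluate(y, y, 3)
        assert rep.as_score == 1.0 and rep.f1_macro == 1.0

    def test_binary_confusion_example(self):
        """Class-1 confusion TP=8, FP=2, FN=4 -> precision 0.8,
        recall 0.6667, F1 ~ 0.7273."""
        truth = np.r_[np.ones(12, int), np.zeros(8, int)]
        preds = np.r_[np.ones(8, int), np.zeros(4, int), np.ones(2, int),
                      np.zeros(6, int)]
        rep = evaluate(preds, truth, 2)
        row = rep.per_class[1]
        assert row["tp"] == 8 and row["fp"] == 2 and row["fn"] == 4
        assert row["precision"] == pytest.approx(0.8)
        assert row["recall"] == pytest.approx(2 / 3, abs=1e-4)
        assert row["f1"] == pytest.approx(0.727272, abs=1e-4)

    def test_constant_predictor_on_balanced_binary(self):
        truth = np.r_[np.zeros(5, int), np.ones(5, int)]
        rep = evaluate(np.zeros(10, int), truth, 2)
        assert rep.as_score == 0.5

    def test_absent_class_flagged_with_zero_f1(self):
        rep = evaluate(np.array([0, 0]), np.array([0, 0]), 3)
        assert rep.absent_classes == [1, 2]
        assert rep.per_class[1]["f1"] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            evaluate(np.array([0, 1]), np.array([0]), 2)

    def test_agrees_with_sklearn_on_random_cases(self):
        """Independent confusion-matrix oracle, 1000 random label pairs."""
        rng = np.random.default_rng(99)
        yhat = rng.integers(0, 4, 1000)
        y = rng.integers(0, 4, 1000)
        rep = evaluate(yhat, y, 4)
        assert rep.as_score == accuracy_score(y, yhat)
        prec, rec, f1, _ = precision_recall_fscore_support(
            y, yhat, labels=np.arange(4), zero_division=0
        )
        assert rep.f1_macro == pytest.approx(f1.mean(), abs=1e-12)
        for c in range(4):
            assert rep.per_class[c]["precision"] == pytest.approx(prec[c])
            assert rep.per_class[c]["recall"] == pytest.approx(rec[c])
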