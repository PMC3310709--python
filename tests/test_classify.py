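"""Tests for the label-attachment stage and the k-NN baseline."""

import numpy as np
import pytest

import poismix as pm


def _separable_fields(A=40.0):
    raw = np.array([
        [9.0, 1.0, 1.0, 1.0],
        [1.0, 9.0, 1.0, 1.0],
        [1.0, 1.0, 9.0, 1.0],
    ])
    return pm.normalize_fields(raw, A)


class TestEstimateLabelMap:
    def test_bijection_gives_permutation_matrix(self):
        W = _separable_fields()
        # one clean example per class, labels permuted
        X = W * 1.0
        labels = np.array([2, 0, 1])
        T = pm.estimate_label_map(X, labels, W, 3)
        expected = np.zeros((3, 3))
        expected[labels, np.arange(3)] = 1.0
        np.testing.assert_allclose(T, expected, atol=1e-6)

    def test_columns_sum_to_one(self, rng):
        W = _separable_fields()
        X, true = pm.sample_mixture(W, 60, seed=1)
        T = pm.estimate_label_map(X, true % 2, W, 2)
        np.testing.assert_allclose(T.sum(axis=0), 1.0, rtol=1e-9)

    def test_components_sharing_a_label(self):
        """Two components responsive only to label-0 examples both get
        columns concentrated on label 0."""
        W = _separable_fields()
        X, true = pm.sample_mixture(W, 300, seed=2)
        labels = np.where(true <= 1, 0, 1)  # components 0 and 1 -> label 0
        T = pm.estimate_label_map(X, labels, W, 2)
        assert T[0, 0] > 0.95 and T[0, 1] > 0.95 and T[1, 2] > 0.95

    def test_empty_labeled_set_rejected(self):
        with pytest.raises(ValueError):
            pm.estimate_label_map(np.empty((0, 4)), [], _separable_fields(), 2)


class TestClassify:
    def test_identity_map_equals_argmax_responsibility(self):
        W = _separable_fields()
        X, _ = pm.sample_mixture(W, 50, seed=3)
        preds, P = pm.classify(X, W, np.eye(3))
        q = pm.posterior(X, W, mode="full")
        np.testing.assert_array_equal(preds, q.argmax(axis=1))
        np.testing.assert_allclose(P, q, rtol=1e-12)

    def test_uniform_map_gives_uniform_posteriors(self):
        W = _separable_fields()
        X, _ = pm.sample_mixture(W, 20, seed=4)
        _, P = pm.classify(X, W, np.full((2, 3), 0.5))
        np.testing.assert_allclose(P, 0.5, rtol=1e-12)

    def test_posterior_rows_sum_to_one(self, rng):
        W = _separable_fields()
        X, true = pm.sample_mixture(W, 30, seed=5)
        T = pm.estimate_label_map(X, true % 2, W, 2)
        _, P = pm.classify(X, W, T)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, rtol=1e-9)

    def test_end_to_end_blocks_accuracy(self, blocks_data):
        """With the true generative fields and 10 labels/class, held-out
        accuracy on fresh blocks data exceeds 95%."""
        truth = blocks_data["truth"]
        Xl, yl = pm.sample_mixture(truth, 40, seed=21)
        clf = pm.MixtureLabelClassifier(fields=truth).fit(Xl, yl)
        Xt, yt = pm.sample_mixture(truth, 500, seed=22)
        assert (clf.predict(Xt) == yt).mean() > 0.95

    def test_more_labels_never_hurt_on_average(self, blocks_data):
        """Held-out accuracy trends upward with labeled-set size."""
        truth = blocks_data["truth"]
        Xt, yt = pm.sample_mixture(truth, 400, seed=30)
        acc = {}
        for n_per in (1, 5, 10, 50):
            scores = []
            for rep in range(5):
                Xl, yl = pm.sample_mixture(truth, 4 * n_per, seed=100 + rep)
                clf = pm.MixtureLabelClassifier(fields=truth).fit(Xl, yl)
                scores.append((clf.predict(Xt) == yt).mean())
            acc[n_per] = np.mean(scores)
        assert acc[50] >= acc[1] - 0.02

    def test_overcomplete_components_help_multistyle_classes(self):
        """With two distinct styles per label, an overcomplete component set
        classifies better than one component per label."""
        styles = pm.normalize_fields(np.array([
            [9.0, 1.0, 1.0, 1.0],
            [1.0, 9.0, 1.0, 1.0],   # styles of label 0
            [1.0, 1.0, 9.0, 1.0],
            [1.0, 1.0, 1.0, 9.0],   # styles of label 1
        ]), 8.0)
        X, comp = pm.sample_mixture(styles, 800, seed=6)
        labels = (comp >= 2).astype(int)
        Xt, comp_t = pm.sample_mixture(styles, 800, seed=7)
        yt = (comp_t >= 2).astype(int)

        over = pm.MixtureLabelClassifier(fields=styles).fit(X[:100], labels[:100])
        acc_over = (over.predict(Xt) == yt).mean()

        complete_fields = pm.normalize_fields(
            np.vstack([styles[:2].mean(axis=0), styles[2:].mean(axis=0)]), 8.0)
        complete = pm.MixtureLabelClassifier(fields=complete_fields).fit(
            X[:100], labels[:100])
        acc_complete = (complete.predict(Xt) == yt).mean()
        assert acc_over > acc_complete


class TestKnn:
    def test_exact_match_wins_at_k1(self):
        train = np.array([[0.0, 0.0], [5.0, 5.0]])
        preds = pm.knn_classify(train, np.array([7, 9]), np.array([[5.0, 5.0]]), k=1)
        assert preds[0] == 9

    def test_euclidean_special_case(self):
        train = np.array([[0.0], [10.0]])
        preds = pm.knn_classify(train, np.array([0, 1]), np.array([[4.0]]),
                                k=1, norm_exponent=2.0)
        assert preds[0] == 0

    def test_l3_and_l2_order_differently(self):
        """A constructed instance where coordinate-wise spread flips the
        nearest neighbour between exponents 2 and 3."""
        q = np.array([[0.0, 0.0]])
        a = np.array([3.0, 3.0])     # L2^2 = 18, L3^3 = 54
        b = np.array([4.05, 0.0])    # L2^2 = 16.4, L3^3 = 66.4
        train = np.vstack([a, b])
        labels = np.array([0, 1])
        assert pm.knn_classify(train, labels, q, k=1, norm_exponent=2.0)[0] == 1
        assert pm.knn_classify(train, labels, q, k=1, norm_exponent=3.0)[0] == 0

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            pm.knn_classify(np.zeros((2, 1)), np.array([0, 1]),
                            np.zeros((1, 1)), k=3)

    def test_majority_vote(self):
        train = np.array([[0.0], [0.1], [0.2], [5.0]])
        labels = np.array([1, 1, 0, 0])
        preds = pm.knn_classify(train, labels, np.array([[0.0]]), k=3)
        assert preds[0] == 1
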