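"""Second-stage classification on top of the learned mixture representation.

The hierarchical model assumes an external label l (e.g. a digit type) picks
a mixture component c (e.g. a writing style), which generates the stimulus.
With a small labeled subset, the label-given-component map
``T[l, c] ~ p(l | c)`` is estimated by summing component responsibilities
over each label's examples and normalizing over labels; unlabeled stimuli
are then classified by marginalizing the component posterior through T:

    p(l | y) = sum_c T[l, c] p(c | y).

Only the label attachment uses supervision — the representation itself is
learned unsupervised.  A k-nearest-neighbour baseline (Minkowski distance,
exponent 3 by default) is included for comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neighbors import NearestNeighbors

from .mixture import check_batch, check_fields, posterior


def estimate_label_map(labeled_batch, labels, fields, n_labels: int, priors=None) -> np.ndarray:
    """Estimate T[l, c] ~ p(l | c) from a labeled subset.

    T[l, c] is proportional to the total responsibility component c takes
    for label l's examples, normalized over labels for each component.
    Components claiming no responsibility at all get a uniform column (with
    a warning).
    """
    y = check_batch(labeled_batch, name="labeled_batch")
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0 or y.shape[0] == 0:
        raise ValueError("labeled set must be nonempty")
    if labels.shape[0] != y.shape[0]:
        raise ValueError("labels and batch disagree on N")
    if labels.min() < 0 or labels.max() >= n_labels:
        raise ValueError(f"labels must lie in [0, {n_labels})")
    W = check_fields(fields)
    q = posterior(y, W, priors, mode="full")          # N x C
    T = np.zeros((n_labels, W.shape[0]))
    for lab in range(n_labels):
        T[lab] = q[labels == lab].sum(axis=0)
    col_mass = T.sum(axis=0)
    empty = col_mass <= 0
    if np.any(empty):
        warnings.warn(
            f"{int(empty.sum())} component(s) received no responsibility; "
            "their label columns are set uniform",
            stacklevel=2,
        )
        T[:, empty] = 1.0 / n_labels
        col_mass[empty] = 1.0
    return T / col_mass[None, :]


def classify(batch, fields, label_map, priors=None):
    """Label posteriors and argmax labels for a batch.

    p(l | y) = sum_c T[l, c] p(c | y); ties in the argmax go to the lowest
    label index.  Returns ``(pred_labels, label_posteriors)``.
    """
    y = check_batch(batch)
    W = check_fields(fields)
    T = np.asarray(label_map, dtype=np.float64)
    if T.shape[1] != W.shape[0]:
        raise ValueError("label_map columns must match the number of components")
    q = posterior(y, W, priors, mode="full")
    P = q @ T.T                                        # N x K, rows sum to 1
    return np.argmax(P, axis=1), P


class MixtureLabelClassifier(ClassifierMixin, BaseEstimator):
    """Classifier that attaches labels to a fixed, unsupervised mixture.

    Parameters
    ----------
    fields : ndarray (C, D)
        Generative fields / learned weights of the first processing stage.
    priors : ndarray (C,) or None
        Component priors (flat when None).

    ``fit(X, y)`` only estimates the label map; the representation is not
    retrained.
    """

    def __init__(self, fields=None, priors=None):
        self.fields = fields
        self.priors = priors

    def fit(self, X, y):
        if self.fields is None:
            raise ValueError("fields must be provided")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        codes = np.searchsorted(self.classes_, y)
        self.label_map_ = estimate_label_map(
            X, codes, self.fields, len(self.classes_), self.priors
        )
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def predict_proba(self, X):
        _, P = classify(X, self.fields, self.label_map_, self.priors)
        return P

    def predict(self, X):
        idx, _ = classify(X, self.fields, self.label_map_, self.priors)
        return self.classes_[idx]


def knn_classify(train, train_labels, test, k: int = 1, norm_exponent: float = 3.0):
    """k-nearest-neighbour baseline under a Minkowski norm (default L3).

    Majority vote among the k nearest training points; ties between labels
    are broken in favour of the label owning the closer neighbour (then the
    lower training index), which makes the result deterministic.
    """
    train = check_batch(train, name="train")
    test = check_batch(test, name="test")
    train_labels = np.asarray(train_labels)
    if k < 1 or k > train.shape[0]:
        raise ValueError("k must lie in [1, n_train]")
    if norm_exponent < 1:
        raise ValueError("norm_exponent must be >= 1")
    nn = NearestNeighbors(n_neighbors=k, metric="minkowski", p=norm_exponent)
    nn.fit(train)
    dist, idx = nn.kneighbors(test)
    preds = np.empty(test.shape[0], dtype=train_labels.dtype)
    for i in range(test.shape[0]):
        # order neighbours by (distance, training index) for determinism
        order = np.lexsort((idx[i], dist[i]))
        neigh_labels = train_labels[idx[i][order]]
        votes: dict = {}
        for lab in neigh_labels:
            votes[lab] = votes.get(lab, 0) + 1
        best = max(votes.values())
        # first label (in distance-then-index order) reaching the top count
        for lab in neigh_labels:
            if votes[lab] == best:
                preds[i] = lab
                break
    return preds
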