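"""Normalized Poisson mixture model: fields, sampling, likelihoods, posteriors.

The generative model assumes each stimulus ``y`` (a length-D vector of
nonnegative rates) is produced by first picking one of C classes and then
drawing every pixel independently from a Poisson distribution whose mean is
the class's *generative field* ``W[c]``.  In the constrained variant every
field row sums to a common normalization constant ``A`` — the model
counterpart of stimuli whose total intensity is fixed by feedforward
inhibition.  Under that constraint (and flat class priors) the posterior over
classes collapses to a softmax of the log-field projections
``I_c = sum_d y_d log W_cd``, which is the quantity a lateral-inhibition
circuit can compute locally.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

#: Fields are clamped to this floor before logarithms are taken.  M-steps can
#: drive entries of pixels that are never active arbitrarily close to zero.
FIELD_FLOOR = 1e-8

#: Relative tolerance for "each row sums to A" checks.
ROW_SUM_RTOL = 1e-9


# ---------------------------------------------------------------------------
# validation helpers

def check_batch(y, *, name: str = "batch") -> np.ndarray:
    """Validate a stimulus batch: 2-D, finite, nonnegative. Returns float64."""
    y = np.asarray(y, dtype=np.float64)
    if y.ndim == 1:
        y = y[None, :]
    if y.ndim != 2:
        raise ValueError(f"{name} must be 2-D (N, D), got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"{name} contains NaN or Inf")
    if np.any(y < 0):
        raise ValueError(f"{name} contains negative entries")
    return y


def check_fields(W, *, A: float | None = None, name: str = "fields") -> np.ndarray:
    """Validate a field/weight matrix: 2-D, finite, strictly positive.

    If ``A`` is given, additionally require each row to sum to ``A`` within
    relative tolerance ``ROW_SUM_RTOL``.
    """
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2:
        raise ValueError(f"{name} must be 2-D (C, D), got shape {W.shape}")
    if not np.all(np.isfinite(W)):
        raise ValueError(f"{name} contains NaN or Inf")
    if np.any(W <= 0):
        raise ValueError(f"{name} must be strictly positive")
    if A is not None:
        sums = W.sum(axis=1)
        if not np.allclose(sums, A, rtol=ROW_SUM_RTOL, atol=0.0):
            raise ValueError(
                f"{name} rows must sum to A={A} (got row sums {sums})"
            )
    return W


def is_row_normalized(y: np.ndarray, target: float | None = None) -> bool:
    """True when every row of ``y`` sums to a common constant (``target`` if
    given, else the first row's sum) within relative tolerance."""
    sums = np.asarray(y, dtype=np.float64).sum(axis=1)
    ref = float(sums[0]) if target is None else float(target)
    return bool(np.allclose(sums, ref, rtol=ROW_SUM_RTOL, atol=0.0))


# ---------------------------------------------------------------------------
# operations

def normalize_fields(raw_fields, A: float) -> np.ndarray:
    """Rescale each row of ``raw_fields`` multiplicatively to sum to ``A``.

    Relative proportions within each row are preserved; this fixes the
    "contrast" of every field to the same total intensity.
    """
    W = np.asarray(raw_fields, dtype=np.float64)
    if W.ndim != 2:
        raise ValueError(f"raw_fields must be 2-D, got shape {W.shape}")
    if not np.all(np.isfinite(W)):
        raise ValueError("raw_fields contains NaN or Inf")
    if np.any(W <= 0):
        raise ValueError("raw_fields must be strictly positive")
    if not A > 0:
        raise ValueError(f"A must be positive, got {A}")
    sums = W.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("degenerate field: a row sums to zero")
    return A * W / sums


def sample_mixture(
    fields,
    n_samples: int,
    seed,
    priors=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_samples`` stimuli from the Poisson mixture.

    For each datum a class ``c`` is drawn from ``priors`` (flat by default)
    and each pixel from ``Poisson(W[c, d])``.  The returned batch is *not*
    re-normalized: row sums fluctuate around the fields' row sums.

    Returns ``(X, labels)`` with ``X`` of shape (n_samples, D) (float, integer
    valued) and the true class of each datum (for evaluation only).
    """
    W = check_fields(fields)
    C = W.shape[0]
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if priors is None:
        priors = np.full(C, 1.0 / C)
    priors = np.asarray(priors, dtype=np.float64)
    if priors.shape != (C,) or np.any(priors <= 0):
        raise ValueError("priors must be a positive length-C vector")
    if not np.isclose(priors.sum(), 1.0):
        raise ValueError("priors must sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(C, size=n_samples, p=priors)
    X = rng.poisson(W[labels]).astype(np.float64)
    return X, labels


def _log_joint(y: np.ndarray, W: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """N x C matrix of log [ pi_c * prod_d Poisson(y_d; W_cd) ].

    Uses the continuous extension ``log Gamma(y+1)`` of the factorial so the
    model also accepts non-integer rates (e.g. rescaled image intensities).
    """
    logW = np.log(np.maximum(W, FIELD_FLOOR))
    # y @ logW.T  -  sum_d W_cd  -  sum_d logGamma(y_d + 1)
    ll = y @ logW.T
    ll -= W.sum(axis=1)[None, :]
    ll -= gammaln(y + 1.0).sum(axis=1)[:, None]
    ll += np.log(priors)[None, :]
    return ll


def poisson_log_likelihood(
    batch, fields, priors=None
) -> tuple[np.ndarray, float]:
    """Per-point and total log-likelihood under the Poisson mixture.

    per_point[n] = log sum_c pi_c prod_d Poisson(y_nd; W_cd), evaluated in
    log space with max-shift stabilization; total is the sum over points.
    """
    y = check_batch(batch)
    W = check_fields(fields)
    C = W.shape[0]
    if priors is None:
        priors = np.full(C, 1.0 / C)
    priors = np.asarray(priors, dtype=np.float64)
    per_point = logsumexp(_log_joint(y, W, priors), axis=1)
    return per_point, float(per_point.sum())


def posterior(batch, fields, priors=None, mode: str = "full") -> np.ndarray:
    """Class responsibilities p(c | y) for every stimulus in ``batch``.

    mode="full"
        Bayes responsibilities from the Poisson mixture directly; works for
        any positive fields and priors.
    mode="compact"
        The softmax-of-projections form ``softmax_c( sum_d y_d log W_cd )``.
        Valid only when all field rows sum to a common constant and priors
        are flat — then the ``sum_d W_cd`` and prior terms are
        class-independent and cancel.  This is the form a neural circuit
        computes.

    Both modes subtract the per-row maximum before exponentiation.
    """
    y = check_batch(batch)
    W = check_fields(fields)
    C = W.shape[0]
    if priors is None:
        priors = np.full(C, 1.0 / C)
    priors = np.asarray(priors, dtype=np.float64)

    if mode == "full":
        log_post = _log_joint(y, W, priors)
    elif mode == "compact":
        if not is_row_normalized(W):
            raise ValueError(
                "compact posterior requires row-normalized fields "
                "(all rows summing to a common constant A)"
            )
        if not np.allclose(priors, 1.0 / C):
            raise ValueError("compact posterior requires flat priors")
        log_post = y @ np.log(np.maximum(W, FIELD_FLOOR)).T
    else:
        raise ValueError(f"unknown mode {mode!r}")

    log_post = log_post - log_post.max(axis=1, keepdims=True)
    q = np.exp(log_post)
    q /= q.sum(axis=1, keepdims=True)
    return q


def check_responsibilities(q, *, name: str = "responsibilities") -> np.ndarray:
    """Validate an N x C row-stochastic responsibility matrix."""
    q = np.asarray(q, dtype=np.float64)
    if q.ndim != 2:
        raise ValueError(f"{name} must be 2-D (N, C)")
    if np.any(q < 0) or np.any(q > 1 + 1e-12):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    if not np.allclose(q.sum(axis=1), 1.0, rtol=1e-9, atol=1e-9):
        raise ValueError(f"{name} rows must sum to 1")
    return q
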