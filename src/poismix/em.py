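"""Batch expectation–maximization for the (normalized) Poisson mixture.

Two model variants are supported:

``constrained``
    Generative fields are constrained to a fixed total intensity
    (each row of W sums to A).  The M-step rescales responsibility-weighted
    data means to that total; the E-step uses the compact softmax posterior.
    A can optionally be annealed: a small A acts like a high temperature
    (broad posteriors, fewer local optima), so increasing it gradually during
    early iterations is a form of deterministic annealing.

``unconstrained``
    A plain Poisson mixture; the M-step is the responsibility-weighted mean
    and the E-step the full Bayes posterior.

The reference implementation is the scikit-learn style estimator
:class:`PoissonMixtureEM`; :func:`run_em` is a thin functional wrapper.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, DensityMixin

from .mixture import (
    FIELD_FLOOR,
    check_batch,
    check_responsibilities,
    normalize_fields,
    poisson_log_likelihood,
    posterior,
)
from .trace import TrainingTrace, dataset_hash

logger = logging.getLogger(__name__)

_MAX_DEAD_CLASS_RESCUES = 10


class DeadClassError(RuntimeError):
    """A mixture component lost all responsibility mass."""

    def __init__(self, class_index: int):
        self.class_index = class_index
        super().__init__(f"component {class_index} has zero total responsibility")


@dataclass
class AnnealSchedule:
    """Linear schedule for the normalization constant A.

    A interpolates linearly from ``start_value`` to ``end_value`` over
    ``n_steps`` iterations and then holds at ``end_value``.
    """

    start_value: float
    end_value: float
    n_steps: int

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.start_value <= 0 or self.end_value <= 0:
            raise ValueError("annealing values must be positive")

    def value_at(self, iteration: int) -> float:
        if iteration >= self.n_steps:
            return self.end_value
        frac = iteration / self.n_steps
        return self.start_value + frac * (self.end_value - self.start_value)


def init_fields(batch, n_components: int, A: float | None, noise_frac: float, seed) -> np.ndarray:
    """Data-driven initialization: mean stimulus plus uniform jitter.

    Every field starts at the per-pixel mean intensity of the dataset, plus
    independent uniform noise of half-width ``noise_frac`` times the overall
    mean intensity (this is what breaks the symmetry between components).
    Rows are then normalized to ``A`` when given, and clamped to a positive
    floor either way.
    """
    y = check_batch(batch)
    if y.shape[0] == 0:
        raise ValueError("batch must be nonempty")
    if not 0 <= noise_frac < 1:
        raise ValueError("noise_frac must lie in [0, 1)")
    mean = y.mean(axis=0)
    half_width = noise_frac * float(mean.mean())
    rng = np.random.default_rng(seed)
    W = mean[None, :] + rng.uniform(-half_width, half_width, size=(n_components, y.shape[1]))
    if np.any(W <= 0):
        logger.warning("init_fields: clamping nonpositive initial entries to the floor")
        W = np.maximum(W, FIELD_FLOOR)
    W = np.maximum(W, FIELD_FLOOR)
    if A is not None:
        W = normalize_fields(W, A)
    return W


def m_step_constrained(batch, resp, A: float) -> np.ndarray:
    """Constrained M-step: W_cd = A * (sum_n q_nc y_nd) / (sum_n q_nc sum_d' y_nd').

    Every output row sums to A by construction (the denominator is the
    responsibility-weighted total intensity).  Entries are clamped to the
    positive floor afterwards, which matters only for pixels that are never
    active.
    """
    y = check_batch(batch)
    q = check_responsibilities(resp)
    if q.shape[0] != y.shape[0]:
        raise ValueError("batch and responsibilities disagree on N")
    mass = q.sum(axis=0)
    dead = np.flatnonzero(mass <= 1e-12)
    if dead.size:
        raise DeadClassError(int(dead[0]))
    num = q.T @ y                      # C x D
    den = q.T @ y.sum(axis=1)          # C
    W = A * num / den[:, None]
    if np.any(W < FIELD_FLOOR):
        # flooring breaks the exact row-sum identity; restore it
        W = np.maximum(W, FIELD_FLOOR)
        W *= A / W.sum(axis=1, keepdims=True)
    return W


def m_step_unconstrained(batch, resp) -> np.ndarray:
    """Unconstrained M-step: the responsibility-weighted mean of the data."""
    y = check_batch(batch)
    q = check_responsibilities(resp)
    if q.shape[0] != y.shape[0]:
        raise ValueError("batch and responsibilities disagree on N")
    mass = q.sum(axis=0)
    dead = np.flatnonzero(mass <= 1e-12)
    if dead.size:
        raise DeadClassError(int(dead[0]))
    W = (q.T @ y) / mass[:, None]
    return np.maximum(W, FIELD_FLOOR)


class PoissonMixtureEM(DensityMixin, BaseEstimator):
    """Poisson mixture fitted by batch EM, optionally with a normalization
    constraint on the fields and deterministic annealing of its constant.

    Parameters
    ----------
    n_components : int
        Number of mixture components C.
    constrained : bool
        If True, fields are constrained to a common row sum A and the
        compact softmax posterior is used in the E-step.
    A : float or None
        Field normalization constant.  Required when ``constrained``; when
        None in constrained mode, the mean row sum of the training data is
        used (the model-side counterpart of the stimulus normalization).
    tol : float
        Convergence threshold: relative change of the total log-likelihood
        must stay below ``tol`` on two consecutive iterations.
    max_iter : int
        Iteration cap.
    anneal : AnnealSchedule or None
        Optional linear schedule for A (constrained mode only); convergence
        is only tested after the schedule has ended.
    init_noise_frac : float
        Half-width of the uniform initialization jitter, as a fraction of
        the mean pixel intensity.
    snapshot_every : int or None
        Record a copy of the fields every this many iterations.
    random_state : int or None
        Seed for initialization and dead-component rescue draws.

    Attributes
    ----------
    fields_ : ndarray of shape (C, D)
        Learned generative fields.
    priors_ : ndarray of shape (C,)
        Mixing proportions (fixed flat; not learned).
    trace_ : TrainingTrace
        Per-iteration log-likelihood and annealing value.
    n_iter_ : int
        Iterations executed.
    converged_ : bool
    """

    def __init__(
        self,
        n_components: int = 4,
        constrained: bool = True,
        A: float | None = None,
        tol: float = 1e-7,
        max_iter: int = 200,
        anneal: AnnealSchedule | None = None,
        init_noise_frac: float = 0.1,
        snapshot_every: int | None = None,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.constrained = constrained
        self.A = A
        self.tol = tol
        self.max_iter = max_iter
        self.anneal = anneal
        self.init_noise_frac = init_noise_frac
        self.snapshot_every = snapshot_every
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _resolve_A(self, y: np.ndarray) -> float | None:
        if not self.constrained:
            return None
        if self.A is not None:
            return float(self.A)
        return float(y.sum(axis=1).mean())

    def fit(self, X, y=None):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        Xv = check_batch(X, name="X")
        A_final = self._resolve_A(Xv)
        if self.constrained:
            # Poisson draws from normalized fields are only approximately
            # normalized; warn only when the totals are clearly off-scale.
            mean_sum = float(Xv.sum(axis=1).mean())
            if abs(mean_sum - A_final) / A_final > 0.1:
                warnings.warn(
                    "constrained EM expects stimuli whose total intensity "
                    f"matches A={A_final:g}; mean row sum is {mean_sum:g}",
                    stacklevel=2,
                )
        rng = np.random.default_rng(self.random_state)
        C = self.n_components

        if self.anneal is not None and not self.constrained:
            raise ValueError("annealing applies to the constrained model only")

        A0 = self.anneal.value_at(0) if self.anneal is not None else A_final
        W = init_fields(Xv, C, A0 if self.constrained else None,
                        self.init_noise_frac, rng)
        priors = np.full(C, 1.0 / C)

        trace = TrainingTrace(data_hash=dataset_hash(Xv))
        prev_ll = -np.inf
        small_changes = 0
        rescues = 0
        converged = False
        n_iter = 0

        for it in range(self.max_iter):
            if self.anneal is not None:
                A_it = self.anneal.value_at(it)
                if self.constrained:
                    W = normalize_fields(W, A_it)
            else:
                A_it = A_final
            anneal_active = self.anneal is not None and it < self.anneal.n_steps

            mode = "compact" if self.constrained else "full"
            q = posterior(Xv, W, priors, mode=mode)
            _, ll = poisson_log_likelihood(Xv, W, priors)
            trace.append(ll, A_it if A_it is not None else float("nan"))
            if self.snapshot_every and it % self.snapshot_every == 0:
                trace.snapshots.append((it, W.copy()))

            try:
                if self.constrained:
                    W = m_step_constrained(Xv, q, A_it)
                else:
                    W = m_step_unconstrained(Xv, q)
            except DeadClassError as err:
                rescues += 1
                if rescues > _MAX_DEAD_CLASS_RESCUES:
                    raise RuntimeError(
                        "too many dead-component rescues; aborting EM"
                    ) from err
                logger.warning("reseeding dead component %d", err.class_index)
                W = self._reseed_component(W, Xv, err.class_index, A_it, rng)
                prev_ll = -np.inf
                small_changes = 0
                n_iter = it + 1
                continue

            n_iter = it + 1
            rel_change = abs(ll - prev_ll) / max(abs(ll), 1.0)
            if not anneal_active and rel_change < self.tol:
                small_changes += 1
                if small_changes >= 2:
                    converged = True
                    break
            else:
                small_changes = 0
            prev_ll = ll

        self.fields_ = W
        self.priors_ = priors
        self.A_ = A_final
        self.trace_ = trace
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_features_in_ = Xv.shape[1]
        return self

    def _reseed_component(self, W, Xv, c, A_it, rng):
        datum = Xv[rng.integers(Xv.shape[0])]
        jitter = rng.uniform(0, 0.1 * max(datum.mean(), FIELD_FLOOR), size=datum.shape)
        row = np.maximum(datum + jitter, FIELD_FLOOR)
        W = W.copy()
        if self.constrained:
            row = row * (A_it / row.sum())
        W[c] = row
        return W

    # ------------------------------------------------------------------
    def predict_proba(self, X):
        mode = "compact" if self.constrained else "full"
        return posterior(check_batch(X, name="X"), self.fields_, self.priors_, mode=mode)

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)

    def score_samples(self, X):
        per_point, _ = poisson_log_likelihood(check_batch(X, name="X"), self.fields_, self.priors_)
        return per_point

    def score(self, X, y=None):
        return float(np.mean(self.score_samples(X)))


@dataclass
class EMConfig:
    """Bag of EM hyperparameters for the functional interface."""

    n_classes: int = 4
    mode: str = "constrained"  # or "unconstrained"
    A: float | None = None
    max_iters: int = 200
    rel_tol: float = 1e-7
    anneal: AnnealSchedule | None = None
    seed: int | None = None
    init_noise_frac: float = 0.1

    def __post_init__(self):
        if self.mode not in ("constrained", "unconstrained"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.max_iters < 1 or self.rel_tol <= 0:
            raise ValueError("max_iters must be >= 1 and rel_tol > 0")
        if not 0 <= self.init_noise_frac < 1:
            raise ValueError("init_noise_frac must lie in [0, 1)")


def run_em(batch, config: EMConfig):
    """Run batch EM as configured; returns ``((fields, priors), trace)``."""
    est = PoissonMixtureEM(
        n_components=config.n_classes,
        constrained=config.mode == "constrained",
        A=config.A,
        tol=config.rel_tol,
        max_iter=config.max_iters,
        anneal=config.anneal,
        init_noise_frac=config.init_noise_frac,
        random_state=config.seed,
    ).fit(batch)
    return (est.fields_, est.priors_), est.trace_
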