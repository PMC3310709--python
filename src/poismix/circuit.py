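"""Online neural-circuit learner for normalized stimuli.

The circuit is a single layer of C processing neurons receiving a D-pixel
stimulus through excitatory weights W.  Three mechanisms interact:

* **Feedforward inhibition** — fast, unspecific inhibition modeled as exact
  divisive normalization of each stimulus to a constant total intensity A
  (optionally with a unit background offset that keeps converged weights at
  or above one, where the logarithmic synaptic transform is exact).
* **Softmax lateral competition** — neuron activities are
  ``g = softmax(I)`` with synaptic drive ``I_c = sum_d y_d f(W_cd)``, where
  ``f`` is either a logarithm saturating for weights above one or a plain
  linear transform.  With log-saturating synapses and weights >= 1 the
  activity equals the compact mixture posterior exactly.
* **Hebbian plasticity with synaptic scaling** —
  ``dW_cd = eps * g_c * (y_d - W_cd)``: a Hebbian term plus an
  activity-gated decay toward the input.  With normalized inputs this pins
  every weight row sum to the stimulus total, so the circuit performs an
  online approximation of constrained EM without any global normalization
  signal.  Control variants replace scaling by explicit per-row weight
  normalization or drop it entirely.

The per-datum update loop is compiled with numba; the single-step functions
(:func:`transfer`, :func:`plasticity_update`) are the plain-numpy reference
the kernel is cross-checked against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, TransformerMixin

from .em import init_fields
from .mixture import FIELD_FLOOR, check_batch, check_fields, normalize_fields, poisson_log_likelihood
from .trace import TrainingTrace, dataset_hash

_DIVERGENCE_CAP = 1e6

_CONSTRAINT_CODES = {"synaptic_scaling": 0, "explicit_norm": 1, "none": 2}


class DivergenceError(RuntimeError):
    """Weights exceeded the divergence cap or became non-finite."""

    def __init__(self, epoch: int, trace: TrainingTrace):
        self.epoch = epoch
        self.trace = trace
        super().__init__(f"weight divergence detected at epoch {epoch}")


@dataclass
class CircuitConfig:
    """Hyperparameters of the online learner (functional interface)."""

    n_neurons: int = 4
    variant: str = "linear"               # or "log_saturating"
    ffi_mode: str = "plain"               # "plain" | "offset" | "off"
    weight_constraint: str = "synaptic_scaling"  # | "explicit_norm" | "none"
    A: float = 300.0
    learning_rate: float = 1.5e-3
    n_epochs: int = 60
    seed: int | None = None
    init_noise_frac: float = 0.1

    def __post_init__(self):
        if self.variant not in ("linear", "log_saturating"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.ffi_mode not in ("plain", "offset", "off"):
            raise ValueError(f"unknown ffi_mode {self.ffi_mode!r}")
        if self.weight_constraint not in _CONSTRAINT_CODES:
            raise ValueError(f"unknown weight_constraint {self.weight_constraint!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.learning_rate > 0.1:
            warnings.warn("learning_rate above 0.1; online updates assume a small rate")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


# ---------------------------------------------------------------------------
# single-step reference operations

def feedforward_normalize(raw, A: float, mode: str = "plain") -> np.ndarray:
    """Normalize raw stimuli to a constant total intensity.

    ``plain``:  y = A * raw / sum(raw), so every row sums to A.
    ``offset``: y = A * raw / sum(raw) + 1, adding a unit background on every
    pixel; rows then sum to A + D (the effective normalization constant) and
    pixels carrying at least an average share of input are >= 1, which keeps
    the converged weights in the regime where the log transform applies.
    """
    y = check_batch(raw, name="raw")
    if not A > 0:
        raise ValueError("A must be positive")
    sums = y.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"degenerate stimulus: row {int(zero[0])} sums to zero")
    out = A * y / sums[:, None]
    if mode == "plain":
        return out
    if mode == "offset":
        return out + 1.0
    raise ValueError(f"unknown mode {mode!r}")


def synaptic_transform(weights, variant: str) -> np.ndarray:
    """Elementwise synaptic transform f(w).

    ``log_saturating``: f(w) = log w for w >= 1, w - 1 below (continuous in
    value and slope at w = 1).  ``linear``: f(w) = w - 1 everywhere.
    """
    W = np.asarray(weights, dtype=np.float64)
    if variant == "linear":
        return W - 1.0
    if variant == "log_saturating":
        return np.where(W >= 1.0, np.log(np.maximum(W, FIELD_FLOOR)), W - 1.0)
    raise ValueError(f"unknown variant {variant!r}")


def transfer(weights, y, variant: str) -> np.ndarray:
    """Softmax neuron activities for stimuli ``y`` (single vector or batch).

    g = softmax over the synaptic drive I_c = sum_d y_d f(W_cd), max-shifted.
    Equals the compact mixture posterior when ``variant='log_saturating'``
    and all weights are >= 1.
    """
    W = check_fields(weights, name="weights")
    y = np.asarray(y, dtype=np.float64)
    single = y.ndim == 1
    yb = y[None, :] if single else y
    drive = yb @ synaptic_transform(W, variant).T
    if not np.all(np.isfinite(drive)):
        raise FloatingPointError("non-finite synaptic drive")
    drive -= drive.max(axis=1, keepdims=True)
    g = np.exp(drive)
    g /= g.sum(axis=1, keepdims=True)
    return g[0] if single else g


def plasticity_update(
    weights,
    y,
    activity,
    eps: float,
    weight_constraint: str = "synaptic_scaling",
    A: float | None = None,
) -> np.ndarray:
    """One online weight update for a single stimulus.

    synaptic_scaling:  W += eps * g[:, None] * (y - W)
    explicit_norm:     W += eps * g[:, None] * y, then each row rescaled to
                       sum to A (the biologically non-local control)
    none:              pure Hebbian growth W += eps * g[:, None] * y
    """
    W = np.asarray(weights, dtype=np.float64).copy()
    y = np.asarray(y, dtype=np.float64)
    g = np.asarray(activity, dtype=np.float64)
    if eps <= 0:
        raise ValueError("eps must be positive")
    if weight_constraint == "synaptic_scaling":
        W += eps * g[:, None] * (y[None, :] - W)
    elif weight_constraint == "explicit_norm":
        if A is None:
            raise ValueError("explicit_norm requires A")
        W += eps * g[:, None] * y[None, :]
        W *= A / W.sum(axis=1, keepdims=True)
    elif weight_constraint == "none":
        W += eps * g[:, None] * y[None, :]
    else:
        raise ValueError(f"unknown weight_constraint {weight_constraint!r}")
    return np.maximum(W, FIELD_FLOOR)


# ---------------------------------------------------------------------------
# compiled epoch kernel

@njit(cache=False)
def _epoch_kernel(W, X, order, eps, log_variant, constraint, A, floor):  # pragma: no cover
    N, D = X.shape
    C = W.shape[0]
    drive = np.empty(C)
    for i in range(N):
        n = order[i]
        for c in range(C):
            s = 0.0
            for d in range(D):
                w = W[c, d]
                if log_variant and w >= 1.0:
                    fw = np.log(w)
                else:
                    fw = w - 1.0
                s += X[n, d] * fw
            drive[c] = s
        m = drive[0]
        for c in range(1, C):
            if drive[c] > m:
                m = drive[c]
        Z = 0.0
        for c in range(C):
            drive[c] = np.exp(drive[c] - m)
            Z += drive[c]
        for c in range(C):
            drive[c] /= Z
        if constraint == 0:  # synaptic scaling
            for c in range(C):
                gc = eps * drive[c]
                for d in range(D):
                    w = W[c, d] + gc * (X[n, d] - W[c, d])
                    W[c, d] = w if w > floor else floor
        elif constraint == 1:  # explicit per-row normalization
            for c in range(C):
                gc = eps * drive[c]
                rs = 0.0
                for d in range(D):
                    w = W[c, d] + gc * X[n, d]
                    W[c, d] = w
                    rs += w
                sc = A / rs
                for d in range(D):
                    w = W[c, d] * sc
                    W[c, d] = w if w > floor else floor
        else:  # pure Hebbian
            for c in range(C):
                gc = eps * drive[c]
                for d in range(D):
                    w = W[c, d] + gc * X[n, d]
                    W[c, d] = w if w > floor else floor


class NeuralCircuitLearner(TransformerMixin, BaseEstimator):
    """Online Hebbian learner with feedforward normalization and softmax
    competition, scikit-learn style.

    ``fit(X)`` normalizes the stimuli (per ``ffi_mode``), initializes the
    weights from the data mean plus jitter, then performs one per-datum
    update per stimulus per epoch, visiting the data in a fresh seeded
    permutation each epoch.  ``transform(X)`` returns the neuron activities
    (posterior-like responsibilities) for new stimuli.

    Parameters mirror :class:`CircuitConfig`; additionally ``init_weights``
    lets a run start from given weights (e.g. an EM solution).

    Attributes
    ----------
    weights_ : ndarray (C, D)
        Learned synaptic weights.
    trace_ : TrainingTrace
        Per-epoch data log-likelihood (weights read as mixture fields on a
        row-normalized copy) and the effective normalization constant.
    A_eff_ : float
        Row sum enforced on the inputs (A, A + D, or nan when ffi is off).
    """

    def __init__(
        self,
        n_neurons: int = 4,
        variant: str = "linear",
        ffi_mode: str = "plain",
        weight_constraint: str = "synaptic_scaling",
        A: float = 300.0,
        learning_rate: float = 1.5e-3,
        n_epochs: int = 60,
        init_noise_frac: float = 0.1,
        init_weights=None,
        snapshot_every: int | None = None,
        random_state: int | None = None,
    ):
        self.n_neurons = n_neurons
        self.variant = variant
        self.ffi_mode = ffi_mode
        self.weight_constraint = weight_constraint
        self.A = A
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.init_noise_frac = init_noise_frac
        self.init_weights = init_weights
        self.snapshot_every = snapshot_every
        self.random_state = random_state

    def _config(self) -> CircuitConfig:
        return CircuitConfig(
            n_neurons=self.n_neurons,
            variant=self.variant,
            ffi_mode=self.ffi_mode,
            weight_constraint=self.weight_constraint,
            A=self.A,
            learning_rate=self.learning_rate,
            n_epochs=self.n_epochs,
            seed=self.random_state,
            init_noise_frac=self.init_noise_frac,
        )

    def fit(self, X, y=None):
        cfg = self._config()  # validates
        Xraw = check_batch(X, name="X")
        if cfg.ffi_mode == "off":
            Xn = Xraw
            A_eff = float("nan")
        else:
            Xn = feedforward_normalize(Xraw, cfg.A, mode=cfg.ffi_mode)
            A_eff = cfg.A if cfg.ffi_mode == "plain" else cfg.A + Xraw.shape[1]

        seed = self.random_state if self.random_state is not None else 0
        if self.init_weights is not None:
            W = check_fields(self.init_weights, name="init_weights").copy()
        else:
            init_A = A_eff if cfg.ffi_mode != "off" else None
            W = init_fields(Xn, cfg.n_neurons, init_A, cfg.init_noise_frac, seed)
        W = np.ascontiguousarray(W)
        Xc = np.ascontiguousarray(Xn)

        trace = TrainingTrace(data_hash=dataset_hash(Xn))
        log_variant = cfg.variant == "log_saturating"
        constraint = _CONSTRAINT_CODES[cfg.weight_constraint]

        for epoch in range(cfg.n_epochs):
            order = np.random.default_rng([seed, epoch]).permutation(Xc.shape[0])
            _epoch_kernel(
                W, Xc, order, cfg.learning_rate, log_variant, constraint,
                cfg.A, FIELD_FLOOR,
            )
            if not np.all(np.isfinite(W)) or np.max(W) > _DIVERGENCE_CAP:
                raise DivergenceError(epoch, trace)
            trace.append(self._monitor_loglik(Xc, W), A_eff)
            if self.snapshot_every and epoch % self.snapshot_every == 0:
                trace.snapshots.append((epoch, W.copy()))

        self.weights_ = W
        self.trace_ = trace
        self.A_eff_ = A_eff
        self.n_features_in_ = Xraw.shape[1]
        return self

    @staticmethod
    def _monitor_loglik(Xn: np.ndarray, W: np.ndarray) -> float:
        """Constrained-model log-likelihood of the data under a
        row-normalized *copy* of the weights (live weights untouched)."""
        target = float(Xn.sum(axis=1).mean())
        Wn = normalize_fields(np.maximum(W, FIELD_FLOOR), target)
        _, total = poisson_log_likelihood(Xn, Wn)
        return total

    def transform(self, X):
        Xv = check_batch(X, name="X")
        if self.ffi_mode != "off":
            Xv = feedforward_normalize(Xv, self.A, mode=self.ffi_mode)
        return transfer(self.weights_, Xv, self.variant)

    def predict(self, X):
        return np.argmax(self.transform(X), axis=1)


def train_circuit(batch, config: CircuitConfig, init_weights=None):
    """Functional wrapper: returns ``(weights, trace)``."""
    est = NeuralCircuitLearner(
        n_neurons=config.n_neurons,
        variant=config.variant,
        ffi_mode=config.ffi_mode,
        weight_constraint=config.weight_constraint,
        A=config.A,
        learning_rate=config.learning_rate,
        n_epochs=config.n_epochs,
        init_noise_frac=config.init_noise_frac,
        init_weights=init_weights,
        random_state=config.seed,
    ).fit(batch)
    return est.weights_, est.trace_


def fixed_point_residual(weights, batch, variant: str) -> np.ndarray:
    """Relative deviation of weights from their theoretical fixed point.

    At convergence of the synaptic-scaling rule the weights satisfy
    ``W_cd = <g_c y_d> / <g_c>`` with averages over the stimulus ensemble and
    activities computed at the converged weights.  Returns
    ``|W - W_hat| / max(W, floor)`` per weight; neurons that are never active
    get a sentinel residual of +inf.
    """
    W = check_fields(weights, name="weights")
    y = check_batch(batch)
    g = transfer(W, y, variant)              # N x C
    mass = g.sum(axis=0)                     # C
    resid = np.full_like(W, np.inf)
    alive = mass > 0
    W_hat = np.empty_like(W)
    W_hat[alive] = (g.T[alive] @ y) / mass[alive, None]
    resid[alive] = np.abs(W[alive] - W_hat[alive]) / np.maximum(W[alive], FIELD_FLOOR)
    return resid
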