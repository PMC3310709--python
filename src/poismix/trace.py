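"""Training trajectory record shared by batch EM and the online circuit."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np


def dataset_hash(X) -> str:
    """Stable content hash of a data matrix (used to refuse cross-dataset
    trace comparisons)."""
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    return hashlib.sha1(X.tobytes()).hexdigest()


@dataclass
class TrainingTrace:
    """Per-iteration (EM) or per-epoch (circuit) learning trajectory.

    ``loglik_per_iter`` holds the total data log-likelihood, and
    ``anneal_value_per_iter`` the normalization constant in force at that
    iteration (constant when no annealing is used).  ``snapshots`` optionally
    stores sparse ``(iteration, weights)`` pairs.
    """

    loglik_per_iter: list[float] = field(default_factory=list)
    anneal_value_per_iter: list[float] = field(default_factory=list)
    snapshots: list[tuple[int, np.ndarray]] = field(default_factory=list)
    data_hash: str | None = None

    def append(self, loglik: float, anneal_value: float) -> None:
        self.loglik_per_iter.append(float(loglik))
        self.anneal_value_per_iter.append(float(anneal_value))

    @property
    def final_loglik(self) -> float:
        return self.loglik_per_iter[-1]

    def __len__(self) -> int:
        return len(self.loglik_per_iter)
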