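"""Synthetic "blocks" stimuli: overlapping rectangles on a flat background.

Each generative field is a constant background with one brighter filled
rectangle; rectangles of different classes must mutually overlap by a
bounded fraction, which controls how ambiguous the classes are and hence how
prone learning is to locally optimal solutions.  Stimuli are Poisson draws
from these fields.  The constrained variant normalizes every field to a
common total intensity A; the unconstrained variant (used for the
normalization-ablation experiments) applies one global rescaling instead, so
different classes keep different totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mixture import sample_mixture

_MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass
class BlocksSpec:
    """Parameters of the blocks generator.

    Defaults: a 16x16 grid (D = 256), four classes, rectangle sides of 5-9
    pixels, pairwise overlap between 1% and 50% of the smaller rectangle,
    unit background.  ``A`` set -> constrained fields (rows sum to A);
    ``A`` None with ``mean_intensity`` set -> unconstrained variant whose
    grand pixel mean equals ``mean_intensity``.
    """

    grid_height: int = 16
    grid_width: int = 16
    n_classes: int = 4
    block_size_range: tuple[int, int] = (5, 9)
    overlap_range: tuple[float, float] = (0.01, 0.5)
    background: float = 1.0
    A: float | None = 300.0
    mean_intensity: float | None = None
    rect_contrast: float = 2.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.block_size_range
        if not (1 <= lo <= hi <= min(self.grid_height, self.grid_width)):
            raise ValueError("block sizes must fit the grid")
        olo, ohi = self.overlap_range
        if not (0 < olo <= ohi <= 0.5):
            raise ValueError("overlap_range must lie inside (0, 0.5]")
        if self.background <= 0:
            raise ValueError("background must be positive")
        if self.A is not None and self.A <= 0:
            raise ValueError("A must be positive")
        if self.rect_contrast <= 1:
            raise ValueError("rect_contrast must exceed 1")

    @property
    def n_pixels(self) -> int:
        return self.grid_height * self.grid_width


def _overlap_fraction(r1, r2) -> float:
    """Intersection area over the smaller rectangle's area.

    Rectangles are (top, left, height, width).
    """
    t1, l1, h1, w1 = r1
    t2, l2, h2, w2 = r2
    ih = min(t1 + h1, t2 + h2) - max(t1, t2)
    iw = min(l1 + w1, l2 + w2) - max(l1, l2)
    inter = max(ih, 0) * max(iw, 0)
    return inter / min(h1 * w1, h2 * w2)


def _sample_rects(spec: BlocksSpec, rng: np.random.Generator) -> list[tuple[int, int, int, int]]:
    lo, hi = spec.block_size_range
    olo, ohi = spec.overlap_range
    attempts = 0
    while attempts < _MAX_PLACEMENT_ATTEMPTS:
        rects: list[tuple[int, int, int, int]] = []
        stuck = False
        while len(rects) < spec.n_classes and not stuck:
            # up to 200 placements for this rectangle, then restart from
            # scratch: earlier placements may have made the constraint
            # unsatisfiable
            for _ in range(200):
                if attempts >= _MAX_PLACEMENT_ATTEMPTS:
                    break
                attempts += 1
                h = int(rng.integers(lo, hi + 1))
                w = int(rng.integers(lo, hi + 1))
                t = int(rng.integers(0, spec.grid_height - h + 1))
                left = int(rng.integers(0, spec.grid_width - w + 1))
                cand = (t, left, h, w)
                if all(olo <= _overlap_fraction(cand, r) <= ohi for r in rects):
                    rects.append(cand)
                    break
            else:
                stuck = True
            if attempts >= _MAX_PLACEMENT_ATTEMPTS and len(rects) < spec.n_classes:
                stuck = True
        if len(rects) == spec.n_classes:
            return rects
    raise RuntimeError(
        "could not place rectangles satisfying the overlap constraint; "
        "loosen the spec (sizes, overlap range, grid)"
    )


def _rects_to_fields(spec: BlocksSpec, rects) -> np.ndarray:
    """Fields at the template contrast: background plus a rectangle at
    ``rect_contrast`` times the background (used by the unconstrained
    variant; the constrained variant's contrast is set by A instead)."""
    W = np.full((spec.n_classes, spec.n_pixels), spec.background, dtype=np.float64)
    for c, (t, left, h, w) in enumerate(rects):
        img = W[c].reshape(spec.grid_height, spec.grid_width)
        img[t : t + h, left : left + w] = spec.rect_contrast * spec.background
    return W


def make_blocks_fields(spec: BlocksSpec) -> np.ndarray:
    """Generate constrained blocks fields (each row summing to spec.A).

    The background stays at exactly ``spec.background`` (1 by default) and
    the rectangle absorbs the normalization: its per-pixel elevation is
    ``(A - D * background) / area``, so smaller rectangles are brighter.
    Keeping the background at one places the converged weights in the regime
    where the log-saturating synaptic transform reproduces the mixture
    posterior exactly.  Requires ``A > D * background``.
    """
    if spec.A is None:
        raise ValueError("constrained fields require spec.A; "
                         "use make_unconstrained_fields otherwise")
    base = spec.n_pixels * spec.background
    if spec.A <= base:
        raise ValueError(
            f"A must exceed the background total {base:g} "
            "(the rectangle carries the remaining intensity)"
        )
    rng = np.random.default_rng([spec.seed, 0])
    rects = _sample_rects(spec, rng)
    W = np.full((spec.n_classes, spec.n_pixels), spec.background, dtype=np.float64)
    for c, (t, left, h, w) in enumerate(rects):
        img = W[c].reshape(spec.grid_height, spec.grid_width)
        img[t : t + h, left : left + w] += (spec.A - base) / (h * w)
    return W


def make_unconstrained_fields(spec: BlocksSpec) -> np.ndarray:
    """Blocks fields with one *global* rescaling instead of per-row
    normalization: the grand mean over all pixels of all fields equals
    ``spec.mean_intensity``, while rows keep different totals (larger
    rectangles -> larger totals)."""
    if spec.A is not None:
        raise ValueError("unconstrained fields require spec.A = None")
    if spec.mean_intensity is None or spec.mean_intensity <= 0:
        raise ValueError("unconstrained fields require a positive mean_intensity")
    rng = np.random.default_rng([spec.seed, 0])
    W = _rects_to_fields(spec, _sample_rects(spec, rng))
    return W * (spec.mean_intensity / W.mean())


def generate_blocks_dataset(spec: BlocksSpec, n_samples: int):
    """Fields + Poisson dataset with flat class priors.

    Returns ``(X, labels, fields)``; ``X`` is the raw (un-renormalized)
    Poisson sample, ``labels`` and ``fields`` are ground truth for
    evaluation.
    """
    if spec.A is not None:
        W = make_blocks_fields(spec)
    else:
        W = make_unconstrained_fields(spec)
    X, labels = sample_mixture(W, n_samples, np.random.default_rng([spec.seed, 1]))
    return X, labels, W
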