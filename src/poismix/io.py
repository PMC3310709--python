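"""Plain-text and PNG serialization for fields, batches and traces."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .trace import TrainingTrace


def save_fields_csv(path, fields, A: float | None = None) -> None:
    """Write a field/weight matrix row-major as CSV with a comment header
    recording C, D and (when constrained) A."""
    W = np.asarray(fields, dtype=np.float64)
    C, D = W.shape
    header = f"C={C} D={D}" + (f" A={A}" if A is not None else "")
    np.savetxt(path, W, delimiter=",", header=header)


def load_fields_csv(path):
    """Read a field matrix written by :func:`save_fields_csv`.

    Returns ``(fields, A)`` with ``A`` None when absent from the header.
    """
    A = None
    with open(path) as f:
        first = f.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if token.startswith("A="):
                A = float(token[2:])
    W = np.loadtxt(path, delimiter=",", ndmin=2)
    return W, A


def save_batch_csv(path, X, manifest_path=None, manifest: dict | None = None) -> None:
    X = np.asarray(X, dtype=np.float64)
    np.savetxt(path, X, delimiter=",", header=f"N={X.shape[0]} D={X.shape[1]}")
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest or {}, indent=2, default=str))


def save_trace_csv(path, trace: TrainingTrace) -> None:
    rows = np.column_stack([
        np.arange(len(trace)),
        trace.loglik_per_iter,
        trace.anneal_value_per_iter,
    ])
    np.savetxt(path, rows, delimiter=",", header="iteration,loglik,anneal_value")


def load_trace_csv(path) -> TrainingTrace:
    rows = np.loadtxt(path, delimiter=",", ndmin=2)
    return TrainingTrace(
        loglik_per_iter=list(rows[:, 1]),
        anneal_value_per_iter=list(rows[:, 2]),
    )


def save_predictions_csv(path, labels) -> None:
    labels = np.asarray(labels)
    rows = np.column_stack([np.arange(labels.shape[0]), labels])
    np.savetxt(path, rows, fmt="%d", delimiter=",", header="index,label")


def fields_to_png(path, fields, grid_shape: tuple[int, int], n_cols: int = 4) -> None:
    """Render each field as a grayscale tile (linear intensity scaling over
    the whole matrix) and lay the tiles out on a grid."""
    W = np.asarray(fields, dtype=np.float64)
    C = W.shape[0]
    h, w = grid_shape
    if h * w != W.shape[1]:
        raise ValueError("grid_shape does not match the number of pixels")
    lo, hi = W.min(), W.max()
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    n_cols = min(n_cols, C)
    n_rows = -(-C // n_cols)
    pad = 2
    canvas = np.zeros((n_rows * (h + pad) - pad, n_cols * (w + pad) - pad), dtype=np.uint8)
    for c in range(C):
        tile = ((W[c].reshape(h, w) - lo) * scale).astype(np.uint8)
        r, col = divmod(c, n_cols)
        canvas[r * (h + pad): r * (h + pad) + h, col * (w + pad): col * (w + pad) + w] = tile
    img = Image.fromarray(canvas, mode="L")
    img.info["scaling"] = f"linear min={lo:g} max={hi:g}"
    img.save(path)
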