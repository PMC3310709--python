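"""Reader/writer for the IDX binary container (MNIST images and labels).

Big-endian, magic 0x00000803 for uint8 image tensors (N x rows x cols) and
0x00000801 for uint8 label vectors.  The writer exists mainly so tests can
round-trip small synthetic fixtures; no download logic is provided.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_IMAGES_MAGIC = 0x00000803
_LABELS_MAGIC = 0x00000801


class IdxFormatError(ValueError):
    def __init__(self, path, offset: int, message: str):
        super().__init__(f"{path}: {message} (byte offset {offset})")
        self.offset = offset


def _read_exact(f, n: int, path, what: str) -> bytes:
    data = f.read(n)
    if len(data) != n:
        raise IdxFormatError(path, f.tell(), f"truncated file while reading {what}")
    return data


def read_idx(images_path, labels_path, rescale: bool = False):
    """Read an IDX image/label pair.

    Returns ``(X, labels)`` with images flattened row-major to an N x D float
    matrix of values in [0, 255] (divided by 255 when ``rescale``) and labels
    as an integer vector.  Image and label counts must agree.
    """
    images_path, labels_path = Path(images_path), Path(labels_path)
    with open(images_path, "rb") as f:
        magic, n, rows, cols = struct.unpack(
            ">IIII", _read_exact(f, 16, images_path, "image header")
        )
        if magic != _IMAGES_MAGIC:
            raise IdxFormatError(images_path, 0, f"bad image magic 0x{magic:08x}")
        raw = _read_exact(f, n * rows * cols, images_path, "image data")
    X = np.frombuffer(raw, dtype=np.uint8).astype(np.float64).reshape(n, rows * cols)

    with open(labels_path, "rb") as f:
        magic, n_labels = struct.unpack(
            ">II", _read_exact(f, 8, labels_path, "label header")
        )
        if magic != _LABELS_MAGIC:
            raise IdxFormatError(labels_path, 0, f"bad label magic 0x{magic:08x}")
        raw = _read_exact(f, n_labels, labels_path, "label data")
    labels = np.frombuffer(raw, dtype=np.uint8).astype(np.int64)

    if n != n_labels:
        raise IdxFormatError(
            labels_path, 8, f"image count {n} != label count {n_labels}"
        )
    if rescale:
        X = X / 255.0
    return X, labels


def write_idx(images, labels, images_path, labels_path) -> None:
    """Write uint8 images (N x rows x cols) and labels to IDX files."""
    images = np.asarray(images)
    labels = np.asarray(labels)
    if images.ndim != 3:
        raise ValueError("images must have shape (N, rows, cols)")
    n, rows, cols = images.shape
    if labels.shape != (n,):
        raise ValueError("labels must have shape (N,)")
    with open(images_path, "wb") as f:
        f.write(struct.pack(">IIII", _IMAGES_MAGIC, n, rows, cols))
        f.write(np.ascontiguousarray(images, dtype=np.uint8).tobytes())
    with open(labels_path, "wb") as f:
        f.write(struct.pack(">II", _LABELS_MAGIC, n))
        f.write(np.ascontiguousarray(labels, dtype=np.uint8).tobytes())
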