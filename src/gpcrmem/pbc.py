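"""Minimum-image geometry for orthorhombic periodic boxes."""

from __future__ import annotations

import numpy as np

from .model import Box

__all__ = ["min_image_displacement", "min_image_distance", "wrap_into_box"]


def min_image_displacement(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """Displacement ``b - a`` wrapped component-wise into ``[-L/2, L/2)``.

    Broadcasts over leading dimensions, so ``a`` and ``b`` may be arrays of
    points.  The Euclidean norm of the result is the minimum-image distance.
    """
    lengths = box.lengths
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - lengths * np.floor(d / lengths + 0.5)


def min_image_distance(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """Minimum-image Euclidean distance between points (broadcasting)."""
    return np.linalg.norm(min_image_displacement(a, b, box), axis=-1)


def wrap_into_box(coords: np.ndarray, box: Box) -> np.ndarray:
    """Wrap coordinates into the primary cell ``[0, L)`` per component."""
    lengths = box.lengths
    return np.mod(coords, lengths)
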