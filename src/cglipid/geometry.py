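"""Periodic-boundary geometry helpers (orthorhombic boxes only)."""

from __future__ import annotations

import numpy as np

__all__ = ["minimum_image", "pair_displacements", "all_pair_distances"]


def minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    box = np.asarray(box, dtype=np.float64)
    return disp - box * np.round(disp / box)


def pair_displacements(coords: np.ndarray, pairs: np.ndarray, box: np.ndarray):
    """Minimum-image displacement r_j - r_i and distances for index pairs."""
    pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
    disp = minimum_image(coords[pairs[:, 1]] - coords[pairs[:, 0]], box)
    return disp, np.linalg.norm(disp, axis=1)


def all_pair_distances(coords: np.ndarray, box: np.ndarray):
    """All unordered pairs (i<j) with minimum-image distances. O(N^2)."""
    n = len(coords)
    ii, jj = np.triu_indices(n, k=1)
    pairs = np.column_stack([ii, jj])
    _, d = pair_displacements(coords, pairs, box)
    return pairs, d
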