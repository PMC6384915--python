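"""Periodic-box geometry primitives.

All analysis in this package runs in a cubic periodic box, so every distance
is a minimum-image distance.  Coordinates are in angstroms throughout.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

AVOGADRO = 6.02214076e23  # 1/mol


def min_image_displacement(a: np.ndarray, b: np.ndarray, box_edge: float) -> np.ndarray:
    """Displacement b - a under the cubic minimum-image convention.

    Broadcasts over leading dimensions; the last axis must be length 3.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box_edge * np.round(d / box_edge)


def min_image_distance(a, b, box_edge: float):
    """Euclidean distance between points under the cubic minimum-image convention.

    Parameters
    ----------
    a, b : array-like, shape (..., 3)
        Cartesian coordinates in angstrom.
    box_edge : float
        Edge length of the cubic periodic box (angstrom); must be > 0.
    """
    if box_edge <= 0:
        raise ValueError("box_edge must be positive")
    d = min_image_displacement(a, b, box_edge)
    return np.sqrt(np.sum(d * d, axis=-1))


def wrap_coordinates(coords: np.ndarray, box_edge: float) -> np.ndarray:
    """Map coordinates into the primary cell [0, box_edge)."""
    return np.mod(coords, box_edge)


def periodic_pairs(coords: np.ndarray, cutoff: float, box_edge: float) -> np.ndarray:
    """All unordered index pairs with minimum-image distance < ``cutoff``.

    Uses a periodic k-d tree (cell-list equivalent); results are identical to
    the all-pairs minimum-image search.  Returns an (n_pairs, 2) int array
    with i < j, sorted lexicographically for deterministic downstream output.
    """
    if cutoff * 2.0 >= box_edge:
        # KD-tree periodic queries require cutoff < box/2; fall back to brute force.
        n = len(coords)
        d = min_image_distance(coords[:, None, :], coords[None, :, :], box_edge)
        ii, jj = np.where(np.triu(d < cutoff, k=1))
        return np.stack([ii, jj], axis=1)
    wrapped = wrap_coordinates(coords, box_edge)
    # guard against coords == box_edge after mod with floating error
    wrapped[wrapped >= box_edge] = 0.0
    tree = cKDTree(wrapped, boxsize=box_edge)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.intp)
    pairs = np.sort(pairs, axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


def solute_concentration(n_molecules: int, box_edge: float) -> float:
    """Molar concentration (mM) of ``n_molecules`` solutes in a cubic box.

    box_edge is in angstrom; 1 A^3 = 1e-27 L.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if box_edge <= 0:
        raise ValueError("box_edge must be positive")
    volume_litre = (box_edge ** 3) * 1e-27
    return 1000.0 * n_molecules / (AVOGADRO * volume_litre)
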