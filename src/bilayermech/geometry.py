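"""Periodic-geometry utilities for orthorhombic boxes.

All coordinates and box lengths are in Ångström. Only rectangular
(orthorhombic) boxes are supported; every distance below uses the
minimum-image convention, either in all three dimensions or laterally
(x, y) only, which is the natural metric for in-plane leaflet statistics.
"""

from __future__ import annotations

import numpy as np

__all__ = ["minimum_image_displacement", "wrap_positions", "pairwise_min_image_distances"]


def _wrap(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    # maps each component into the half-open interval [-L/2, L/2)
    return d - box * np.floor(d / box + 0.5)


def minimum_image_displacement(a, b, box, mode: str = "xyz") -> np.ndarray:
    """Minimum-image displacement ``a - b``.

    Parameters
    ----------
    a, b : array_like, shape (..., 3)
        Positions in Å. Broadcast against each other.
    box : array_like, shape (3,)
        Orthorhombic edge lengths (Lx, Ly, Lz) in Å, all positive.
    mode : {"xyz", "xy"}
        ``"xy"`` wraps only the lateral components, leaving Δz untouched;
        use it for in-plane leaflet distances.

    Returns
    -------
    ndarray, shape (..., 3)
        Each wrapped component lies in ``[-L/2, L/2)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    d = a - b
    if mode == "xyz":
        return _wrap(d, box)
    if mode == "xy":
        out = d.copy()
        out[..., :2] = _wrap(d[..., :2], box[:2])
        return out
    raise ValueError(f"unknown mode {mode!r}")


def wrap_positions(coords, box) -> np.ndarray:
    """Wrap positions into the primary cell [0, L) per dimension."""
    coords = np.asarray(coords, dtype=float)
    box = np.asarray(box, dtype=float)
    return coords - box * np.floor(coords / box)


def pairwise_min_image_distances(x, y, box, mode: str = "xyz") -> np.ndarray:
    """Dense matrix of minimum-image distances between two point sets.

    ``mode="xy"`` gives lateral distances (the z component is ignored,
    not merely unwrapped). Intended for modest point counts; contact
    searches on large leaflets should go through a periodic KD-tree.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = minimum_image_displacement(x[:, None, :], y[None, :, :], box, mode="xyz")
    if mode == "xy":
        return np.sqrt(d[..., 0] ** 2 + d[..., 1] ** 2)
    return np.linalg.norm(d, axis=-1)
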