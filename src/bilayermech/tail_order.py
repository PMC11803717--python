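"""Acyl-tail carbon–carbon order parameters.

For carbon i of a tail, S_C(i) = ⟨(3 cos²θ_i − 1)/2⟩ where θ_i is the
angle between the membrane normal (the box z-axis) and the vector joining
carbons C_{i−1} and C_{i+1}. S_C = 1 for chains aligned with the normal,
−0.5 for chains lying in the membrane plane, 0 for isotropic orientations.
Both leaflets are pooled (cos² makes the normal's sign irrelevant), and
the average runs over molecules and frames; the quoted standard error is
autocorrelation-corrected over the per-frame means.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .frames import BoxedFrame, GroupMap
from .geometry import minimum_image_displacement
from .mechanics import autocorr_sem

__all__ = ["chain_vector", "order_parameter_profile"]


def _chain_positions(frame: BoxedFrame, gmap: GroupMap, species: str, chain: str) -> np.ndarray:
    """Coordinates of one chain for every molecule of a species.

    Returns an (n_molecules, n_carbons, 3) array ordered from the
    glycerol end to the terminal methyl.
    """
    smap = gmap.require(species)
    labels = smap.chains.get(chain)
    if not labels:
        raise KeyError(f"species {species!r} has no chain {chain!r} in the group map")
    pos_in_chain = {lab: k for k, lab in enumerate(labels)}
    sel = (frame.species == species) & np.isin(frame.names, labels)
    if not sel.any():
        raise ValueError(f"species {species!r} absent from frame")
    mols = frame.molecule[sel]
    order_keys = np.array([pos_in_chain[n] for n in frame.names[sel]])
    coords = frame.coords[sel]
    idx = np.lexsort((order_keys, mols))
    n_mol = np.unique(mols).size
    if coords.shape[0] != n_mol * len(labels):
        raise ValueError(
            f"species {species!r}: incomplete {chain} chains "
            f"({coords.shape[0]} sites for {n_mol} molecules × {len(labels)} carbons)"
        )
    return coords[idx].reshape(n_mol, len(labels), 3)


def chain_vector(frame: BoxedFrame, gmap: GroupMap, mol: int, chain: str, i: int) -> np.ndarray:
    """Minimum-image vector from carbon C_{i−1} to C_{i+1} of one tail.

    ``i`` is 1-based along the chain list; terminal carbons (i = 1 or
    i = n) have no two flanking neighbours and raise.
    """
    sp = frame.species[frame.molecule == mol]
    if sp.size == 0:
        raise KeyError(f"no molecule {mol} in frame")
    species = sp[0]
    labels = gmap.require(species).chains.get(chain)
    if not labels:
        raise KeyError(f"species {species!r} has no chain {chain!r}")
    n = len(labels)
    if not 2 <= i <= n - 1:
        raise ValueError(f"carbon index {i} has no two neighbours on a {n}-carbon chain")
    a = frame.coords[frame.site_index(mol, labels[i])]      # C_{i+1} (0-based i)
    b = frame.coords[frame.site_index(mol, labels[i - 2])]  # C_{i-1}
    return minimum_image_displacement(a, b, frame.box)


def order_parameter_profile(frames: Sequence[BoxedFrame], gmap: GroupMap,
                            species: str, chain: str) -> pd.DataFrame:
    """S_C profile along one tail of one species.

    Returns a DataFrame with columns ``species, chain, carbon_index, S_C,
    se``; carbon_index runs from 2 to n−1 for an n-carbon chain.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    per_frame = []
    for frame in frames:
        c = _chain_positions(frame, gmap, species, chain)
        vec = minimum_image_displacement(c[:, 2:, :], c[:, :-2, :], frame.box)
        norm2 = np.einsum("ijk,ijk->ij", vec, vec)
        cos2 = vec[..., 2] ** 2 / norm2
        p2 = 1.5 * cos2 - 0.5
        per_frame.append(p2.mean(axis=0))  # molecule average, per position
    arr = np.asarray(per_frame)  # (n_frames, n_positions)
    s_c = arr.mean(axis=0)
    if arr.shape[0] >= 10:
        se = np.array([autocorr_sem(arr[:, k])[1] for k in range(arr.shape[1])])
    elif arr.shape[0] > 1:
        se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
    else:
        se = np.zeros_like(s_c)
    return pd.DataFrame(
        {
            "species": species,
            "chain": chain,
            "carbon_index": np.arange(2, 2 + s_c.size),
            "S_C": s_c,
            "se": se,
        }
    )
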