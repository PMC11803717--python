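"""Pairwise nonbonded energies and their subunit decomposition.

Interaction energies between lipids are accumulated on the level of four
subunits per molecule — headgroup, phosphate, glycol, acyl tails — into a
symmetric (species, group) × (species, group) matrix. From it follow:

* the **total** lipid–lipid interaction energy (all cells),
* the **partial** energy, which excludes every like-group pair
  (head–head, phosphate–phosphate, glycol–glycol, tail–tail) regardless
  of the species involved; like-group pairs are dominated by
  like-charge Coulomb repulsion, so partial energies isolate the
  attractive cross-subunit couplings,
* the **species decomposition** (primary–primary, primary–secondary,
  secondary–secondary), and
* **ion–lipid** terms between salt ions and the head or phosphate group
  of a chosen species.

The evaluator offers two short-range electrostatics schemes — cutoff
Coulomb with potential shift, and reaction field with a configurable
dielectric (ε_rf = 15 is the common coarse-grained choice) — plus
Lorentz–Berthelot Lennard-Jones with potential switching between the
switch-on radius and the cutoff. Long-range lattice sums (Ewald/PME) are
deliberately out of scope: the decomposition bookkeeping, not absolute
force-field fidelity, is the contract here, and every number is checked
against a brute-force pairwise sum. Intramolecular pairs are wholly
excluded. Energies are in kcal/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .frames import GROUPS, BoxedFrame, GroupMap
from .geometry import minimum_image_displacement, wrap_positions

__all__ = [
    "NonbondedScheme",
    "EnergyDecomposition",
    "pair_energy",
    "group_pair_energies",
    "total_and_partial",
    "species_decomposition",
    "ion_lipid_energies",
    "average_decomposition",
]

ION_SPECIES = ("NA", "CL")


@dataclass(frozen=True)
class NonbondedScheme:
    """Short-range nonbonded interaction parameters.

    lj_switch_on / cutoff in Å; ``coulomb_mode`` one of {"shifted",
    "reaction_field"}; ``epsilon_rf`` the reaction-field dielectric;
    the Coulomb constant is fixed at 332.0636 kcal·Å/(mol·e²).
    """

    lj_switch_on: float = 10.0
    cutoff: float = 12.0
    coulomb_mode: str = "shifted"
    epsilon_rf: float = 15.0
    coulomb_constant: float = 332.0636

    def __post_init__(self):
        if not 0.0 < self.lj_switch_on < self.cutoff:
            raise ValueError("require 0 < lj_switch_on < cutoff")
        if self.coulomb_mode not in ("shifted", "reaction_field"):
            raise ValueError(f"unknown coulomb_mode {self.coulomb_mode!r}")


def _coulomb(r: np.ndarray, qq: np.ndarray, scheme: NonbondedScheme) -> np.ndarray:
    rc = scheme.cutoff
    k = scheme.coulomb_constant
    if scheme.coulomb_mode == "shifted":
        e = k * qq * (1.0 / r - 1.0 / rc)
    else:  # reaction field, potential zeroed at the cutoff
        krf = (scheme.epsilon_rf - 1.0) / ((2.0 * scheme.epsilon_rf + 1.0) * rc**3)
        crf = 1.0 / rc + krf * rc**2
        e = k * qq * (1.0 / r + krf * r**2 - crf)
    return np.where(r < rc, e, 0.0)


def _lennard_jones(r: np.ndarray, eps: np.ndarray, sig: np.ndarray,
                   scheme: NonbondedScheme) -> np.ndarray:
    ron, rc = scheme.lj_switch_on, scheme.cutoff
    sr6 = (sig / r) ** 6
    e = 4.0 * eps * (sr6**2 - sr6)
    r2, ron2, rc2 = r**2, ron**2, rc**2
    # CHARMM-style potential switching function, C1-continuous at both ends
    sw = ((rc2 - r2) ** 2 * (rc2 + 2.0 * r2 - 3.0 * ron2)) / (rc2 - ron2) ** 3
    s = np.where(r <= ron, 1.0, np.where(r < rc, sw, 0.0))
    return e * s


def _pair_terms(r, qq, eps, sig, scheme):
    return _coulomb(r, qq, scheme), _lennard_jones(r, eps, sig, scheme)


def pair_energy(dr: float, q_i: float, q_j: float, lj_i: tuple[float, float],
                lj_j: tuple[float, float], scheme: NonbondedScheme,
                split: bool = False):
    """Nonbonded energy of one site pair at separation ``dr`` Å.

    ``lj_i``/``lj_j`` are (ε kcal/mol, σ Å); Lorentz–Berthelot combining
    (arithmetic σ, geometric ε). Returns kcal/mol, or a (coulomb, lj)
    tuple when ``split``.
    """
    if dr <= 0:
        raise ValueError("overlapping sites (dr <= 0)")
    eps = np.sqrt(lj_i[0] * lj_j[0])
    sig = 0.5 * (lj_i[1] + lj_j[1])
    c, l = _pair_terms(np.asarray(dr, dtype=float), q_i * q_j, eps, sig, scheme)
    if split:
        return float(c), float(l)
    return float(c + l)


@dataclass
class EnergyDecomposition:
    """Subunit-resolved intermolecular energies of one frame (kcal/mol).

    ``cells`` maps a canonical key ((species_i, group_i), (species_j,
    group_j)), sorted lexicographically, to the accumulated energy of all
    intermolecular site pairs falling in that cell. ``coulomb_cells`` and
    ``lj_cells`` hold the electrostatic / Lennard-Jones split.
    """

    cells: dict
    coulomb_cells: dict
    lj_cells: dict
    lipid_species: list[str]

    @property
    def total(self) -> float:
        """Sum over all lipid–lipid cells."""
        lip = set(self.lipid_species)
        return float(sum(e for ((si, _), (sj, _)), e in self.cells.items()
                         if si in lip and sj in lip))

    @property
    def like_group_sum(self) -> float:
        lip = set(self.lipid_species)
        return float(sum(e for ((si, gi), (sj, gj)), e in self.cells.items()
                         if gi == gj and si in lip and sj in lip))

    @property
    def partial(self) -> float:
        """Total minus every like-group (g, g) cell, any species pair."""
        return self.total - self.like_group_sum

    def by_species(self) -> dict:
        """Total and partial energies per unordered lipid species pair."""
        lip = set(self.lipid_species)
        out: dict[tuple[str, str], dict[str, float]] = {}
        for ((si, gi), (sj, gj)), e in self.cells.items():
            if si not in lip or sj not in lip:
                continue
            key = tuple(sorted((si, sj)))
            d = out.setdefault(key, {"total": 0.0, "partial": 0.0})
            d["total"] += e
            if gi != gj:
                d["partial"] += e
        return out

    def ion_group_energy(self, species: str, group: str,
                         ion_species: Sequence[str] = ION_SPECIES) -> float:
        """Energy between all listed ion species and one (species, group)."""
        total = 0.0
        ions = set(ion_species)
        for ((si, gi), (sj, gj)), e in self.cells.items():
            if si in ions and (sj, gj) == (species, group):
                total += e
            elif sj in ions and (si, gi) == (species, group):
                total += e
        return float(total)


def _site_parameters(frame: BoxedFrame, gmap: GroupMap):
    """Per-site charge, LJ, group and species arrays; raises on gaps."""
    n = frame.n_sites
    q = np.empty(n)
    eps = np.empty(n)
    sig = np.empty(n)
    groups: list[str] = []
    for i in range(n):
        sp, name = frame.species[i], frame.names[i]
        smap = gmap.require(sp)
        try:
            groups.append(smap.site_group[name])
            q[i] = smap.charges[name]
            e, s = smap.lj_params[name]
        except KeyError:
            raise KeyError(
                f"site {name!r} of species {sp!r} lacks a group/charge/LJ assignment"
            ) from None
        eps[i] = e
        sig[i] = s
    return q, eps, sig, np.array(groups, dtype=object)


def group_pair_energies(frame: BoxedFrame, gmap: GroupMap,
                        scheme: NonbondedScheme | None = None) -> EnergyDecomposition:
    """Accumulate all intermolecular pair energies into subunit cells.

    Every pair of sites belonging to different molecules and lying within
    the cutoff contributes once to the cell of its (species, group) pair;
    intramolecular pairs are excluded entirely.
    """
    scheme = scheme or NonbondedScheme()
    q, eps_i, sig_i, groups = _site_parameters(frame, gmap)
    box = frame.box
    if np.any(box < 2.0 * scheme.cutoff):
        # neighbour search assumes the minimum image is unique within the cutoff
        raise ValueError("box must be at least twice the cutoff in every dimension")
    wrapped = wrap_positions(frame.coords, box)
    wrapped = np.where(wrapped >= box, 0.0, wrapped)
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(scheme.cutoff, output_type="ndarray")
    lipids = gmap.lipid_species()

    cells: dict = {}
    ccells: dict = {}
    lcells: dict = {}
    if pairs.size:
        i, j = pairs[:, 0], pairs[:, 1]
        inter = frame.molecule[i] != frame.molecule[j]
        i, j = i[inter], j[inter]
        d = minimum_image_displacement(frame.coords[i], frame.coords[j], box)
        r = np.linalg.norm(d, axis=1)
        if np.any(r <= 0):
            raise ValueError("overlapping intermolecular sites (r = 0)")
        qq = q[i] * q[j]
        eps = np.sqrt(eps_i[i] * eps_i[j])
        sig = 0.5 * (sig_i[i] + sig_i[j])
        ec, el = _pair_terms(r, qq, eps, sig, scheme)

        keys_i = list(zip(frame.species[i], groups[i]))
        keys_j = list(zip(frame.species[j], groups[j]))
        for ki, kj, c, l in zip(keys_i, keys_j, ec, el):
            key = (ki, kj) if ki <= kj else (kj, ki)
            cells[key] = cells.get(key, 0.0) + c + l
            ccells[key] = ccells.get(key, 0.0) + c
            lcells[key] = lcells.get(key, 0.0) + l
    return EnergyDecomposition(cells=cells, coulomb_cells=ccells, lj_cells=lcells,
                               lipid_species=lipids)


def total_and_partial(decomp: EnergyDecomposition) -> tuple[float, float]:
    """(total, partial) lipid–lipid energies of a decomposition."""
    return decomp.total, decomp.partial


def species_decomposition(frame: BoxedFrame, gmap: GroupMap,
                          scheme: NonbondedScheme | None = None) -> dict:
    """Total/partial energies per unordered lipid species pair."""
    return group_pair_energies(frame, gmap, scheme).by_species()


def ion_lipid_energies(frame: BoxedFrame, gmap: GroupMap, species: str,
                       scheme: NonbondedScheme | None = None,
                       ion_species: Sequence[str] = ION_SPECIES) -> tuple[float, float]:
    """(ion–head, ion–phosphate) energies for one lipid species.

    Sums the pair energies between every ion site (Na⁺ and Cl⁻ by
    default) and every site of the species' head (respectively
    phosphate) subunit. Returns (0, 0) with a warning when no ions are
    present.
    """
    present = set(frame.species)
    if not any(s in present for s in ion_species):
        warnings.warn("no ion species present; ion–lipid energies are zero")
        return 0.0, 0.0
    decomp = group_pair_energies(frame, gmap, scheme)
    return (decomp.ion_group_energy(species, "head", ion_species),
            decomp.ion_group_energy(species, "phosphate", ion_species))


def average_decomposition(frames: Sequence[BoxedFrame], gmap: GroupMap,
                          scheme: NonbondedScheme | None = None) -> dict:
    """Frame-averaged totals: whole-system sums averaged over frames."""
    totals, partials, like_groups = [], [], []
    by_species: dict = {}
    for f in frames:
        d = group_pair_energies(f, gmap, scheme)
        totals.append(d.total)
        partials.append(d.partial)
        like_groups.append(d.like_group_sum)
        for k, v in d.by_species().items():
            acc = by_species.setdefault(k, {"total": [], "partial": []})
            acc["total"].append(v["total"])
            acc["partial"].append(v["partial"])
    return {
        "total_kcal_mol": float(np.mean(totals)),
        "partial_kcal_mol": float(np.mean(partials)),
        "like_group_kcal_mol": float(np.mean(like_groups)),
        "by_species": {
            "-".join(k): {kk: float(np.mean(vv)) for kk, vv in v.items()}
            for k, v in by_species.items()
        },
        "n_frames": len(totals),
    }
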