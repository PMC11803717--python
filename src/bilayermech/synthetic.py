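"""Synthetic bilayer configurations with known ground truth.

Every analysis stage in this package has a generator here that plants the
quantity the stage is supposed to recover:

* :func:`gen_leaflet_frames` — two jittered-lattice leaflets of two lipid
  species at a prescribed mole fraction (random, checkerboard or block
  label placement), each lipid carrying a head, phosphorus, GL1 site and
  two straight 18-carbon tails with a prescribed tilt distribution.
  Ground truth: composition, lattice geometry, tilt law.
* :func:`gen_gamma_area_series` — per-tension area-per-lipid time series
  whose means follow ⟨A⟩(γ) = A0·(1 + γ/K_A) for a chosen true K_A, with
  stationary AR(1) noise of known autocorrelation.
* :func:`gen_pressure_record` — pressure-tensor records whose per-frame
  surface tension has a prescribed mean.
* :func:`gen_charged_toy_system` — small random charged multi-site
  molecules (plus free Na⁺/Cl⁻) for brute-force energy oracles.

Lipids are geometric stand-ins, not physical conformers: every statistic
computed downstream depends only on positions, labels and charges, so
fully controlled geometry gives exact expected values. All generators are
bit-reproducible per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .frames import BoxedFrame, GroupMap, SpeciesMap
from .mechanics import GammaAreaSeries

__all__ = [
    "SyntheticSpec",
    "make_groupmap",
    "gen_leaflet_frames",
    "gen_gamma_area_series",
    "gen_pressure_record",
    "gen_charged_toy_system",
]

CARBONS_PER_TAIL = 18
CC_SPACING = 1.27  # Å, projected C–C spacing of an extended acyl chain


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic bilayer.

    Defaults mirror the simulated systems the analyses target: 100 lipids
    per leaflet on an ~8×8 nm lattice (≈66 Å² per lipid), a 65:35 binary
    mixture, tensions {−7, 0, 7, 15} mN/m, a true K_A equal to the pure
    DOPC reference value, and strongly autocorrelated area noise.
    """

    n_per_leaflet: int = 100
    composition: float = 0.65  # primary mole fraction
    primary_species: str = "DOPC"
    secondary_species: str = "DSPG"
    lattice_spacing: float = 8.1  # Å
    jitter: float = 0.8  # Å, sd of lateral lattice jitter
    tilt_model: tuple = ("vonmises", 3.0)  # or ("fixed", θ_deg) / ("isotropic",)
    true_KA: float = 245.81  # mN/m
    A0: float = 66.3  # Å², reference area per lipid at γ = 0
    gammas: tuple = (-7.0, 0.0, 7.0, 15.0)  # mN/m
    n_frames: int = 1000
    ar1_phi: float = 0.9
    noise_sd: float = 1.0  # Å², stationary sd of the area series
    clustering: str = "random"  # random | checkerboard | blocks
    seed: int = 0

    def __post_init__(self):
        if self.n_per_leaflet < 1:
            raise ValueError("n_per_leaflet must be at least 1")
        if not self.tilt_model or self.tilt_model[0] not in ("fixed", "vonmises", "isotropic"):
            raise ValueError(f"unknown tilt model {self.tilt_model!r}")
        if not 0.0 < self.composition < 1.0:
            raise ValueError("composition must be in (0, 1)")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must be in [0, 1)")
        if self.n_frames < 10:
            raise ValueError("n_frames must be at least 10")
        if self.clustering not in ("random", "checkerboard", "blocks"):
            raise ValueError(f"unknown clustering mode {self.clustering!r}")


def make_groupmap(spec: SyntheticSpec) -> GroupMap:
    """Group map matching the synthetic lipid architecture.

    Sites per lipid: HEAD (head, +1e), P (phosphate, −1e), GL1 (glycol),
    A1..A18 and B1..B18 (tails). Na⁺/Cl⁻ ion entries are included so
    frames with salt are analyzable without edits.
    """
    species = {}
    sn1 = [f"A{k}" for k in range(1, CARBONS_PER_TAIL + 1)]
    sn2 = [f"B{k}" for k in range(1, CARBONS_PER_TAIL + 1)]
    site_group = {"HEAD": "head", "P": "phosphate", "GL1": "glycol"}
    site_group.update({s: "tail" for s in sn1 + sn2})
    charges = {"HEAD": 1.0, "P": -1.0, "GL1": 0.0}
    charges.update({s: 0.0 for s in sn1 + sn2})
    lj = {s: (0.1, 4.0) for s in site_group}
    for name in (spec.primary_species, spec.secondary_species):
        species[name] = SpeciesMap(
            site_group=dict(site_group),
            phosphorus_site="P",
            gl1_site="GL1",
            chains={"SN1": list(sn1), "SN2": list(sn2)},
            charges=dict(charges),
            lj_params=dict(lj),
        )
    species["NA"] = SpeciesMap(site_group={"NA": "ion"}, charges={"NA": 1.0},
                               lj_params={"NA": (0.05, 2.5)})
    species["CL"] = SpeciesMap(site_group={"CL": "ion"}, charges={"CL": -1.0},
                               lj_params={"CL": (0.05, 4.0)})
    gmap = GroupMap(species=species)
    gmap.validate()
    return gmap


def _draw_labels(spec: SyntheticSpec, ix: np.ndarray, iy: np.ndarray,
                 lx: float, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = ix.size
    if spec.clustering == "random":
        primary = rng.random(n) < spec.composition
    elif spec.clustering == "checkerboard":
        primary = (ix + iy) % 2 == 0
    else:  # blocks: a primary stripe occupying the composition fraction of x
        primary = x < spec.composition * lx
    out = np.where(primary, spec.primary_species, spec.secondary_species)
    return out.astype(object)


def _tilt_directions(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit vectors of tail axes, measured from the leaflet-inward normal."""
    model = spec.tilt_model
    kind = model[0]
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    if kind == "fixed":
        u = np.full(n, math.cos(math.radians(model[1])))
    elif kind == "vonmises":
        # von Mises–Fisher cosine sampling about the mean axis
        kappa = float(model[1])
        xi = rng.random(n)
        u = 1.0 + np.log(xi + (1.0 - xi) * np.exp(-2.0 * kappa)) / kappa
    elif kind == "isotropic":
        u = rng.uniform(-1.0, 1.0, n)
    else:
        raise ValueError(f"unknown tilt model {kind!r}")
    s = np.sqrt(np.maximum(1.0 - u**2, 0.0))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), u])


def gen_leaflet_frames(spec: SyntheticSpec, n_frames: int | None = None,
                       with_ions: int = 0) -> list[BoxedFrame]:
    """Generate bilayer frames of two jittered-lattice leaflets.

    Lattice sites keep their positions across frames; jitter, species
    labels (in random mode, drawn once) and tail tilts are redrawn per
    the seed. ``with_ions`` adds that many Na⁺/Cl⁻ pairs in the solvent
    slab. Deterministic per ``spec.seed``.
    """
    if spec.jitter >= spec.lattice_spacing / 2.0:
        raise ValueError("jitter must stay below half the lattice spacing (overlap risk)")
    n_frames = spec.n_frames if n_frames is None else n_frames
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_leaflet
    side = math.ceil(math.sqrt(n))
    a = spec.lattice_spacing
    lx = ly = side * a
    lz = 100.0
    box = np.array([lx, ly, lz])
    leaf_z = {"upper": 70.0, "lower": 30.0}

    cells = np.arange(side * side)[:n]
    ix, iy = cells % side, cells // side
    base_xy = np.column_stack([(ix + 0.5) * a, (iy + 0.5) * a])

    # species drawn once per leaflet: composition is a property of the
    # membrane, not of the frame
    leaf_species = {}
    for leaflet in ("upper", "lower"):
        leaf_species[leaflet] = _draw_labels(spec, ix, iy, lx, base_xy[:, 0], rng)

    sn1 = [f"A{k}" for k in range(1, CARBONS_PER_TAIL + 1)]
    sn2 = [f"B{k}" for k in range(1, CARBONS_PER_TAIL + 1)]
    site_names = ["HEAD", "P", "GL1"] + sn1 + sn2
    n_sites = len(site_names)

    frames = []
    for t in range(n_frames):
        coords, species, molecule, names = [], [], [], []
        mol = 0
        for leaflet in ("upper", "lower"):
            zp = leaf_z[leaflet]
            inward = -1.0 if leaflet == "upper" else 1.0  # tails point to midplane
            xy = base_xy + rng.normal(0.0, spec.jitter, (n, 2))
            d1 = _tilt_directions(spec, n, rng)
            d2 = _tilt_directions(spec, n, rng)
            d1[:, 2] *= inward
            d2[:, 2] *= inward
            for m in range(n):
                x, y = xy[m]
                p = np.array([x, y, zp])
                head = p + np.array([0.0, 0.0, -2.0 * inward])
                gl1 = p + np.array([0.0, 0.0, 1.5 * inward])
                k = np.arange(1, CARBONS_PER_TAIL + 1)[:, None]
                tail1 = gl1 + np.array([0.7, 0.0, 0.0]) + k * CC_SPACING * d1[m]
                tail2 = gl1 + np.array([-0.7, 0.0, 0.0]) + k * CC_SPACING * d2[m]
                coords.append(np.vstack([head, p, gl1, tail1, tail2]))
                species.extend([leaf_species[leaflet][m]] * n_sites)
                molecule.extend([mol] * n_sites)
                names.extend(site_names)
                mol += 1
        for _ in range(with_ions):
            for ion, zoff in (("NA", 5.0), ("CL", 95.0)):
                pos = np.array([rng.uniform(0, lx), rng.uniform(0, ly),
                                zoff + rng.normal(0, 1.0)])
                coords.append(pos[None, :])
                species.append(ion)
                molecule.append(mol)
                names.append(ion)
                mol += 1
        frame = BoxedFrame(
            coords=np.vstack(coords),
            species=np.array(species, dtype=object),
            molecule=np.array(molecule, dtype=int),
            names=np.array(names, dtype=object),
            box=box.copy(),
            time=float(t),
        )
        frames.append(frame)
    return frames


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with marginal sd ``sd``."""
    from scipy.signal import lfilter

    if sd == 0.0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - phi**2), n)
    x0 = rng.normal(0.0, sd)
    out, _ = lfilter([1.0], [1.0, -phi], innov, zi=np.array([phi * x0]))
    return out


def gen_gamma_area_series(spec: SyntheticSpec) -> tuple[GammaAreaSeries, dict]:
    """Per-tension area series with a planted K_A.

    Each tension γ gets ``spec.n_frames`` frames of area per lipid,
    mean A0·(1 + γ/true_KA), AR(1) noise with lag-1 coefficient
    ``ar1_phi`` and stationary sd ``noise_sd``. Returns the series and a
    ground-truth record.
    """
    if spec.true_KA <= 0:
        raise ValueError("true_KA must be positive")
    if 0.0 not in [float(g) for g in spec.gammas]:
        raise ValueError("the γ set must include γ = 0 (reference area)")
    rng = np.random.default_rng(spec.seed)
    series = {}
    for g in spec.gammas:
        mean = spec.A0 * (1.0 + g / spec.true_KA)
        series[float(g)] = mean + _ar1(spec.n_frames, spec.ar1_phi, spec.noise_sd, rng)
    truth = {
        "true_KA_mN_per_m": spec.true_KA,
        "A0_A2": spec.A0,
        "ar1_phi": spec.ar1_phi,
        "noise_sd_A2": spec.noise_sd,
        "n_frames": spec.n_frames,
        "gammas": list(spec.gammas),
    }
    return GammaAreaSeries.from_series(series), truth


def gen_pressure_record(gamma_target: float, lz: float, n_frames: int,
                        noise: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Pressure-tensor records whose mean surface tension is ``gamma_target``.

    Pzz is held at 1 bar; the lateral components are set to
    Pzz − γ/(0.01·Lz) plus optional iid noise (bar). Returns the
    tabular pressure record (frame, Pxx, Pyy, Pzz in bar, Lz in Å).
    """
    if lz <= 0:
        raise ValueError("Lz must be positive")
    rng = np.random.default_rng(seed)
    pzz = np.ones(n_frames)
    lateral = pzz - gamma_target / (0.01 * lz)
    pxx = lateral + (rng.normal(0.0, noise, n_frames) if noise else 0.0)
    pyy = lateral + (rng.normal(0.0, noise, n_frames) if noise else 0.0)
    return pd.DataFrame(
        {
            "frame": np.arange(n_frames),
            "Pxx_bar": pxx,
            "Pyy_bar": pyy,
            "Pzz_bar": pzz,
            "Lz_A": np.full(n_frames, float(lz)),
        }
    )


def gen_charged_toy_system(n: int, box: float | np.ndarray = 30.0,
                           charge_model: str = "mixed", seed: int = 0,
                           ion_fraction: float = 0.2) -> tuple[BoxedFrame, GroupMap]:
    """Random charged multi-site molecules for energy-oracle tests.

    ``n`` molecules are scattered in the box: two artificial lipid
    species ("LIPA", "LIPB") with one site per subunit (head, phosphate,
    glycol, tail) and, with probability ``ion_fraction``, single-site
    Na⁺/Cl⁻ ions. ``charge_model`` is "mixed" (random charges) or
    "neutral" (all lipid charges zero). Deterministic per seed.
    """
    if n < 2:
        raise ValueError("need at least 2 molecules")
    rng = np.random.default_rng(seed)
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()

    def lipid_map(prefix: str) -> SpeciesMap:
        sites = [f"{prefix}H", f"{prefix}P", f"{prefix}G", f"{prefix}T"]
        groups = dict(zip(sites, ("head", "phosphate", "glycol", "tail")))
        if charge_model == "neutral":
            charges = {s: 0.0 for s in sites}
        else:
            charges = {s: float(rng.uniform(-1.0, 1.0)) for s in sites}
        lj = {s: (float(rng.uniform(0.05, 0.3)), float(rng.uniform(3.0, 5.0))) for s in sites}
        return SpeciesMap(site_group=groups, phosphorus_site=sites[1], gl1_site=sites[2],
                          charges=charges, lj_params=lj)

    gmap = GroupMap(
        species={
            "LIPA": lipid_map("A"),
            "LIPB": lipid_map("B"),
            "NA": SpeciesMap(site_group={"NA": "ion"}, charges={"NA": 1.0},
                             lj_params={"NA": (0.05, 2.5)}),
            "CL": SpeciesMap(site_group={"CL": "ion"}, charges={"CL": -1.0},
                             lj_params={"CL": (0.05, 4.0)}),
        }
    )
    gmap.validate()

    # jittered 3D lattice of molecule centres so molecules do not overlap
    # (r → 0 would make the r^-12 repulsion swamp every other term)
    side = math.ceil(n ** (1.0 / 3.0))
    cells = np.stack(np.meshgrid(*[np.arange(side)] * 3, indexing="ij"), axis=-1).reshape(-1, 3)
    centers = (cells[rng.permutation(cells.shape[0])[:n]] + 0.5) * (box / side)
    centers += rng.normal(0.0, min(box) / side * 0.08, centers.shape)

    coords, species, molecule, names = [], [], [], []
    for mol in range(n):
        if rng.random() < ion_fraction:
            ion = "NA" if rng.random() < 0.5 else "CL"
            coords.append(centers[mol][None, :])
            species.append(ion)
            molecule.append(mol)
            names.append(ion)
        else:
            sp = "LIPA" if rng.random() < 0.5 else "LIPB"
            prefix = sp[3]  # "A" or "B"
            local = rng.normal(0.0, 1.0, (4, 3))
            coords.append(centers[mol] + local)
            species.extend([sp] * 4)
            molecule.extend([mol] * 4)
            names.extend([f"{prefix}H", f"{prefix}P", f"{prefix}G", f"{prefix}T"])
    frame = BoxedFrame(
        coords=np.vstack(coords),
        species=np.array(species, dtype=object),
        molecule=np.array(molecule, dtype=int),
        names=np.array(names, dtype=object),
        box=box,
    )
    frame.validate()
    return frame, gmap
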