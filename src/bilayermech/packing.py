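"""Lateral packing and mixing statistics of bilayer leaflets.

Four complementary views of how two lipid species arrange in a leaflet:

* **Lipid spacing distribution** — probability histogram of lateral
  phosphorus–phosphorus distances between lipids of a species pair.
* **Periodic Voronoi tessellation** — per-lipid cell areas from a 2D
  Voronoi diagram of the phosphorus positions under periodic boundary
  conditions (3×3 ghost tiling; the central copy's cells are exact when
  generators are separated by less than half the box).
* **Mixed-contact fraction** — f_mix = 100·C_AB/(C_AA + C_AB) with
  contacts defined by phosphate–phosphate distance below 1.1 nm. C_AA
  counts the primary species' same-species contacts from each primary
  lipid (an A–A pair contributes twice), C_AB each mixed pair once, so
  ideal random mixing gives f_mix equal to the secondary mole percent.
* **Neighbor composition** — counts and percentages of neighbouring
  lipids within 1.5 nm of the first tail-linker (GL1) site, by species
  of the central lipid.

All contacts and neighbours are restricted to same-leaflet pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon

from .frames import BoxedFrame, GroupMap, LeafletPartition, assign_leaflets
from .geometry import pairwise_min_image_distances, wrap_positions

__all__ = [
    "SpacingHistogram",
    "VoronoiResult",
    "MixingStats",
    "NeighborTable",
    "lipid_spacing_distribution",
    "voronoi_leaflet",
    "mixed_contact_fraction",
    "neighbor_composition",
    "plot_voronoi",
]


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _phosphorus_sites(frame: BoxedFrame, gmap: GroupMap, mols: np.ndarray):
    """Positions, species and molecule ids of the P/PO4 site of given lipids."""
    mask = np.zeros(frame.n_sites, dtype=bool)
    for sp in gmap.lipid_species():
        psite = gmap.species[sp].phosphorus_site
        mask |= (frame.species == sp) & (frame.names == psite)
    mask &= np.isin(frame.molecule, mols)
    order = np.argsort(frame.molecule[mask], kind="stable")
    idx = np.flatnonzero(mask)[order]
    return frame.coords[idx], frame.species[idx], frame.molecule[idx]


def _reference_sites(frame: BoxedFrame, gmap: GroupMap, mols: np.ndarray, which: str):
    if which == "phosphorus":
        return _phosphorus_sites(frame, gmap, mols)
    mask = np.zeros(frame.n_sites, dtype=bool)
    for sp in gmap.lipid_species():
        site = gmap.species[sp].gl1_site
        if site is None:
            raise KeyError(f"species {sp!r} has no GL1 designation in the group map")
        mask |= (frame.species == sp) & (frame.names == site)
    mask &= np.isin(frame.molecule, mols)
    order = np.argsort(frame.molecule[mask], kind="stable")
    idx = np.flatnonzero(mask)[order]
    return frame.coords[idx], frame.species[idx], frame.molecule[idx]


def _primary_species(frames: Sequence[BoxedFrame], gmap: GroupMap, primary: str | None) -> str:
    """Default primary species = the most abundant lipid in the first frame."""
    if primary is not None:
        return primary
    f = frames[0]
    counts = {sp: f.molecules_of(sp).size for sp in gmap.lipid_species() if sp in set(f.species)}
    return max(counts, key=counts.get)


def _contact_pairs(points: np.ndarray, box: np.ndarray, cutoff: float) -> np.ndarray:
    """Index pairs with 3D minimum-image distance within ``cutoff``."""
    wrapped = wrap_positions(points, box)
    # guard against points landing exactly on the upper boundary after wrap
    wrapped = np.where(wrapped >= box, 0.0, wrapped)
    tree = cKDTree(wrapped, boxsize=box)
    return tree.query_pairs(cutoff, output_type="ndarray")


# ---------------------------------------------------------------------------
# lipid spacing distribution
# ---------------------------------------------------------------------------


@dataclass
class SpacingHistogram:
    """Probability histogram of P–P distances for one species pair."""

    species_pair: tuple[str, str]
    bin_edges: np.ndarray  # Å
    probability: np.ndarray  # per bin, sums to 1
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_lo_A": self.bin_edges[:-1],
                "r_hi_A": self.bin_edges[1:],
                "probability": self.probability,
            }
        )


def lipid_spacing_distribution(frames: Sequence[BoxedFrame], gmap: GroupMap, leaflet: str,
                               species_pair: tuple[str, str], bin_width: float = 1.0,
                               lateral: bool = True) -> SpacingHistogram:
    """Histogram of same-leaflet phosphorus–phosphorus distances.

    Distances are lateral (xy) minimum-image by default — the natural
    measure of in-plane spacing — with a 3D toggle. Bins cover
    [0, min(Lx, Ly)/2] and the histogram is normalised to unit mass.
    """
    s1, s2 = species_pair
    box0 = frames[0].box
    rmax = min(box0[0], box0[1]) / 2.0
    edges = np.arange(0.0, rmax + bin_width, bin_width)
    counts = np.zeros(edges.size - 1)
    n_pairs = 0
    mode = "xy" if lateral else "xyz"
    for frame in frames:
        part = assign_leaflets(frame, gmap)
        mols = part.molecules(leaflet)
        pos, spec, _ = _phosphorus_sites(frame, gmap, mols)
        p1 = pos[spec == s1]
        p2 = pos[spec == s2]
        if s1 == s2:
            if p1.shape[0] < 2:
                continue
            d = pairwise_min_image_distances(p1, p1, frame.box, mode=mode)
            dist = d[np.triu_indices(p1.shape[0], k=1)]
        else:
            if p1.shape[0] == 0 or p2.shape[0] == 0:
                continue
            dist = pairwise_min_image_distances(p1, p2, frame.box, mode=mode).ravel()
        counts += np.histogram(dist, bins=edges)[0]
        n_pairs += dist.size
    if n_pairs == 0:
        raise ValueError(f"no same-leaflet {s1}–{s2} pairs found in leaflet {leaflet!r}")
    return SpacingHistogram(
        species_pair=(s1, s2), bin_edges=edges, probability=counts / counts.sum(), n_pairs=n_pairs
    )


# ---------------------------------------------------------------------------
# periodic Voronoi tessellation
# ---------------------------------------------------------------------------


@dataclass
class VoronoiResult:
    """Periodic 2D Voronoi tessellation of one leaflet."""

    leaflet: str
    molecules: np.ndarray
    species: np.ndarray
    areas: np.ndarray  # Å² per lipid
    polygons: list  # shapely Polygons (central copy, unwrapped)
    box: np.ndarray

    def area_stats(self) -> pd.DataFrame:
        """Mean and median cell area per species."""
        df = pd.DataFrame({"species": self.species, "area": self.areas})
        out = df.groupby("species")["area"].agg(["mean", "median", "count"])
        return out.rename(columns={"mean": "mean_A2", "median": "median_A2", "count": "n"})


def voronoi_leaflet(frame: BoxedFrame, gmap: GroupMap, leaflet: str,
                    _retry: bool = True) -> VoronoiResult:
    """Periodic Voronoi tessellation of one leaflet's phosphorus sites.

    The generators are tiled over the 3×3 neighbouring images and only
    cells of the central copy are kept; their areas tile the lateral box
    exactly. Coincident generators are jittered once (1e-6 Å) and retried.
    """
    part = assign_leaflets(frame, gmap)
    mols = part.molecules(leaflet)
    if mols.size < 3:
        raise ValueError("need at least 3 lipids in the leaflet for a Voronoi tessellation")
    pos, spec, mol_ids = _phosphorus_sites(frame, gmap, mols)
    box = frame.box
    xy = wrap_positions(pos[:, :2], box[:2])

    # duplicate generators break the tessellation; jitter-retry once
    rounded = np.round(xy, 9)
    if np.unique(rounded, axis=0).shape[0] != xy.shape[0]:
        if not _retry:
            raise ValueError("coincident phosphorus positions persist after jitter")
        rng = np.random.default_rng(0)
        jf = BoxedFrame(
            coords=frame.coords + rng.normal(0.0, 1e-6, frame.coords.shape),
            species=frame.species, molecule=frame.molecule, names=frame.names,
            box=frame.box, pressure=frame.pressure, time=frame.time,
        )
        return voronoi_leaflet(jf, gmap, leaflet, _retry=False)

    n = xy.shape[0]
    shifts = [(ix * box[0], iy * box[1]) for ix in (-1, 0, 1) for iy in (-1, 0, 1) if (ix, iy) != (0, 0)]
    tiled = np.vstack([xy] + [xy + np.array(s) for s in shifts])
    vor = Voronoi(tiled)
    areas = np.empty(n)
    polys = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError("unbounded Voronoi cell in the central copy; degenerate input")
        poly = Polygon(vor.vertices[region])
        areas[i] = poly.area
        polys.append(poly)
    if np.any(areas <= 0):
        raise RuntimeError("non-positive Voronoi cell area")
    return VoronoiResult(leaflet=leaflet, molecules=mol_ids, species=spec,
                         areas=areas, polygons=polys, box=box.copy())


def plot_voronoi(result: VoronoiResult, path, colors: dict[str, str] | None = None) -> None:
    """Write an SVG/PNG leaflet diagram with cells coloured by species."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    species = sorted(set(result.species))
    if colors is None:
        default = ["tab:orange", "tab:green", "tab:blue", "tab:red"]
        colors = {sp: default[i % len(default)] for i, sp in enumerate(species)}
    fig, ax = plt.subplots(figsize=(6, 6))
    for poly, sp in zip(result.polygons, result.species):
        xs, ys = poly.exterior.xy
        ax.fill(xs, ys, color=colors[sp], edgecolor="black", linewidth=0.4)
    ax.set_xlim(0, result.box[0])
    ax.set_ylim(0, result.box[1])
    ax.set_aspect("equal")
    ax.set_xlabel("x (Å)")
    ax.set_ylabel("y (Å)")
    ax.set_title(f"{result.leaflet} leaflet")
    handles = [plt.Rectangle((0, 0), 1, 1, color=colors[sp]) for sp in species]
    ax.legend(handles, species, loc="upper right", fontsize=8)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# mixed contacts
# ---------------------------------------------------------------------------


@dataclass
class MixingStats:
    """Mixed-contact fraction of a binary leaflet system."""

    f_mix: float  # %
    sd: float  # % over frames
    c_aa: float  # primary same-species contact count per frame (A-centric)
    c_ab: float  # mixed contact count per frame
    primary: str
    secondary: str
    per_frame: np.ndarray

    def to_dict(self) -> dict:
        return {
            "f_mix_percent": self.f_mix,
            "sd_percent": self.sd,
            "C_AA_per_frame": self.c_aa,
            "C_AB_per_frame": self.c_ab,
            "primary": self.primary,
            "secondary": self.secondary,
        }


def mixed_contact_fraction(frames: Sequence[BoxedFrame], gmap: GroupMap,
                           cutoff: float = 11.0, primary: str | None = None) -> MixingStats:
    """f_mix from same-leaflet phosphate contacts within ``cutoff`` (Å).

    Exactly two lipid species are required. Contacts are 3D minimum-image
    phosphate–phosphate distances below the cutoff (1.1 nm by default).
    With A the primary species, C_AA counts A's same-species contacts from
    each A lipid and C_AB the mixed pairs, so f_mix = 100·C_AB/(C_AA+C_AB)
    tends to the secondary mole percent for an ideally mixed leaflet.
    Returned f_mix and sd are the mean and sd over frames.
    """
    species = [s for s in gmap.lipid_species() if s in set(frames[0].species)]
    if len(species) != 2:
        raise ValueError(f"mixed-contact fraction needs exactly two lipid species, found {species}")
    prim = _primary_species(frames, gmap, primary)
    sec = [s for s in species if s != prim][0]

    fvals, caa_vals, cab_vals = [], [], []
    for frame in frames:
        part = assign_leaflets(frame, gmap)
        caa = cab = 0
        for leaflet in ("upper", "lower"):
            mols = part.molecules(leaflet)
            pos, spec, _ = _phosphorus_sites(frame, gmap, mols)
            if pos.shape[0] < 2:
                continue
            pairs = _contact_pairs(pos, frame.box, cutoff)
            if pairs.size == 0:
                continue
            a = spec[pairs[:, 0]] == prim
            b = spec[pairs[:, 1]] == prim
            caa += 2 * int(np.count_nonzero(a & b))  # each A–A pair seen from both lipids
            cab += int(np.count_nonzero(a ^ b))
        if caa + cab == 0:
            raise ValueError("no phosphate contacts within the cutoff in a frame")
        fvals.append(100.0 * cab / (caa + cab))
        caa_vals.append(caa)
        cab_vals.append(cab)
    fvals = np.asarray(fvals)
    sd = float(fvals.std(ddof=1)) if fvals.size > 1 else 0.0
    return MixingStats(
        f_mix=float(fvals.mean()), sd=sd, c_aa=float(np.mean(caa_vals)),
        c_ab=float(np.mean(cab_vals)), primary=prim, secondary=sec, per_frame=fvals,
    )


# ---------------------------------------------------------------------------
# neighbor composition
# ---------------------------------------------------------------------------


@dataclass
class NeighborTable:
    """Mean neighbour counts and composition per central species."""

    table: pd.DataFrame  # index: center species; columns per neighbour species
    cutoff: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string()


def neighbor_composition(frames: Sequence[BoxedFrame], gmap: GroupMap,
                         cutoff: float = 15.0) -> NeighborTable:
    """Neighbour counts within ``cutoff`` (Å) of the GL1 site, by species.

    Two same-leaflet lipids are neighbours when their GL1 minimum-image
    distance is at most the cutoff (1.5 nm by default). For each central
    species the table reports the mean neighbour count per lipid of every
    species, the percentage composition of those neighbours, and the sd of
    counts over frames.
    """
    species = sorted(s for s in gmap.lipid_species() if s in set(frames[0].species))
    per_frame = {cs: {ns: [] for ns in species} for cs in species}
    for frame in frames:
        part = assign_leaflets(frame, gmap)
        counts = {cs: {ns: 0.0 for ns in species} for cs in species}
        n_centers = {cs: 0 for cs in species}
        for leaflet in ("upper", "lower"):
            mols = part.molecules(leaflet)
            pos, spec, _ = _reference_sites(frame, gmap, mols, "gl1")
            for cs in species:
                n_centers[cs] += int(np.count_nonzero(spec == cs))
            if pos.shape[0] < 2:
                continue
            pairs = _contact_pairs(pos, frame.box, cutoff)
            for i, j in pairs:
                counts[spec[i]][spec[j]] += 1.0
                counts[spec[j]][spec[i]] += 1.0
        for cs in species:
            denom = max(n_centers[cs], 1)
            for ns in species:
                per_frame[cs][ns].append(counts[cs][ns] / denom)
    rows = []
    for cs in species:
        row = {"center": cs}
        means = {ns: float(np.mean(per_frame[cs][ns])) for ns in species}
        total = sum(means.values())
        for ns in species:
            arr = np.asarray(per_frame[cs][ns])
            row[f"n_{ns}"] = means[ns]
            row[f"sd_{ns}"] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            row[f"pct_{ns}"] = 100.0 * means[ns] / total if total > 0 else 0.0
        rows.append(row)
    table = pd.DataFrame(rows).set_index("center")
    return NeighborTable(table=table, cutoff=cutoff)
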