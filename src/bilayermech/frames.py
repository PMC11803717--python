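"""Core data model: simulation frames, group maps, and leaflet assignment.

Internal unit canon: Å for lengths, bar for pressures, ns for time,
elementary charge for charges, kcal/mol for energies. Readers convert on
ingest (GRO files are nm on disk; MDAnalysis already returns Å).

A :class:`BoxedFrame` is one snapshot of a bilayer system: coordinates,
per-site species/molecule/name labels, an orthorhombic box, and optionally
the diagonal of the pressure tensor. A :class:`GroupMap` declares, per
lipid species, which site belongs to which of the four subunits
(headgroup, phosphate, glycol, acyl tails), which site is the phosphorus
(P atom or PO4 bead), which is the first tail-linker bead (GL1), the
ordered carbon lists of the SN1/SN2 chains, and optional per-site charges
and Lennard-Jones parameters for energy decomposition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BoxedFrame",
    "SpeciesMap",
    "GroupMap",
    "LeafletPartition",
    "read_structure",
    "read_frames_table",
    "write_frames_table",
    "read_pressure_table",
    "assign_leaflets",
]

GROUPS = ("head", "phosphate", "glycol", "tail")

FRAMES_TABLE_COLUMNS = ["frame", "time_ns", "mol", "species", "site", "x", "y", "z", "Lx", "Ly", "Lz"]
PRESSURE_TABLE_COLUMNS = ["frame", "Pxx_bar", "Pyy_bar", "Pzz_bar", "Lz_A"]


@dataclass
class BoxedFrame:
    """One simulation frame of a (bilayer) particle system.

    Attributes
    ----------
    coords : (N, 3) float array, Å
    species : (N,) str array — species label per site (resname-like)
    molecule : (N,) int array — molecule index per site
    names : (N,) str array — site label per site (e.g. "P", "PO4", "GL1")
    box : (3,) float array — orthorhombic edge lengths (Lx, Ly, Lz), Å
    pressure : optional (3,) float array — (Pxx, Pyy, Pzz), bar
    time : float, ns
    """

    coords: np.ndarray
    species: np.ndarray
    molecule: np.ndarray
    names: np.ndarray
    box: np.ndarray
    pressure: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.species = np.asarray(self.species, dtype=object)
        self.molecule = np.asarray(self.molecule, dtype=int)
        self.names = np.asarray(self.names, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        if self.pressure is not None:
            self.pressure = np.asarray(self.pressure, dtype=float)

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    def validate(self) -> None:
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        n = self.n_sites
        for arr, label in ((self.species, "species"), (self.molecule, "molecule"), (self.names, "names")):
            if arr.shape != (n,):
                raise ValueError(f"{label} must have shape ({n},)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        # one species label per molecule
        for mol in np.unique(self.molecule):
            sp = set(self.species[self.molecule == mol])
            if len(sp) != 1:
                raise ValueError(f"molecule {mol} carries multiple species labels: {sorted(sp)}")

    def molecules_of(self, species: str) -> np.ndarray:
        """Sorted unique molecule indices of one species."""
        return np.unique(self.molecule[self.species == species])

    def site_index(self, mol: int, name: str) -> int:
        idx = np.flatnonzero((self.molecule == mol) & (self.names == name))
        if idx.size != 1:
            raise KeyError(f"molecule {mol} has {idx.size} sites named {name!r}")
        return int(idx[0])


@dataclass
class SpeciesMap:
    """Subunit and parameter assignment for one species."""

    site_group: dict[str, str]
    phosphorus_site: str | None = None
    gl1_site: str | None = None
    chains: dict[str, list[str]] = field(default_factory=dict)
    charges: dict[str, float] = field(default_factory=dict)
    lj_params: dict[str, tuple[float, float]] = field(default_factory=dict)  # (ε kcal/mol, σ Å)

    def validate(self, name: str = "?") -> None:
        for site, grp in self.site_group.items():
            if grp not in GROUPS + ("ion",):
                raise ValueError(f"species {name}: site {site!r} mapped to unknown group {grp!r}")
        sn1 = set(self.chains.get("SN1", ()))
        sn2 = set(self.chains.get("SN2", ()))
        if sn1 & sn2:
            raise ValueError(f"species {name}: SN1 and SN2 chains overlap: {sorted(sn1 & sn2)}")
        for chain in (sn1, sn2):
            missing = chain - set(self.site_group)
            if missing:
                raise ValueError(f"species {name}: chain sites not in site_group: {sorted(missing)}")


@dataclass
class GroupMap:
    """Per-species subunit assignments; see module docstring."""

    species: dict[str, SpeciesMap]

    def validate(self) -> None:
        for name, smap in self.species.items():
            smap.validate(name)

    def lipid_species(self) -> list[str]:
        """Species with a designated phosphorus/PO4 site (i.e. lipids)."""
        return [s for s, m in self.species.items() if m.phosphorus_site is not None]

    def require(self, name: str) -> SpeciesMap:
        try:
            return self.species[name]
        except KeyError:
            raise KeyError(f"species {name!r} missing from group map") from None

    def group_of(self, species: str, site: str) -> str:
        smap = self.require(species)
        try:
            return smap.site_group[site]
        except KeyError:
            raise KeyError(f"site {site!r} of species {species!r} has no group assignment") from None

    # ---- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for name, m in self.species.items():
            out[name] = {
                "site_group": dict(m.site_group),
                "phosphorus_site": m.phosphorus_site,
                "gl1_site": m.gl1_site,
                "chains": {k: list(v) for k, v in m.chains.items()},
                "charges": dict(m.charges),
                "lj_params": {k: list(v) for k, v in m.lj_params.items()},
            }
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroupMap":
        species = {}
        for name, m in d.items():
            species[name] = SpeciesMap(
                site_group=dict(m["site_group"]),
                phosphorus_site=m.get("phosphorus_site"),
                gl1_site=m.get("gl1_site"),
                chains={k: list(v) for k, v in m.get("chains", {}).items()},
                charges={k: float(v) for k, v in m.get("charges", {}).items()},
                lj_params={k: (float(v[0]), float(v[1])) for k, v in m.get("lj_params", {}).items()},
            )
        gmap = cls(species=species)
        gmap.validate()
        return gmap

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "GroupMap":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_yaml(cls, path) -> "GroupMap":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class LeafletPartition:
    """Molecule → leaflet assignment for one frame."""

    assignment: dict[int, str]  # molecule index -> "upper" | "lower"
    midplane_z: float

    def molecules(self, leaflet: str) -> np.ndarray:
        if leaflet not in ("upper", "lower"):
            raise ValueError(f"unknown leaflet {leaflet!r}")
        return np.array(sorted(m for m, l in self.assignment.items() if l == leaflet), dtype=int)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _frames_from_mdanalysis(path: str) -> list[BoxedFrame]:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mass/element guessing chatter
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # pragma: no cover - message passthrough
            raise ValueError(f"failed to parse {path}: {exc}") from exc
    # multi-MODEL PDBs commonly state CRYST1 once in the header, which the
    # per-frame reader does not carry over; keep it as a fallback box
    header_box = None
    if str(path).lower().endswith(".pdb"):
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    vals = [float(line[6 + 9 * k:15 + 9 * k]) for k in range(3)]
                    angles = [float(line[33 + 7 * k:40 + 7 * k]) for k in range(3)]
                    header_box = np.array(vals + angles)
                    break

    frames = []
    species = u.atoms.resnames.astype(object)
    names = u.atoms.names.astype(object)
    molecule = u.atoms.resindices.astype(int)
    for ts in u.trajectory:
        dims = ts.dimensions
        if dims is None or not np.all(np.asarray(dims[:3]) > 0):
            dims = header_box
        if dims is None or not np.all(np.asarray(dims[:3]) > 0):
            raise ValueError(f"{path}: frame {ts.frame} has no usable box record")
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise ValueError(f"{path}: only orthorhombic boxes are supported (angles {dims[3:]})")
        time_ns = float(getattr(ts, "time", 0.0) or 0.0) / 1000.0  # MDAnalysis ps -> ns
        frames.append(
            BoxedFrame(
                coords=ts.positions.astype(float).copy(),
                species=species.copy(),
                molecule=molecule.copy(),
                names=names.copy(),
                box=np.asarray(dims[:3], dtype=float),
                time=time_ns,
            )
        )
    return frames


def read_frames_table(path) -> list[BoxedFrame]:
    """Read the frames-table CSV dialect (one row per site per frame)."""
    # keep_default_na: "NA" is sodium, not a missing value
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    missing = [c for c in FRAMES_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: frames table missing columns {missing}")
    frames = []
    for fid, g in df.groupby("frame", sort=True):
        box = g[["Lx", "Ly", "Lz"]].iloc[0].to_numpy(dtype=float)
        frame = BoxedFrame(
            coords=g[["x", "y", "z"]].to_numpy(dtype=float),
            species=g["species"].to_numpy(dtype=object),
            molecule=g["mol"].to_numpy(dtype=int),
            names=g["site"].astype(str).to_numpy(dtype=object),
            box=box,
            time=float(g["time_ns"].iloc[0]),
        )
        frame.validate()
        frames.append(frame)
    if not frames:
        raise ValueError(f"{path}: empty frames table")
    return frames


def write_frames_table(frames: Iterable[BoxedFrame], path) -> None:
    rows = []
    for i, f in enumerate(frames):
        rows.append(
            pd.DataFrame(
                {
                    "frame": i,
                    "time_ns": f.time,
                    "mol": f.molecule,
                    "species": f.species,
                    "site": f.names,
                    "x": f.coords[:, 0],
                    "y": f.coords[:, 1],
                    "z": f.coords[:, 2],
                    "Lx": f.box[0],
                    "Ly": f.box[1],
                    "Lz": f.box[2],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.8f")


def read_structure(path, format: str | None = None) -> list[BoxedFrame]:
    """Read a structure/trajectory into a list of :class:`BoxedFrame`.

    GRO and (multi-MODEL) PDB go through MDAnalysis and arrive in Å;
    ``frames-table`` is this package's CSV dialect. ``format`` defaults to
    the file suffix (.gro, .pdb, .csv).
    """
    path = Path(path)
    if format is None:
        format = {".gro": "gro", ".pdb": "pdb", ".csv": "frames-table"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format of {path}; pass format=")
    if format in ("gro", "pdb"):
        frames = _frames_from_mdanalysis(str(path))
    elif format == "frames-table":
        frames = read_frames_table(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    for f in frames:
        f.validate()
    return frames


def read_pressure_table(path) -> pd.DataFrame:
    """Read the per-frame pressure/box record (bar, Å)."""
    df = pd.read_csv(path)
    missing = [c for c in PRESSURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: pressure table missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# leaflet assignment
# ---------------------------------------------------------------------------


def assign_leaflets(frame: BoxedFrame, gmap: GroupMap, on_single_leaflet: str = "error") -> LeafletPartition:
    """Assign each lipid molecule to the upper or lower leaflet.

    The midplane is the mean z of all phosphorus (P/PO4) positions; a
    molecule is *upper* iff its phosphorus sits above the midplane. Ions
    and any species without a phosphorus designation are left unassigned.
    Deterministic, and invariant under rigid z-translation of the frame.

    ``on_single_leaflet`` chooses between raising and warning when every
    lipid ends up on one side (a degenerate, monolayer-like input).
    """
    lipids = gmap.lipid_species()
    present = set(frame.species)
    present_lipids = [s for s in lipids if s in present]
    for sp in present:
        if sp not in gmap.species:
            raise KeyError(f"species {sp!r} present in frame but missing from group map")
    if not present_lipids:
        raise ValueError("frame contains no lipid species known to the group map")

    mols: list[int] = []
    zs: list[float] = []
    for sp in present_lipids:
        psite = gmap.species[sp].phosphorus_site
        mask = (frame.species == sp) & (frame.names == psite)
        mol_ids = frame.molecule[mask]
        if len(mol_ids) != len(frame.molecules_of(sp)):
            raise ValueError(f"species {sp!r}: not every molecule has one {psite!r} site")
        mols.extend(int(m) for m in mol_ids)
        zs.extend(frame.coords[mask, 2])
    if len(mols) < 2:
        raise ValueError("need at least two lipid molecules to assign leaflets")

    zarr = np.asarray(zs)
    midplane = float(zarr.mean())
    upper = zarr > midplane
    assignment = {m: ("upper" if u else "lower") for m, u in zip(mols, upper)}
    if upper.all() or (~upper).all():
        msg = "all lipid phosphorus sites fall on one side of the midplane (single leaflet?)"
        if on_single_leaflet == "warn":
            warnings.warn(msg)
        else:
            raise ValueError(msg)
    return LeafletPartition(assignment=assignment, midplane_z=midplane)
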