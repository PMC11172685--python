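"""Structure, trajectory, compound-library and score-table I/O.

All coordinates are in Angstrom and residues are addressed by author (PDB)
numbering throughout the package.  The SHP2 domain model (N-SH2, C-SH2, PTP)
lives here as :class:`DomainMap`; every residue id cited elsewhere (Arg111,
Glu83, ...) is interpreted in 2SHP author numbering.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
import biotite.structure as bts
import biotite.structure.io.pdb as bts_pdb

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "DomainMap",
    "CompoundRecord",
    "ScoreTable",
    "StructureFormatError",
    "EmptySelectionError",
    "read_structure",
    "write_structure",
    "select_atoms",
    "read_compounds",
    "read_score_table",
    "DEFAULT_DOMAIN_MAP",
]


class StructureFormatError(ValueError):
    """Raised for malformed structure files (carries a line number if known)."""


class EmptySelectionError(ValueError):
    """Raised when an atom selection matches nothing."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom as read from a PDB file, author numbering preserved."""

    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    model_no: int = 1


class Structure:
    """An ordered collection of atoms backed by flat numpy arrays.

    Atom order is stable under round-trip write/read.  ``residue_index``
    maps ``(chain_id, res_seq)`` to the contiguous index span of that
    residue's atoms.
    """

    def __init__(
        self,
        serial: np.ndarray,
        name: np.ndarray,
        element: np.ndarray,
        alt_loc: np.ndarray,
        res_name: np.ndarray,
        chain_id: np.ndarray,
        res_seq: np.ndarray,
        coords: np.ndarray,
        occupancy: np.ndarray | None = None,
        model_no: int = 1,
    ):
        n = len(serial)
        coords = np.asarray(coords, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        self.serial = np.asarray(serial, dtype=int)
        self.name = np.asarray(name, dtype="U6")
        self.element = np.asarray(element, dtype="U2")
        self.alt_loc = np.asarray(alt_loc, dtype="U1")
        self.res_name = np.asarray(res_name, dtype="U4")
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.res_seq = np.asarray(res_seq, dtype=int)
        self.coords = coords
        self.occupancy = (
            np.ones(n) if occupancy is None else np.asarray(occupancy, dtype=float)
        )
        self.model_no = model_no

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.serial)

    @property
    def n_atoms(self) -> int:
        return len(self)

    @property
    def chains(self) -> set[str]:
        return set(self.chain_id.tolist())

    @property
    def residue_index(self) -> dict[tuple[str, int], slice]:
        """(chain_id, res_seq) -> slice covering that residue's atoms."""
        index: dict[tuple[str, int], slice] = {}
        if len(self) == 0:
            return index
        keys = list(zip(self.chain_id.tolist(), self.res_seq.tolist()))
        start = 0
        for i in range(1, len(keys) + 1):
            if i == len(keys) or keys[i] != keys[start]:
                key = keys[start]
                if key in index:
                    raise ValueError(
                        f"residue {key} appears in non-contiguous atom spans"
                    )
                index[key] = slice(start, i)
                start = i
        return index

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(len(self)):
            yield AtomRecord(
                serial=int(self.serial[i]),
                name=str(self.name[i]),
                element=str(self.element[i]),
                alt_loc=str(self.alt_loc[i]),
                res_name=str(self.res_name[i]),
                chain_id=str(self.chain_id[i]),
                res_seq=int(self.res_seq[i]),
                coords=self.coords[i].copy(),
                occupancy=float(self.occupancy[i]),
                model_no=self.model_no,
            )

    def subset(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask, dtype=bool)
        return Structure(
            self.serial[mask],
            self.name[mask],
            self.element[mask],
            self.alt_loc[mask],
            self.res_name[mask],
            self.chain_id[mask],
            self.res_seq[mask],
            self.coords[mask],
            self.occupancy[mask],
            self.model_no,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.subset(np.ones(len(self), dtype=bool))
        out.coords = np.asarray(coords, dtype=float).reshape(len(self), 3)
        return out

    # -- conversion ---------------------------------------------------------
    @classmethod
    def from_atom_array(cls, arr: bts.AtomArray, model_no: int = 1) -> "Structure":
        n = arr.array_length()
        serial = (
            arr.get_annotation("atom_id")
            if "atom_id" in arr.get_annotation_categories()
            else np.arange(1, n + 1)
        )
        occ = (
            arr.get_annotation("occupancy")
            if "occupancy" in arr.get_annotation_categories()
            else np.ones(n)
        )
        alt = (
            arr.get_annotation("altloc_id")
            if "altloc_id" in arr.get_annotation_categories()
            else np.full(n, "", dtype="U1")
        )
        return cls(
            serial=serial,
            name=arr.atom_name,
            element=arr.element,
            alt_loc=alt,
            res_name=arr.res_name,
            chain_id=arr.chain_id,
            res_seq=arr.res_id,
            coords=arr.coord,
            occupancy=occ,
            model_no=model_no,
        )

    def to_atom_array(self, coords: np.ndarray | None = None) -> bts.AtomArray:
        n = len(self)
        arr = bts.AtomArray(n)
        arr.coord = np.asarray(self.coords if coords is None else coords, dtype=np.float32)
        arr.chain_id = self.chain_id
        arr.res_id = self.res_seq
        arr.res_name = self.res_name
        arr.atom_name = self.name
        arr.element = self.element
        arr.set_annotation("atom_id", self.serial)
        arr.set_annotation("occupancy", self.occupancy)
        arr.hetero = np.array(
            [rn not in _STANDARD_RESIDUES for rn in self.res_name], dtype=bool
        )
        return arr

    def to_dict(self) -> dict:
        return {
            "atoms": [
                {
                    "serial": int(s),
                    "name": str(nm),
                    "element": str(el),
                    "res_name": str(rn),
                    "chain_id": str(ch),
                    "res_seq": int(rs),
                    "coords": [round(float(c), 3) for c in xyz],
                }
                for s, nm, el, rn, ch, rs, xyz in zip(
                    self.serial, self.name, self.element, self.res_name,
                    self.chain_id, self.res_seq, self.coords,
                )
            ]
        }


_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class Trajectory:
    """Frames sharing one atom table.

    ``frames`` has shape (n_frames, n_atoms, 3) in Angstrom;
    ``frame_interval`` is carried as metadata only (time units per frame).
    """

    topology: Structure
    frames: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


class DomainMap:
    """Named residue intervals for the SHP2 domain architecture.

    Intervals are inclusive, author-numbered, and must not overlap.  Residues
    on inter-domain linkers belong to no domain (``domain_of`` returns None).
    """

    def __init__(self, intervals: dict[str, list[tuple[int, int]]]):
        flat: list[tuple[int, int, str]] = []
        for name, ivs in intervals.items():
            for lo, hi in ivs:
                if lo > hi:
                    raise ValueError(f"bad interval ({lo},{hi}) for {name}")
                flat.append((lo, hi, name))
        flat.sort()
        for (lo1, hi1, n1), (lo2, hi2, n2) in zip(flat, flat[1:]):
            if lo2 <= hi1:
                raise ValueError(
                    f"overlapping intervals: {n1} ({lo1},{hi1}) and {n2} ({lo2},{hi2})"
                )
        self.intervals = {k: [tuple(iv) for iv in v] for k, v in intervals.items()}

    def domain_of(self, res_seq: int) -> str | None:
        for name, ivs in self.intervals.items():
            for lo, hi in ivs:
                if lo <= res_seq <= hi:
                    return name
        return None

    @property
    def names(self) -> list[str]:
        return list(self.intervals)

    def residues(self, name: str) -> list[int]:
        return [r for lo, hi in self.intervals[name] for r in range(lo, hi + 1)]

    def to_dict(self) -> dict:
        return {k: [list(iv) for iv in v] for k, v in self.intervals.items()}


#: Default SHP2 domain intervals (author numbering of the closed-state
#: crystal structure).  Boundaries are configuration, not ground truth:
#: the linkers 105-111 and 217-220 belong to no domain.
DEFAULT_DOMAIN_MAP = DomainMap(
    {"N-SH2": [(3, 104)], "C-SH2": [(112, 216)], "PTP": [(221, 524)]}
)


@dataclass
class CompoundRecord:
    """A small molecule with the properties the pre-filter needs."""

    id: str
    mol_weight: float  # Da, average atomic masses, implicit H included
    net_charge: int  # sum of formal charges, a.u.
    elements: frozenset[str]
    graph: object | None = None  # RDKit Mol when available

    def __post_init__(self):
        if not self.mol_weight > 0:
            raise ValueError(f"{self.id}: mol_weight must be positive")
        if self.net_charge != int(self.net_charge):
            raise ValueError(f"{self.id}: net_charge must be integral")


@dataclass
class ScoreTable:
    """Docking affinities: one row per (compound, receptor, pose_rank).

    More negative affinity (kcal/mol) means stronger predicted binding.
    """

    df: pd.DataFrame

    REQUIRED = ("compound_id", "receptor_id", "affinity")

    def __post_init__(self):
        df = self.df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"score table missing column {col!r}")
        if "pose_rank" not in df.columns:
            df["pose_rank"] = 1
        if not np.all(np.isfinite(df["affinity"].to_numpy(dtype=float))):
            raise ValueError("non-finite affinity")
        dup = df.duplicated(subset=["compound_id", "receptor_id", "pose_rank"])
        if dup.any():
            first = df[dup].iloc[0]
            raise ValueError(
                "duplicate (compound, receptor, pose_rank): "
                f"({first['compound_id']}, {first['receptor_id']}, {first['pose_rank']})"
            )
        self.df = df

    @property
    def receptors(self) -> list[str]:
        return sorted(self.df["receptor_id"].unique().tolist())

    @property
    def compounds(self) -> list[str]:
        return sorted(self.df["compound_id"].unique().tolist())

    def best_pose(self, receptor_id: str) -> pd.DataFrame:
        sub = self.df[self.df["receptor_id"] == receptor_id]
        if sub.empty:
            raise KeyError(f"receptor {receptor_id!r} not in score table")
        return sub[sub["pose_rank"] == sub.groupby("compound_id")["pose_rank"].transform("min")]


# ---------------------------------------------------------------------------
# PDB reading / writing


def _prescan_pdb(path: Path) -> None:
    """Cheap line-level validation so errors can cite a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise StructureFormatError(
                        f"{path}:{lineno}: truncated ATOM record"
                    )
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError:
                    raise StructureFormatError(
                        f"{path}:{lineno}: unparseable coordinates in ATOM record"
                    ) from None


def read_structure(
    path: str | Path, model_policy: Literal["first", "all"] = "first"
) -> Structure | Trajectory:
    """Read a PDB file into a :class:`Structure` (or :class:`Trajectory`).

    ``model_policy="all"`` turns a multi-model file into a trajectory whose
    topology is the first model; all models must then share one atom table.
    Alternate locations are resolved to the highest-occupancy conformer
    (ties go to the first, i.e. 'A').  Author residue numbering is kept.
    """
    path = Path(path)
    _prescan_pdb(path)
    pdb = bts_pdb.PDBFile.read(path)
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise StructureFormatError(f"{path}: file contains no atoms")

    def _model(i: int) -> bts.AtomArray:
        arr = pdb.get_structure(
            model=i, altloc="occupancy", extra_fields=["atom_id", "occupancy"]
        )
        if arr.array_length() == 0:
            raise StructureFormatError(f"{path}: model {i} contains no atoms")
        return arr

    if model_policy == "first" or n_models == 1:
        return Structure.from_atom_array(_model(1))
    if model_policy != "all":
        raise ValueError(f"unknown model_policy {model_policy!r}")

    structures = [Structure.from_atom_array(_model(i), model_no=i) for i in range(1, n_models + 1)]
    counts = {s.n_atoms for s in structures}
    if len(counts) != 1:
        raise StructureFormatError(
            f"{path}: MODEL sections differ in atom count ({sorted(counts)}); "
            "frames must share one topology"
        )
    top = structures[0]
    for s in structures[1:]:
        if not (
            np.array_equal(s.name, top.name)
            and np.array_equal(s.res_seq, top.res_seq)
            and np.array_equal(s.chain_id, top.chain_id)
        ):
            raise StructureFormatError(
                f"{path}: MODEL sections differ in atom identity; "
                "frames must share one topology"
            )
    frames = np.stack([s.coords for s in structures])
    return Trajectory(topology=top, frames=frames)


def write_structure(obj: Structure | Trajectory, path: str | Path) -> None:
    """Write a structure (single model) or trajectory (multi-model) PDB."""
    pdb = bts_pdb.PDBFile()
    if isinstance(obj, Trajectory):
        arrays = [obj.topology.to_atom_array(coords=f) for f in obj.frames]
        stack = bts.stack(arrays)
        pdb.set_structure(stack)
    else:
        pdb.set_structure(obj.to_atom_array())
    pdb.write(Path(path))


# ---------------------------------------------------------------------------
# Atom selection

_BACKBONE_TO_CB = {"N", "CA", "C", "O", "CB", "OXT"}
_HYDROGEN = {"H", "D"}


def select_atoms(
    s: Structure,
    chain: str | None = None,
    res_range: tuple[int, int] | Sequence[int] | None = None,
    atom_class: Literal["CA", "heavy_to_CB", "heavy", "all"] = "all",
) -> Structure:
    """Subset a structure by chain, author-numbered residues and atom class.

    ``heavy_to_CB`` keeps backbone heavy atoms plus CB (and OXT when present)
    — the clustering metric atom set; ``CA`` keeps one alpha carbon per
    residue; hydrogens are excluded from all non-``all`` classes.
    """
    mask = np.ones(len(s), dtype=bool)
    if chain is not None:
        mask &= s.chain_id == chain
    if res_range is not None:
        if isinstance(res_range, tuple) and len(res_range) == 2:
            lo, hi = res_range
            mask &= (s.res_seq >= lo) & (s.res_seq <= hi)
        else:
            mask &= np.isin(s.res_seq, np.asarray(list(res_range), dtype=int))
    if atom_class == "CA":
        mask &= (s.name == "CA") & (s.element == "C")
    elif atom_class == "heavy_to_CB":
        mask &= np.isin(s.name, sorted(_BACKBONE_TO_CB)) & ~np.isin(
            s.element, sorted(_HYDROGEN)
        )
    elif atom_class == "heavy":
        mask &= ~np.isin(s.element, sorted(_HYDROGEN))
    elif atom_class != "all":
        raise ValueError(f"unknown atom_class {atom_class!r}")
    if not mask.any():
        raise EmptySelectionError(
            f"selection (chain={chain!r}, res_range={res_range!r}, "
            f"atom_class={atom_class!r}) matched no atoms"
        )
    return s.subset(mask)


# ---------------------------------------------------------------------------
# Compound libraries


def read_compounds(
    path: str | Path, fmt: Literal["sdf", "smiles"]
) -> list[CompoundRecord]:
    """Read an SDF or SMILES library into :class:`CompoundRecord` objects.

    Molecular weight uses standard (average) atomic masses over all atoms
    including implicit hydrogens.  Unparseable records are skipped with a
    logged warning and counted.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    path = Path(path)
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    elif fmt == "smiles":
        supplier = Chem.SmilesMolSupplier(
            str(path), titleLine=False, delimiter=" \t", nameColumn=1
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")

    records: list[CompoundRecord] = []
    n_failed = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            n_failed += 1
            logger.warning("%s: record %d failed to parse, skipped", path, i)
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"record-{i}"
        elements = {a.GetSymbol() for a in mol.GetAtoms()}
        if any(a.GetTotalNumHs() > 0 for a in mol.GetAtoms()):
            elements.add("H")
        records.append(
            CompoundRecord(
                id=cid,
                mol_weight=float(Descriptors.MolWt(mol)),
                net_charge=int(Chem.GetFormalCharge(mol)),
                elements=frozenset(elements),
                graph=mol,
            )
        )
    if n_failed:
        logger.warning("%s: %d records failed to parse", path, n_failed)
    return records


# ---------------------------------------------------------------------------
# Score tables


def read_score_table(path: str | Path) -> ScoreTable:
    """Read a delimited (CSV/TSV, header required) docking score table."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in ScoreTable.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: header missing column(s) {missing}")
    if df.empty:
        warnings.warn(f"{path}: empty score table", stacklevel=2)
        df["affinity"] = df["affinity"].astype(float)
        return ScoreTable(df)
    affinity = pd.to_numeric(df["affinity"], errors="coerce")
    bad = affinity.isna() & df["affinity"].notna() | df["affinity"].isna()
    if bad.any():
        # +2: header line plus 1-based indexing
        lineno = int(bad.idxmax()) + 2
        raise ValueError(f"{path}:{lineno}: non-numeric affinity value")
    df["affinity"] = affinity.astype(float)
    return ScoreTable(df)


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def score_table_to_json(table: ScoreTable) -> str:
    return json.dumps(table.df.to_dict(orient="records"))
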