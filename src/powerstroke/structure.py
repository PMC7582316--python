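"""Atomic-coordinate containers and PDB input/output.

Structures are flat, ordered atom lists keyed by author residue numbering,
which is how the crystallographic literature on the myosin motor domain
names its residues (P-loop 179-186, switch-1 232-238, and so on).  Parsing
and writing of the fixed-column PDB format is delegated to :mod:`gemmi`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "AtomSelection",
    "BACKBONE_NAMES",
    "WATER_NAMES",
    "read_pdb",
    "write_pdb",
    "write_trajectory_pdb",
    "select",
]

#: Protein backbone heavy-atom names.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

#: Residue names treated as solvent.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


@dataclass
class Atom:
    """One ATOM/HETATM record.

    ``res_seq`` carries the author (deposited) residue number.  ``coords``
    is a length-3 float array in Angstrom.
    """

    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atom_name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0
    het: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.atom_name}: coords must be 3 finite numbers")
        if not self.res_name:
            raise ValueError("res_name must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.res_seq, self.icode, self.atom_name, self.altloc)

    @property
    def residue_id(self) -> tuple:
        return (self.chain_id, self.res_seq, self.icode)


class Structure:
    """Ordered collection of atoms; iteration preserves file order."""

    def __init__(self, atoms: Iterable[Atom], id: str = "") -> None:
        self.atoms: list[Atom] = list(atoms)
        self.id = id
        seen: set[tuple] = set()
        for a in self.atoms:
            if a.key in seen:
                raise ValueError(f"duplicate atom record {a.key} in structure {id!r}")
            seen.add(a.key)
        self._index = {a.key: i for i, a in enumerate(self.atoms)}

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def __getitem__(self, i: int) -> Atom:
        return self.atoms[i]

    def coord_array(self) -> np.ndarray:
        """(n_atoms, 3) coordinate matrix in file order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.coords for a in self.atoms])

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        """Copy of the structure with replaced coordinates (same atom list)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match {len(self.atoms)} atoms"
            )
        atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms, id=self.id if id is None else id)

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def find_atom(
        self, chain_id: str, res_seq: int, atom_name: str, icode: str = ""
    ) -> Atom | None:
        for altloc in ("", "A"):
            a = self._index.get((chain_id, res_seq, icode, atom_name, altloc))
            if a is not None:
                return self.atoms[a]
        return None

    def residues(self) -> list[tuple]:
        """Residue ids (chain, res_seq, icode) in first-appearance order."""
        out: list[tuple] = []
        seen: set[tuple] = set()
        for a in self.atoms:
            rid = a.residue_id
            if rid not in seen:
                seen.add(rid)
                out.append(rid)
        return out


@dataclass(frozen=True)
class AtomSelection:
    """Declarative atom subset: chain, inclusive author-numbering ranges,
    atom names, and optionally residue names (for HETATM ligands)."""

    chain: str | None = None
    residue_ranges: tuple[tuple[int, int], ...] = ()
    atom_names: frozenset[str] | None = None
    res_names: frozenset[str] | None = None

    def __post_init__(self) -> None:
        ranges = tuple((int(a), int(b)) for a, b in self.residue_ranges)
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError(f"residue range ({lo}, {hi}) has start > end")
        object.__setattr__(self, "residue_ranges", ranges)
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", frozenset(self.atom_names))
        if self.res_names is not None:
            object.__setattr__(self, "res_names", frozenset(self.res_names))

    def matches(self, atom: Atom) -> bool:
        if atom.altloc not in ("", "A"):
            return False
        if self.chain is not None and atom.chain_id != self.chain:
            return False
        if self.residue_ranges and not any(
            lo <= atom.res_seq <= hi for lo, hi in self.residue_ranges
        ):
            return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        if self.res_names is not None and atom.res_name not in self.res_names:
            return False
        return True


def select(structure: Structure, sel: AtomSelection) -> Structure:
    """Subset of ``structure`` matching ``sel``, preserving atom order.

    Residue ranges are inclusive on author numbering; only blank/'A'
    alternate locations are kept.  Raises ``ValueError`` when nothing
    matches (a silent empty selection hides typos in residue ranges).
    """
    if not structure.atoms:
        raise ValueError("cannot select from an empty structure")
    atoms = [a for a in structure.atoms if sel.matches(a)]
    if not atoms:
        raise ValueError(f"selection {sel} matched zero atoms in {structure.id!r}")
    return Structure(atoms, id=structure.id)


def selection_indices(structure: Structure, sel: AtomSelection) -> np.ndarray:
    """Indices (into file order) of atoms matching ``sel``."""
    idx = np.array(
        [i for i, a in enumerate(structure.atoms) if sel.matches(a)], dtype=int
    )
    if idx.size == 0:
        raise ValueError(f"selection {sel} matched zero atoms in {structure.id!r}")
    return idx


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _from_gemmi(st: gemmi.Structure, id: str) -> Structure:
    if len(st) == 0:
        raise ValueError(f"{id!r}: no models / no parseable ATOM records")
    model = st[0]  # first model only; crystal structures here are single-model
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        icode=(res.seqid.icode or " ").strip(),
                        res_name=res.name,
                        atom_name=at.name,
                        element=at.element.name,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        altloc="" if at.altloc in ("\0", " ", "") else at.altloc,
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        bfactor=at.b_iso,
                        het=het,
                    )
                )
    if not atoms:
        raise ValueError(f"{id!r}: no ATOM/HETATM records found")
    return Structure(atoms, id=id)


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file into a :class:`Structure` (first model only,
    HETATM retained)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    return _from_gemmi(st, id=path.stem)


def read_pdb_frames(path: str | Path) -> tuple[Structure, list[np.ndarray]]:
    """Read a multi-MODEL PDB file: template (first model) plus one
    coordinate array per model."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    template = _from_gemmi(st, id=path.stem)
    frames = []
    for model in st:
        xyz = [
            [at.pos.x, at.pos.y, at.pos.z]
            for chain in model
            for res in chain
            for at in res
        ]
        frames.append(np.asarray(xyz, dtype=float))
    if any(f.shape != (len(template), 3) for f in frames):
        raise ValueError(f"{path}: models have inconsistent atom counts")
    return template, frames


def _to_gemmi(structure: Structure, models: Sequence[np.ndarray] | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id or "model"
    coord_sets: Sequence[np.ndarray | None]
    if models is None:
        coord_sets = [None]
    else:
        coord_sets = list(models)
    for m, coords in enumerate(coord_sets, start=1):
        model = gemmi.Model(m)
        chain = None
        residue = None
        last_rid = None
        last_chain = None
        for i, a in enumerate(structure.atoms):
            if a.chain_id != last_chain:
                chain = gemmi.Chain(a.chain_id)
                model.add_chain(chain)
                chain = model[-1]
                last_chain = a.chain_id
                last_rid = None
            if a.residue_id != last_rid:
                residue = gemmi.Residue()
                residue.name = a.res_name
                residue.seqid = gemmi.SeqId(a.res_seq, a.icode or " ")
                residue.het_flag = "H" if a.het else "A"
                chain.add_residue(residue)
                residue = chain[-1]
                last_rid = a.residue_id
            at = gemmi.Atom()
            at.name = a.atom_name
            xyz = a.coords if coords is None else coords[i]
            at.pos = gemmi.Position(*map(float, xyz))
            at.element = gemmi.Element(a.element or a.atom_name[:1])
            at.occ = a.occupancy
            at.b_iso = a.bfactor
            at.altloc = a.altloc or "\0"
            residue.add_atom(at)
        st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB file (fixed-format, 3-decimal coordinates)."""
    _to_gemmi(structure).write_pdb(str(path))


def write_trajectory_pdb(
    template: Structure, frames: Sequence[np.ndarray], path: str | Path
) -> None:
    """Write a multi-frame coordinate set as a frame-per-MODEL PDB file."""
    if len(frames) == 0:
        raise ValueError("no frames to write")
    _to_gemmi(template, models=frames).write_pdb(str(path))


def pair_atoms(
    mobile: Structure,
    reference: Structure,
    sel: AtomSelection | None = None,
    match_chain: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of atoms present in both structures, paired by
    (chain, res_seq, icode, atom_name), in reference order.

    Deposited structures differ in resolved termini, so pairing is the
    intersection of author residue numbers rather than a strict match.
    """
    def eligible(s: Structure) -> dict:
        out = {}
        for a in s.atoms:
            if a.altloc not in ("", "A"):
                continue
            if sel is not None and not sel.matches(a):
                continue
            if match_chain:
                k = (a.chain_id, a.res_seq, a.icode, a.atom_name)
            else:
                k = (a.res_seq, a.icode, a.atom_name)
            out.setdefault(k, a)
        return out

    mob = eligible(mobile)
    ref = eligible(reference)
    keys = [k for k in ref if k in mob]
    if len(keys) < 3:
        raise ValueError(
            f"only {len(keys)} paired atoms between {mobile.id!r} and {reference.id!r}"
        )
    x = np.stack([mob[k].coords for k in keys])
    y = np.stack([ref[k].coords for k in keys])
    return x, y
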