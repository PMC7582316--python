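"""Hydrogen-bond and salt-bridge detection, trajectory occupancy, and
per-residue interaction hubs.

Crystal structures carry no hydrogens, so the hydrogen-bond criterion is
purely geometric by default: two N/O/S heavy atoms from different
residues within a donor-acceptor cutoff (3.5 A).  When explicit
hydrogens are present, a D-H...A angle criterion is applied on top.
Salt bridges pair the charged-group nitrogens of Arg/Lys/His with the
carboxylate oxygens of Asp/Glu within 4.0 A.  These are the common
literature conventions; both cutoffs are arguments, not constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import WATER_NAMES, Atom, AtomSelection, Structure, select
from .trajectory import Trajectory

__all__ = [
    "HBond",
    "SaltBridge",
    "OccupancyTable",
    "HBondCriteria",
    "detect_hbonds",
    "detect_salt_bridges",
    "occupancy_over_trajectory",
    "interaction_hub",
]

#: Heavy-atom elements that can donate or accept a hydrogen bond.
POLAR_ELEMENTS = frozenset({"N", "O", "S"})

BASIC_RESIDUES = frozenset({"ARG", "LYS", "HIS"})
ACIDIC_RESIDUES = frozenset({"ASP", "GLU"})

#: Charged-group heavy atoms per residue type.
BASIC_ATOMS = {
    "ARG": frozenset({"NH1", "NH2", "NE"}),
    "LYS": frozenset({"NZ"}),
    "HIS": frozenset({"ND1", "NE2"}),
}
ACIDIC_ATOMS = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}


@dataclass(frozen=True)
class HBond:
    """Heavy-atom polar contact; donor/acceptor assignment is geometric
    only when hydrogens are present, otherwise the two partners are
    reported in selection order."""

    atom_a: tuple
    atom_b: tuple
    distance: float
    angle: float | None = None


@dataclass(frozen=True)
class SaltBridge:
    basic_residue: tuple
    acidic_residue: tuple
    distance: float


@dataclass(frozen=True)
class HBondCriteria:
    dist_cutoff: float = 3.5
    angle_cutoff: float = 120.0


@dataclass
class OccupancyTable:
    """Per-residue hydrogen-bond occupancy over a trajectory, as a
    percentage of frames.  A residue holding k simultaneous bonds in a
    frame contributes k, so occupancies above 100% are meaningful (they
    are how multi-dentate anchors such as the P-loop lysine show up)."""

    occupancy: dict[tuple, float]
    n_frames: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chain": r[0], "res_seq": r[1], "icode": r[2], "occupancy_pct": v}
            for r, v in sorted(self.occupancy.items(), key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows, columns=["chain", "res_seq", "icode", "occupancy_pct"])


def _polar(atom: Atom) -> bool:
    element = atom.element or atom.atom_name[:1]
    return element.upper() in POLAR_ELEMENTS


def _is_hydrogen(atom: Atom) -> bool:
    element = atom.element or atom.atom_name[:1]
    return element.upper() in ("H", "D")


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    structure: Structure,
    partner_a: AtomSelection,
    partner_b: AtomSelection,
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
) -> list[HBond]:
    """All polar heavy-atom pairs across the two selections within
    ``dist_cutoff`` (excluding same-residue pairs).

    The D-H...A angle criterion (>= ``angle_cutoff``) is applied only to
    pairs where either partner carries an attached hydrogen (within
    1.25 A), i.e. only on coordinates that actually have hydrogens.
    """
    def wanted(sel: AtomSelection):
        # waters stay out of interaction analysis unless asked for by name
        return [
            a
            for a in select(structure, sel)
            if _polar(a)
            and (a.res_name not in WATER_NAMES or (sel.res_names and a.res_name in sel.res_names))
        ]

    atoms_a = wanted(partner_a)
    atoms_b = wanted(partner_b)
    if not atoms_a or not atoms_b:
        return []
    hydrogens = [a for a in structure if _is_hydrogen(a)]
    h_coords = np.stack([h.coords for h in hydrogens]) if hydrogens else None

    xb = np.stack([a.coords for a in atoms_b])
    tree_b = cKDTree(xb)
    out: list[HBond] = []
    for a in atoms_a:
        for j in tree_b.query_ball_point(a.coords, r=dist_cutoff):
            b = atoms_b[j]
            if a.residue_id == b.residue_id:
                continue
            d = float(np.linalg.norm(a.coords - b.coords))
            angle = None
            if h_coords is not None:
                angle = _best_dha_angle(a, b, hydrogens, h_coords)
                if angle is not None and angle < angle_cutoff:
                    continue
            out.append(HBond(atom_a=a.key, atom_b=b.key, distance=d, angle=angle))
    out.sort(key=lambda hb: (hb.distance, hb.atom_a, hb.atom_b))
    return out


def _best_dha_angle(a: Atom, b: Atom, hydrogens, h_coords) -> float | None:
    """Largest D-H...A angle over hydrogens covalently attached (<=1.25 A)
    to either partner; None when neither partner carries a hydrogen."""
    best = None
    for donor, acceptor in ((a, b), (b, a)):
        dist_h = np.linalg.norm(h_coords - donor.coords, axis=1)
        for k in np.nonzero(dist_h <= 1.25)[0]:
            ang = _angle_deg(donor.coords, hydrogens[k].coords, acceptor.coords)
            best = ang if best is None else max(best, ang)
    return best


def detect_salt_bridges(structure: Structure, cutoff: float = 4.0) -> list[SaltBridge]:
    """Arg/Lys/His vs Asp/Glu residue pairs whose charged-group heavy
    atoms approach within ``cutoff``; one bridge per residue pair at the
    minimum such distance.

    Histidine counts as basic only when both imidazole nitrogens are
    present (protonation is unknowable from coordinates alone).
    """
    basic: dict[tuple, list[Atom]] = {}
    acidic: dict[tuple, list[Atom]] = {}
    for a in structure:
        if a.altloc not in ("", "A"):
            continue
        if a.res_name in BASIC_ATOMS and a.atom_name in BASIC_ATOMS[a.res_name]:
            basic.setdefault(a.residue_id, []).append(a)
        elif a.res_name in ACIDIC_ATOMS and a.atom_name in ACIDIC_ATOMS[a.res_name]:
            acidic.setdefault(a.residue_id, []).append(a)
    basic = {
        rid: atoms
        for rid, atoms in basic.items()
        if atoms[0].res_name != "HIS" or len({a.atom_name for a in atoms}) == 2
    }
    if not basic or not acidic:
        return []
    acid_atoms = [a for atoms in acidic.values() for a in atoms]
    tree = cKDTree(np.stack([a.coords for a in acid_atoms]))
    best: dict[tuple[tuple, tuple], float] = {}
    for rid, atoms in basic.items():
        for a in atoms:
            for j in tree.query_ball_point(a.coords, r=cutoff):
                b = acid_atoms[j]
                d = float(np.linalg.norm(a.coords - b.coords))
                key = (rid, b.residue_id)
                if key not in best or d < best[key]:
                    best[key] = d
    bridges = [
        SaltBridge(basic_residue=k[0], acidic_residue=k[1], distance=v)
        for k, v in best.items()
    ]
    bridges.sort(key=lambda sb: (sb.distance, sb.basic_residue, sb.acidic_residue))
    return bridges


def occupancy_over_trajectory(
    traj: Trajectory,
    ligand_sel: AtomSelection,
    protein_sel: AtomSelection,
    criteria: HBondCriteria = HBondCriteria(),
) -> OccupancyTable:
    """Hydrogen-bond occupancy of each protein residue against the ligand:
    100 x (total simultaneous bonds summed over frames) / n_frames."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    counts: dict[tuple, int] = {}
    for i in range(len(traj)):
        frame = traj.frame_structure(i)
        for hb in detect_hbonds(
            frame,
            ligand_sel,
            protein_sel,
            dist_cutoff=criteria.dist_cutoff,
            angle_cutoff=criteria.angle_cutoff,
        ):
            rid = hb.atom_b[:3]  # (chain, res_seq, icode) of the protein partner
            counts[rid] = counts.get(rid, 0) + 1
    occ = {rid: 100.0 * n / len(traj) for rid, n in counts.items()}
    return OccupancyTable(occupancy=occ, n_frames=len(traj))


def interaction_hub(
    structure: Structure,
    chain: str,
    res_seq: int,
    hbond_cutoff: float = 3.5,
    bridge_cutoff: float = 4.0,
) -> list[tuple[tuple, str, float]]:
    """Interaction partners of one residue: the union of salt bridges and
    hydrogen bonds it participates in, sorted by distance.

    Returns (partner residue id, interaction type, distance) tuples; used
    to characterize communication hubs such as the switch-1 arginine
    (Arg232) and the nucleotide groove (Arg131-Glu187).
    """
    rid = (chain, res_seq, "")
    if not any(a.residue_id == rid for a in structure):
        raise ValueError(f"residue {chain}{res_seq} absent from {structure.id!r}")
    partners: dict[tuple[tuple, str], float] = {}
    for sb in detect_salt_bridges(structure, cutoff=bridge_cutoff):
        if sb.basic_residue == rid:
            partners[(sb.acidic_residue, "salt-bridge")] = sb.distance
        elif sb.acidic_residue == rid:
            partners[(sb.basic_residue, "salt-bridge")] = sb.distance
    own = AtomSelection(chain=chain, residue_ranges=((res_seq, res_seq),))
    rest = AtomSelection()
    for hb in detect_hbonds(structure, own, rest, dist_cutoff=hbond_cutoff):
        partner = hb.atom_b[:3]
        if partner == rid:
            continue
        key = (partner, "hbond")
        if key not in partners or hb.distance < partners[key]:
            partners[key] = hb.distance
    out = [(p, kind, d) for (p, kind), d in partners.items()]
    out.sort(key=lambda x: x[2])
    return out
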