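"""Hydrogen-bond / salt-bridge detection against brute-force oracles,
occupancy accounting, and the interaction-hub report."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from powerstroke.interactions import (
    ACIDIC_ATOMS,
    BASIC_ATOMS,
    HBondCriteria,
    detect_hbonds,
    detect_salt_bridges,
    interaction_hub,
    occupancy_over_trajectory,
)
from powerstroke.structure import Atom, AtomSelection, Structure
from powerstroke.synthetic import ToyMotorSpec, make_toy_motor
from powerstroke.trajectory import Trajectory

ALL = AtomSelection()
ADP = AtomSelection(res_names=frozenset({"ADP"}))


def brute_force_hbond_pairs(structure, sel_a, sel_b, cutoff):
    """All-pairs N/O/S contact enumeration (independent of the KD-tree
    path in the implementation)."""
    def polar(atoms, sel):
        return [
            a
            for a in atoms
            if sel.matches(a)
            and (a.element or a.atom_name[:1]).upper() in ("N", "O", "S")
            and a.res_name not in ("HOH", "WAT", "DOD")
        ]

    pairs = set()
    for a in polar(structure.atoms, sel_a):
        for b in polar(structure.atoms, sel_b):
            if a.residue_id == b.residue_id:
                continue
            if np.linalg.norm(a.coords - b.coords) <= cutoff:
                pairs.add((a.key, b.key))
    return pairs


def brute_force_bridges(structure, cutoff):
    best = {}
    for a in structure:
        if a.res_name not in BASIC_ATOMS or a.atom_name not in BASIC_ATOMS[a.res_name]:
            continue
        for b in structure:
            if b.res_name not in ACIDIC_ATOMS or b.atom_name not in ACIDIC_ATOMS[b.res_name]:
                continue
            d = float(np.linalg.norm(a.coords - b.coords))
            if d <= cutoff:
                key = (a.residue_id, b.residue_id)
                best[key] = min(best.get(key, np.inf), d)
    return best


def test_two_far_atoms_no_hbond():
    st = Structure(
        [
            Atom("A", 1, "", "SER", "OG", "O", np.zeros(3)),
            Atom("A", 2, "", "SER", "OG", "O", np.array([10.0, 0, 0])),
        ]
    )
    assert detect_hbonds(st, ALL, ALL) == []


def test_constructed_pair_at_2p9_A_is_one_hbond():
    st = Structure(
        [
            Atom("A", 1, "", "ASN", "ND2", "N", np.zeros(3)),
            Atom("A", 2, "", "SER", "OG", "O", np.array([2.9, 0, 0])),
            Atom("A", 3, "", "ALA", "CB", "C", np.array([1.0, 1.0, 0])),  # not polar
        ]
    )
    sel1 = AtomSelection(residue_ranges=((1, 1),))
    sel2 = AtomSelection(residue_ranges=((2, 3),))
    bonds = detect_hbonds(st, sel1, sel2)
    assert len(bonds) == 1
    assert bonds[0].distance == pytest.approx(2.9)


def test_angle_criterion_applies_only_with_hydrogens():
    # donor N with H pointing away from the acceptor: D-H...A angle ~25 deg
    st = Structure(
        [
            Atom("A", 1, "", "ASN", "ND2", "N", np.zeros(3)),
            Atom("A", 1, "", "ASN", "HD2", "H", np.array([-0.5, 0.85, 0])),
            Atom("A", 2, "", "SER", "OG", "O", np.array([2.9, 0, 0])),
        ]
    )
    sel1 = AtomSelection(residue_ranges=((1, 1),))
    sel2 = AtomSelection(residue_ranges=((2, 2),))
    assert detect_hbonds(st, sel1, sel2, angle_cutoff=120.0) == []
    # H between donor and acceptor: near-linear, passes
    st2 = Structure(
        [
            Atom("A", 1, "", "ASN", "ND2", "N", np.zeros(3)),
            Atom("A", 1, "", "ASN", "HD2", "H", np.array([1.0, 0.05, 0])),
            Atom("A", 2, "", "SER", "OG", "O", np.array([2.9, 0, 0])),
        ]
    )
    bonds = detect_hbonds(st2, sel1, sel2, angle_cutoff=120.0)
    assert len(bonds) == 1 and bonds[0].angle > 150


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_hbond_detector_matches_brute_force_on_random_structures(seed):
    rng = np.random.default_rng(seed)
    atoms = []
    elements = ["N", "O", "S", "C"]
    for i in range(120):
        e = elements[rng.integers(0, 4)]
        atoms.append(
            Atom(
                "A",
                i + 1,
                "",
                "GLY",
                f"{e}X",
                e,
                rng.uniform(0, 18, 3),
            )
        )
    st = Structure(atoms, id=f"rand{seed}")
    got = {(b.atom_a, b.atom_b) for b in detect_hbonds(st, ALL, ALL, dist_cutoff=3.5)}
    want = brute_force_hbond_pairs(st, ALL, ALL, 3.5)
    assert got == want


def test_constructed_arg_glu_salt_bridge():
    st = Structure(
        [
            Atom("A", 10, "", "ARG", "NH1", "N", np.zeros(3)),
            Atom("A", 10, "", "ARG", "NH2", "N", np.array([0.0, 1.0, 0])),
            Atom("A", 20, "", "GLU", "OE1", "O", np.array([3.0, 0, 0])),
            Atom("A", 20, "", "GLU", "OE2", "O", np.array([3.5, 1.0, 0])),
        ]
    )
    bridges = detect_salt_bridges(st)
    assert len(bridges) == 1
    sb = bridges[0]
    assert sb.basic_residue == ("A", 10, "") and sb.acidic_residue == ("A", 20, "")
    assert sb.distance == pytest.approx(3.0)


def test_glycine_chain_has_no_bridges():
    from conftest import make_chain

    assert detect_salt_bridges(make_chain(range(1, 8), res_name="GLY")) == []


def test_histidine_needs_both_imidazole_nitrogens():
    glu = [
        Atom("A", 2, "", "GLU", "OE1", "O", np.array([3.0, 0, 0])),
    ]
    his_one = Structure([Atom("A", 1, "", "HIS", "ND1", "N", np.zeros(3))] + glu)
    assert detect_salt_bridges(his_one) == []
    his_both = Structure(
        [
            Atom("A", 1, "", "HIS", "ND1", "N", np.zeros(3)),
            Atom("A", 1, "", "HIS", "NE2", "N", np.array([0, 1.3, 0])),
        ]
        + glu
    )
    assert len(detect_salt_bridges(his_both)) == 1


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_salt_bridge_detector_matches_brute_force(seed):
    rng = np.random.default_rng(100 + seed)
    atoms = []
    i = 0
    for r in range(60):
        res = ["ARG", "LYS", "GLU", "ASP", "ALA"][rng.integers(0, 5)]
        names = {
            "ARG": ["NH1", "NH2", "NE"],
            "LYS": ["NZ"],
            "GLU": ["OE1", "OE2"],
            "ASP": ["OD1", "OD2"],
            "ALA": ["CB"],
        }[res]
        base = rng.uniform(0, 25, 3)
        for n in names:
            atoms.append(Atom("A", r + 1, "", res, n, n[0], base + rng.uniform(0, 1.5, 3)))
    st = Structure(atoms, id=f"sb{seed}")
    got = {
        (b.basic_residue, b.acidic_residue): b.distance
        for b in detect_salt_bridges(st, cutoff=4.0)
    }
    want = brute_force_bridges(st, 4.0)
    assert set(got) == set(want)
    for key in got:
        assert got[key] == pytest.approx(want[key])


def test_detectors_invariant_under_rigid_transform(toy_motor_ligand):
    rng = np.random.default_rng(5)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(0, 15, 3)
    moved = toy_motor_ligand.with_coords(toy_motor_ligand.coord_array() @ R.T + t)
    b0 = {(b.basic_residue, b.acidic_residue) for b in detect_salt_bridges(toy_motor_ligand)}
    b1 = {(b.basic_residue, b.acidic_residue) for b in detect_salt_bridges(moved)}
    assert b0 == b1
    h0 = {(b.atom_a, b.atom_b) for b in detect_hbonds(toy_motor_ligand, ADP, ALL)}
    h1 = {(b.atom_a, b.atom_b) for b in detect_hbonds(moved, ADP, ALL)}
    assert h0 == h1


def test_toy_motor_encodes_the_active_site_salt_bridges(toy_motor):
    pairs = {
        (b.basic_residue[1], b.acidic_residue[1]) for b in detect_salt_bridges(toy_motor)
    }
    assert {(131, 187), (238, 459), (232, 180), (232, 674)} <= pairs


def test_interaction_hub_on_toy_switch1_arginine(toy_motor):
    partners = interaction_hub(toy_motor, "A", 232)
    residues = {p[0][1] for p in partners}
    assert {180, 674} <= residues
    # sorted by distance
    dists = [p[2] for p in partners]
    assert dists == sorted(dists)
    with pytest.raises(ValueError, match="absent"):
        interaction_hub(toy_motor, "A", 999)


def _bond_trajectory(pattern):
    """Trajectory of a donor/acceptor pair: in each frame the acceptor is
    near (bonded) or far according to ``pattern``; a second acceptor atom
    doubles the simultaneous-bond count when requested."""
    atoms = [
        Atom("L", 900, "", "ADP", "O3B", "O", np.zeros(3), het=True),
        Atom("A", 1, "", "SER", "OG", "O", np.array([3.0, 0, 0])),
        Atom("A", 1, "", "SER", "N", "N", np.array([0, 3.0, 0])),
    ]
    template = Structure(atoms, id="occ")
    frames = []
    for near, double in pattern:
        c = template.coord_array().copy()
        c[1] = [3.0, 0, 0] if near else [30.0, 0, 0]
        c[2] = [0, 3.0, 0] if double else [0, 30.0, 0]
        frames.append(c)
    return Trajectory(template=template, coords=np.stack(frames),
                      times_ps=np.arange(len(frames), dtype=float))


def test_occupancy_counts_simultaneous_bonds():
    lig = AtomSelection(res_names=frozenset({"ADP"}))
    prot = AtomSelection(chain="A")
    rid = ("A", 1, "")
    # one bond every frame -> 100%
    t = _bond_trajectory([(True, False)] * 4)
    assert occupancy_over_trajectory(t, lig, prot).occupancy[rid] == 100.0
    # two simultaneous bonds every frame -> 200%
    t = _bond_trajectory([(True, True)] * 4)
    assert occupancy_over_trajectory(t, lig, prot).occupancy[rid] == 200.0
    # bonded 1 of 4 frames -> 25%
    t = _bond_trajectory([(True, False), (False, False), (False, False), (False, False)])
    assert occupancy_over_trajectory(t, lig, prot).occupancy[rid] == 25.0


def test_occupancy_concatenation_is_frame_weighted_mean():
    lig = AtomSelection(res_names=frozenset({"ADP"}))
    prot = AtomSelection(chain="A")
    rid = ("A", 1, "")
    t1 = _bond_trajectory([(True, False)] * 3)           # 100%
    t2 = _bond_trajectory([(True, True)] * 2 + [(False, False)] * 4)  # 200*2/6
    occ1 = occupancy_over_trajectory(t1, lig, prot).occupancy[rid]
    occ2 = occupancy_over_trajectory(t2, lig, prot).occupancy[rid]
    both = occupancy_over_trajectory(t1.concat(t2), lig, prot).occupancy[rid]
    expected = (occ1 * 3 + occ2 * 6) / 9
    assert both == pytest.approx(expected)


def test_occupancy_empty_trajectory_rejected():
    t = _bond_trajectory([(True, False)])
    t.coords = t.coords[:0]
    with pytest.raises(ValueError):
        occupancy_over_trajectory(
            t,
            AtomSelection(res_names=frozenset({"ADP"})),
            AtomSelection(chain="A"),
        )
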