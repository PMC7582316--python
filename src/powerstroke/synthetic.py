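"""Synthetic fixtures: toy motor-domain structures, interpolated
trajectories, and Hill-model binding curves.

The toy motor is a metric test jig, not a physically realistic fold.  It
reproduces the *measurable geometry* of the myosin-II motor domain — the
two actin-binding-cleft marker pairs (Ser272/Ser465 inner, Ser416/Lys589
outer), a rotatable converter group, the P-loop, purine-binding loop,
switch-1/2 and SH2-helix residues with salt-bridge-forming side-chain
tips, and an optional four-bead ADP ligand nestled against the P-loop and
the Arg131–Glu187 groove.  Every generator is a pure function of its spec
(seed included), so fixtures never need to be shipped or downloaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .hillfit import DoseResponse
from .structure import Atom, Structure
from .trajectory import Trajectory

__all__ = [
    "ToyMotorSpec",
    "TrajectorySpec",
    "BindingCurveSpec",
    "DoseResponse",
    "make_toy_motor",
    "make_trajectory",
    "make_binding_curve",
    "hill_signal",
]

# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyMotorSpec:
    """Geometry knobs for the toy motor.

    ``inner_cleft``/``outer_cleft`` are the exact Ca-Ca distances of the
    272-465 and 416-589 marker pairs; ``converter_angle`` rotates the
    converter group about a fixed axis relative to the canonical pose.
    """

    n_residues: int = 100
    inner_cleft: float = 10.7
    outer_cleft: float = 10.2
    converter_angle: float = 0.0
    seed: int = 0
    with_ligand: bool = False
    #: rigid translation (A) applied to the P-loop block 179-187, used to
    #: pose release-like targets with the P-loop shifted towards the
    #: front entrance of the active site
    ploop_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ploop_shift", tuple(float(v) for v in self.ploop_shift))
        if self.n_residues < 60:
            raise ValueError("n_residues must be >= 60")
        if self.inner_cleft <= 0 or self.outer_cleft <= 0:
            raise ValueError("cleft distances must be positive")
        if not 0.0 <= self.converter_angle <= 180.0:
            raise ValueError("converter_angle must be in [0, 180] degrees")


@dataclass(frozen=True)
class TrajectorySpec:
    start: Structure
    end: Structure
    n_frames: int = 11
    thermal_sigma: float = 0.0
    seed: int = 0
    dt_ps: float = 1.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.thermal_sigma < 0:
            raise ValueError("thermal_sigma must be >= 0")


@dataclass(frozen=True)
class BindingCurveSpec:
    """Hill-model dose-response generator, emulating a thermophoresis
    titration: a 1:1 dilution series from ``top_conc`` with additive
    Gaussian noise on the normalized signal."""

    kd_true: float = 37.5          # uM
    hill_n: float = 1.0
    top_conc: float = 10_000.0     # uM (10 mM)
    n_points: int = 16
    dilution_factor: float = 2.0
    noise_sigma: float = 0.02      # fraction of the signal range
    seed: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        if self.kd_true <= 0 or self.hill_n <= 0:
            raise ValueError("kd_true and hill_n must be positive")
        if self.n_points < 8:
            raise ValueError("n_points must be >= 8")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


# ---------------------------------------------------------------------------
# Toy motor layout
# ---------------------------------------------------------------------------

# Residue names for the functionally named positions; filler is ALA.
_NAMED_RESIDUES: dict[int, str] = {
    # purine-binding loop 126-136 (VNPFKRIPIYT)
    126: "VAL", 127: "ASN", 128: "PRO", 129: "PHE", 130: "LYS", 131: "ARG",
    132: "ILE", 133: "PRO", 134: "ILE", 135: "TYR", 136: "THR",
    # P-loop 179-186 (Walker A, GESGAGKT) and Glu187
    179: "GLY", 180: "GLU", 181: "SER", 182: "GLY", 183: "ALA", 184: "GLY",
    185: "LYS", 186: "THR", 187: "GLU",
    # switch-1 232-238 (RNNNSSR)
    232: "ARG", 233: "ASN", 234: "ASN", 235: "ASN", 236: "SER", 237: "SER",
    238: "ARG",
    # switch-2 454-459 (DISGFE) and Ile460
    454: "ASP", 455: "ILE", 456: "SER", 457: "GLY", 458: "PHE", 459: "GLU",
    460: "ILE",
    # cleft markers
    272: "SER", 465: "SER", 416: "SER", 589: "LYS",
    # SH2-helix
    674: "ASP",
}

# Side-chain reach (Angstrom from Ca to the charged/polar tip), used to
# split tip placement along a salt-bridge axis.
_REACH = {"ARG": 4.5, "LYS": 4.0, "GLU": 3.2, "ASP": 2.8, "SER": 1.9,
          "THR": 1.9, "ASN": 2.5, "TYR": 4.5}

# Charged/polar tip atom names per residue type.
_TIP_ATOMS = {
    "ARG": ("NH1", "NH2"), "LYS": ("NZ",), "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"), "SER": ("OG",), "THR": ("OG1",),
    "ASN": ("OD1", "ND2"), "TYR": ("OH",),
}

# Group membership by residue-number block (used for overlap checks and
# for documentation of the four-subdomain layout).
_GROUPS = {
    "core": [(2, 13), (670, 678)],
    "u50": [(126, 136), (179, 187), (230, 238), (268, 275), (412, 420)],
    "l50": [(454, 465), (585, 592)],
    "converter": [(690, 702)],
}

_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.50, 0.00]),
    "C": np.array([1.20, 0.50, 0.00]),
    "O": np.array([1.60, 1.60, 0.30]),
}


def _group_of(res_seq: int) -> str:
    for g, ranges in _GROUPS.items():
        if any(lo <= res_seq <= hi for lo, hi in ranges):
            return g
    return "converter"  # extension residues appended past 702


def _base_residue_numbers(n_residues: int) -> list[int]:
    base = [n for rng in _GROUPS.values() for lo, hi in rng for n in range(lo, hi + 1)]
    base.sort()
    essential = set(_NAMED_RESIDUES) | {179, 180, 181, 182, 183, 184, 185, 186}
    # core/converter need enough residues to define non-degenerate frames
    essential |= set(range(2, 8)) | set(range(690, 698)) | set(range(670, 676))
    if n_residues <= len(base):
        removable = [n for n in reversed(base) for _ in [0] if n not in essential]
        drop = set(removable[: len(base) - n_residues])
        if len(drop) < len(base) - n_residues:
            raise ValueError(f"cannot shrink toy motor to {n_residues} residues")
        return [n for n in base if n not in drop]
    # grow by extending the converter helix past 702
    extra = [703 + i for i in range(n_residues - len(base))]
    return base + extra


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise ValueError("zero-length direction")
    return v / n


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(_unit(axis) * np.deg2rad(angle_deg)).as_matrix()


def _ca_positions(spec: ToyMotorSpec, numbers: list[int]) -> dict[int, np.ndarray]:
    """Canonical (unrotated) Ca coordinates for every residue."""
    pos: dict[int, np.ndarray] = {}

    def line(first: int, last: int, origin, step) -> None:
        origin = np.asarray(origin, float)
        step = np.asarray(step, float)
        for n in range(first, last + 1):
            pos[n] = origin + (n - first) * step

    def helix(first: int, last: int, center, rise=1.5, radius=2.3, axis="z") -> None:
        center = np.asarray(center, float)
        for j, n in enumerate(range(first, last + 1)):
            a = np.deg2rad(100.0 * j)
            offset = np.array([radius * np.cos(a), radius * np.sin(a), rise * j])
            if axis == "x":
                offset = offset[[2, 0, 1]]
            pos[n] = center + offset

    # N-terminal-like core
    helix(2, 13, (-16.0, 4.0, 0.0), axis="x")
    line(670, 678, (-6.5 - 4 * 1.1, -1.5 + 4 * 0.3, -4.0 - 4 * 0.25), (1.1, -0.3, 0.25))
    # U50-like: purine loop, P-loop, switch-1, marker blocks
    line(126, 136, (0.5, -10.5, 4.0), (1.2, 0.3, 0.0))
    line(179, 187, (1.6, -4.2, -2.1), (1.4, 0.2, 0.1))
    line(230, 238, (1.0 + 0.0, 1.5, -4.0), (1.3, 0.0, 0.2))
    a272 = np.array([16.0, 0.0, 0.0])
    a416 = np.array([26.0, 0.0, 2.0])
    line(268, 275, a272 - 4 * np.array([1.4, -0.7, 0.4]), (1.4, -0.7, 0.4))
    pos[272] = a272  # marker exact
    line(412, 420, a416 - 4 * np.array([1.3, -0.8, -0.5]), (1.3, -0.8, -0.5))
    pos[416] = a416  # marker exact
    # L50-like: switch-2 running up to the inner-cleft partner 465
    a465 = a272 + np.array([0.0, spec.inner_cleft, 0.0])
    a589 = a416 + np.array([0.0, spec.outer_cleft, 0.0])
    ca459 = np.array([13.5, 6.0, -2.0])
    line(454, 459, ca459 - 5 * np.array([-1.3, 0.6, -0.4]), (-1.3, 0.6, -0.4))
    for n in range(460, 465):
        pos[n] = ca459 + (n - 459) / 6.0 * (a465 - ca459)
    pos[465] = a465
    line(585, 592, a589 - 4 * np.array([1.2, 0.9, 0.5]), (1.2, 0.9, 0.5))
    pos[589] = a589
    # converter helix (canonical pose) plus any extension residues;
    # its base sits close enough to the core helix to join the elastic
    # network (the relay/SH1 coupling of the real motor)
    conv = [n for n in numbers if n >= 690]
    helix(conv[0], conv[-1], (-14.0, 4.0, 7.0))
    return {n: pos[n] for n in numbers}


def _tip_pair(ca_a, ca_b, res_a, res_b, pair_dist):
    """Place one tip per residue on the Ca-Ca axis so the tips sit
    ``pair_dist`` apart, splitting the span by side-chain reach."""
    ca_a, ca_b = np.asarray(ca_a, float), np.asarray(ca_b, float)
    u = _unit(ca_b - ca_a)
    span = float(np.linalg.norm(ca_b - ca_a)) - pair_dist
    ra, rb = _REACH[res_a], _REACH[res_b]
    ta = np.clip(span * ra / (ra + rb), 0.3, ra + 1.5)
    tb = np.clip(span - ta, 0.3, rb + 1.5)
    return ca_a + ta * u, ca_b - tb * u


# Ligand bead layout: four beads for the ADP heavy-atom groups, strung
# through the front entrance of the active site between the P-loop and
# the purine-binding loop.  Each bead carries the element of the group's
# hydrogen-bonding atoms (ring nitrogens, hydroxyl/phosphate oxygens) so
# polar-contact detection sees the ligand.
_LIGAND_BEADS = [
    ("ADE", "N", np.array([7.0, -7.0, 1.5])),
    ("RIB", "O", np.array([8.8, -6.3, 0.9])),
    ("PA", "O", np.array([10.6, -5.6, 0.3])),
    ("PB", "O", np.array([12.4, -4.9, -0.3])),
]

# Ligand H-bond anchors: (residue, tip atom, ligand bead, tip-bead distance).
_LIGAND_CONTACTS = [
    (135, "OH", "ADE", 2.9),
    (127, "ND2", "ADE", 2.9),
    (181, "OG", "PA", 2.9),
    (185, "NZ", "PA", 2.9),
    (186, "OG1", "PB", 2.9),
]

# Salt-bridge pairs encoded in the canonical pose: (basic, acidic, tip-tip
# distance).  These mirror the networks characterized on the crystal
# structures: the 131-187 nucleotide groove, the 238-459 switch bridge and
# the 232-centered hub with the P-loop (180) and the SH2-helix (674).
_SALT_BRIDGES = [
    (131, 187, 3.0),
    (238, 459, 3.0),
    (232, 180, 3.0),
    (232, 674, 3.3),
]


def make_toy_motor(spec: ToyMotorSpec) -> Structure:
    """Build the toy motor for ``spec``.

    Marker-pair distances match the spec exactly; the converter group is
    rotated by ``spec.converter_angle`` about the x axis through its own
    centroid (so any rotation stays clash-free).  Raises ``ValueError``
    for infeasible geometry (overlapping groups).
    """
    rng = np.random.default_rng(spec.seed)
    numbers = _base_residue_numbers(spec.n_residues)
    ca = _ca_positions(spec, numbers)
    shift = np.asarray(spec.ploop_shift, dtype=float)
    if np.any(shift != 0):
        for n in range(179, 188):
            if n in ca:
                ca[n] = ca[n] + shift

    # seeded jitter on filler residues only; named residues, markers and
    # the converter stay exact so metric round-trips are 1e-6-tight
    protected = set(_NAMED_RESIDUES) | {n for n in numbers if n >= 690}
    for n in numbers:
        jitter = rng.normal(0.0, 0.05, size=3)
        if n not in protected:
            ca[n] = ca[n] + jitter

    # side-chain tips: salt bridges first, then ligand anchors
    tips: dict[int, dict[str, np.ndarray]] = {n: {} for n in numbers}
    for basic, acidic, d in _SALT_BRIDGES:
        rb, ra = _NAMED_RESIDUES[basic], _NAMED_RESIDUES[acidic]
        tip_b, tip_a = _tip_pair(ca[basic], ca[acidic], rb, ra, d)
        names_b, names_a = _TIP_ATOMS[rb], _TIP_ATOMS[ra]
        free_b = [x for x in names_b if x not in tips[basic]]
        free_a = [x for x in names_a if x not in tips[acidic]]
        if not free_b or not free_a:
            continue
        tips[basic][free_b[0]] = tip_b
        tips[acidic][free_a[0]] = tip_a

    bead_pos = {name: p.copy() for name, _, p in _LIGAND_BEADS}
    if spec.with_ligand:
        for res, tip_name, bead, d in _LIGAND_CONTACTS:
            if res in ca and tip_name not in tips[res]:
                tips[res][tip_name] = bead_pos[bead] + d * _unit(
                    ca[res] - bead_pos[bead]
                )

    # converter rotation about the x axis through the group centroid
    conv = [n for n in numbers if n >= 690]
    centroid = np.mean([ca[n] for n in conv], axis=0)
    R = _rotation_about_axis(np.array([1.0, 0.0, 0.0]), spec.converter_angle)

    def place(n: int, xyz: np.ndarray) -> np.ndarray:
        if n in conv:
            return centroid + R @ (xyz - centroid)
        return xyz

    atoms: list[Atom] = []
    for n in numbers:
        res_name = _NAMED_RESIDUES.get(n, "ALA")
        for atom_name in ("N", "CA", "C", "O"):
            xyz = ca[n] if atom_name == "CA" else ca[n] + _BACKBONE_OFFSETS[atom_name]
            atoms.append(
                Atom(
                    chain_id="A",
                    res_seq=n,
                    icode="",
                    res_name=res_name,
                    atom_name=atom_name,
                    element="N" if atom_name == "N" else ("O" if atom_name == "O" else "C"),
                    coords=place(n, xyz),
                )
            )
        for tip_name, xyz in sorted(tips[n].items()):
            atoms.append(
                Atom(
                    chain_id="A",
                    res_seq=n,
                    icode="",
                    res_name=res_name,
                    atom_name=tip_name,
                    element="N" if tip_name.startswith("N") else "O",
                    coords=place(n, xyz),
                )
            )
    if spec.with_ligand:
        for bead_name, element, _ in _LIGAND_BEADS:
            atoms.append(
                Atom(
                    chain_id="A",
                    res_seq=900,
                    icode="",
                    res_name="ADP",
                    atom_name=bead_name,
                    element=element,
                    coords=bead_pos[bead_name],
                    het=True,
                )
            )

    structure = Structure(atoms, id=f"toy-motor-{spec.inner_cleft}-{spec.outer_cleft}-{spec.converter_angle}")
    _check_feasible(structure)
    return structure


def _check_feasible(structure: Structure, min_sep: float = 1.2) -> None:
    """Reject geometries where distinct groups collide (e.g. a cleft so
    narrow that the L50 markers sit inside the U50 block)."""
    from scipy.spatial import cKDTree

    ca = [(a.res_seq, a.coords) for a in structure if a.atom_name == "CA"]
    coords = np.stack([c for _, c in ca])
    groups = [_group_of(n) for n, _ in ca]
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(r=min_sep):
        if groups[i] != groups[j]:
            raise ValueError(
                "infeasible toy-motor geometry: groups "
                f"{groups[i]}/{groups[j]} overlap at residues "
                f"{ca[i][0]}/{ca[j][0]}"
            )


# ---------------------------------------------------------------------------
# Trajectories and binding curves
# ---------------------------------------------------------------------------


def make_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Linear interpolation start -> end with seeded Gaussian thermal noise."""
    start_keys = [a.key for a in spec.start]
    end_keys = [a.key for a in spec.end]
    if start_keys != end_keys:
        raise ValueError("start and end structures have different atom lists")
    x0 = spec.start.coord_array()
    x1 = spec.end.coord_array()
    rng = np.random.default_rng(spec.seed)
    fracs = np.linspace(0.0, 1.0, spec.n_frames)
    coords = x0[None] + fracs[:, None, None] * (x1 - x0)[None]
    if spec.thermal_sigma > 0:
        coords = coords + rng.normal(0.0, spec.thermal_sigma, size=coords.shape)
    times = spec.dt_ps * np.arange(spec.n_frames)
    return Trajectory(template=spec.start, coords=coords, times_ps=times)


def hill_signal(conc: np.ndarray, kd: float, n: float) -> np.ndarray:
    """Noiseless normalized Hill isotherm c^n / (kd^n + c^n)."""
    c = np.asarray(conc, dtype=float)
    return c**n / (kd**n + c**n)


def make_binding_curve(spec: BindingCurveSpec) -> DoseResponse:
    """Geometric dilution series with Hill-model signal plus seeded
    additive Gaussian noise (sigma expressed as fraction of the 0-1
    normalized signal range)."""
    rng = np.random.default_rng(spec.seed)
    conc = spec.top_conc / spec.dilution_factor ** np.arange(spec.n_points)
    signal = hill_signal(conc, spec.kd_true, spec.hill_n)
    if spec.noise_sigma > 0:
        signal = signal + rng.normal(0.0, spec.noise_sigma, size=signal.shape)
    signal = np.clip(signal, -1e6, 1e6)
    return DoseResponse(conc_uM=conc, signal=signal, condition=spec.condition)
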