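"""Characteristic structural-element metrics of the myosin motor domain.

These are the observables used throughout the structural literature to
assign a motor-domain structure to a state of the actomyosin cycle:

* actin-binding cleft width, measured as two Ca-Ca marker distances
  (inner cleft Ser272-Ser465, outer cleft Ser416-Lys589);
* converter rotation, as the axis-angle magnitude of the least-squares
  rotation of the converter after superposing on the N-terminal core;
* P-loop displacement (mean Ca shift of residues 179-186 after core
  superposition);
* global Ca RMSD against a reference structure.

A structure is classified along the pre-power-stroke -> ADP-release ->
rigor-like axis by nearest landmark in normalized metric space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import (
    AtomSelection,
    Structure,
    pair_atoms,
)

__all__ = [
    "StateMetrics",
    "LandmarkSet",
    "StateCall",
    "DEFAULT_LANDMARKS",
    "CORE_SELECTION",
    "CONVERTER_SELECTION",
    "PLOOP_RESIDUES",
    "cleft_distances",
    "superpose",
    "domain_rotation_angle",
    "ploop_displacement",
    "classify_state",
    "compute_state_metrics",
]

# Default region definitions (Dd myosin-II author numbering).  The angle
# procedure is the standard core/domain decomposition; both selections
# are overridable because different labs use slightly different cores.
CORE_SELECTION = AtomSelection(residue_ranges=((2, 80),), atom_names=frozenset({"CA"}))
CONVERTER_SELECTION = AtomSelection(
    residue_ranges=((690, 750),), atom_names=frozenset({"CA"})
)
PLOOP_RESIDUES = (179, 186)

# Marker residue pairs for the actin-binding cleft.
INNER_CLEFT_PAIR = (272, 465)
OUTER_CLEFT_PAIR = (416, 589)


@dataclass
class StateMetrics:
    """Metric vector for one structure (distances in Angstrom, angles in
    degrees).  Unmeasured entries are None."""

    inner_cleft: float | None = None
    outer_cleft: float | None = None
    converter_rotation_vs_pps: float | None = None
    converter_rotation_vs_rigor: float | None = None
    ploop_shift: float | None = None
    global_rmsd_vs_reference: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass
class StateCall:
    label: str
    distance_to_each_landmark: dict[str, float]


@dataclass
class LandmarkSet:
    """Per-state reference metric vectors plus per-metric normalization
    scales.  State order fixes deterministic tie-breaking."""

    landmarks: dict[str, dict[str, float]]
    scales: dict[str, float]
    state_order: tuple[str, ...]

    def __post_init__(self) -> None:
        metric_sets = [set(v) for v in self.landmarks.values()]
        if metric_sets and any(m != metric_sets[0] for m in metric_sets):
            raise ValueError("every landmark must supply every metric")
        if any(s <= 0 for s in self.scales.values()):
            raise ValueError("normalization scales must be positive")
        missing = [s for s in self.state_order if s not in self.landmarks]
        if missing:
            raise ValueError(f"state_order names unknown landmarks: {missing}")


# Landmarks from the printed metrics of the three reference conformations:
# cleft widths of the pre-power-stroke structure (12.6/13.4), the apo
# rigor-like structure (10.7/10.2) and the ADP-release conformation
# (11.7/11.3); converter rotation away from the pre-power-stroke up
# position (~55 deg for ADP-release, ~60 deg for rigor).  Scales put the
# ~1 A cleft steps and ~5 deg rotation steps on comparable footing.
DEFAULT_LANDMARKS = LandmarkSet(
    landmarks={
        "pre-power-stroke": {
            "inner_cleft": 12.6,
            "outer_cleft": 13.4,
            "converter_rotation_vs_pps": 0.0,
        },
        "ADP-release": {
            "inner_cleft": 11.7,
            "outer_cleft": 11.3,
            "converter_rotation_vs_pps": 55.0,
        },
        "rigor-like": {
            "inner_cleft": 10.7,
            "outer_cleft": 10.2,
            "converter_rotation_vs_pps": 60.0,
        },
    },
    scales={
        "inner_cleft": 1.0,
        "outer_cleft": 1.0,
        "converter_rotation_vs_pps": 10.0,
    },
    state_order=("pre-power-stroke", "ADP-release", "rigor-like"),
)


def _marker_ca(structure: Structure, chain: str, res_seq: int) -> np.ndarray:
    atom = structure.find_atom(chain, res_seq, "CA")
    if atom is None:
        raise ValueError(
            f"{structure.id!r} chain {chain}: missing Ca for marker residue {res_seq}"
        )
    return atom.coords


def cleft_distances(structure: Structure, chain: str = "A") -> tuple[float, float]:
    """Inner and outer actin-binding-cleft widths (Angstrom): Ca272-Ca465
    and Ca416-Ca589."""
    inner = np.linalg.norm(
        _marker_ca(structure, chain, INNER_CLEFT_PAIR[0])
        - _marker_ca(structure, chain, INNER_CLEFT_PAIR[1])
    )
    outer = np.linalg.norm(
        _marker_ca(structure, chain, OUTER_CLEFT_PAIR[0])
        - _marker_ca(structure, chain, OUTER_CLEFT_PAIR[1])
    )
    return float(inner), float(outer)


def _kabsch(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of point set ``x`` onto ``y``.

    Returns (R, t, rmsd) with R a proper rotation and x' = x @ R.T + t.
    """
    if len(x) < 3:
        raise ValueError("need at least 3 paired atoms for superposition")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # degenerate (collinear) selections leave a rotation dof undetermined
    if np.linalg.matrix_rank(xc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection; superposition ill-posed")
    rot, rssd = Rotation.align_vectors(yc, xc)
    R = rot.as_matrix()
    t = y.mean(axis=0) - x.mean(axis=0) @ R.T
    rmsd = float(rssd) / np.sqrt(len(x))
    return R, t, rmsd


def superpose(
    mobile: Structure,
    reference: Structure,
    sel: AtomSelection | None = None,
    match_chain: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch superposition of ``mobile`` onto ``reference`` over the
    atoms paired by (chain, residue, atom name) within ``sel``.

    ``match_chain=False`` pairs by residue number and atom name only,
    for comparisons between depositions that use different chain ids.
    Returns (rotation 3x3 with det +1, translation 3-vector, rmsd in
    Angstrom); the transform maps mobile coordinates as x @ R.T + t.
    """
    x, y = pair_atoms(mobile, reference, sel, match_chain=match_chain)
    return _kabsch(x, y)


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


def domain_rotation_angle(
    target: Structure,
    reference: Structure,
    core_sel: AtomSelection = CORE_SELECTION,
    domain_sel: AtomSelection = CONVERTER_SELECTION,
    match_chain: bool = True,
) -> float:
    """Rotation (degrees, in [0, 180]) of ``domain_sel`` between the two
    structures after superposing on ``core_sel``.

    Standard core/domain decomposition: fit the core, then take the
    axis-angle magnitude of the residual least-squares rotation carrying
    the reference domain onto the target domain.
    """
    xc, yc = pair_atoms(target, reference, core_sel, match_chain=match_chain)
    R_core, t_core, _ = _kabsch(xc, yc)
    xd, yd = pair_atoms(target, reference, domain_sel, match_chain=match_chain)
    xd = apply_transform(xd, R_core, t_core)  # target, in the reference core frame
    R_dom, _, _ = _kabsch(yd, xd)
    angle = np.rad2deg(np.linalg.norm(Rotation.from_matrix(R_dom).as_rotvec()))
    return float(angle)


def ploop_displacement(
    target: Structure,
    reference: Structure,
    core_sel: AtomSelection = CORE_SELECTION,
    ploop_residues: tuple[int, int] = PLOOP_RESIDUES,
    match_chain: bool = True,
) -> float:
    """Mean Ca displacement (Angstrom) of the P-loop after superposing
    the structures on the core selection."""
    xc, yc = pair_atoms(target, reference, core_sel, match_chain=match_chain)
    R, t, _ = _kabsch(xc, yc)
    sel = AtomSelection(residue_ranges=(ploop_residues,), atom_names=frozenset({"CA"}))
    try:
        xp, yp = pair_atoms(target, reference, sel, match_chain=match_chain)
    except ValueError as err:
        raise ValueError(
            f"P-loop residues {ploop_residues} not paired between structures"
        ) from err
    xp = apply_transform(xp, R, t)
    return float(np.mean(np.linalg.norm(xp - yp, axis=1)))


def classify_state(
    metrics: StateMetrics | dict[str, float],
    landmarks: LandmarkSet = DEFAULT_LANDMARKS,
) -> StateCall:
    """Nearest landmark in per-metric-normalized Euclidean distance;
    deterministic tie-break by the landmark set's fixed state order."""
    values = metrics.as_dict() if isinstance(metrics, StateMetrics) else dict(metrics)
    needed = set(next(iter(landmarks.landmarks.values())))
    missing = sorted(needed - set(values))
    if missing:
        raise ValueError(f"metrics missing required entries: {missing}")
    distances: dict[str, float] = {}
    for state in landmarks.state_order:
        ref = landmarks.landmarks[state]
        d = sum(
            ((values[m] - ref[m]) / landmarks.scales[m]) ** 2 for m in needed
        )
        distances[state] = float(np.sqrt(d))
    best = min(landmarks.state_order, key=lambda s: (distances[s],))
    return StateCall(label=best, distance_to_each_landmark=distances)


def compute_state_metrics(
    structure: Structure,
    chain: str = "A",
    reference_pps: Structure | None = None,
    reference_rigor: Structure | None = None,
    core_sel: AtomSelection = CORE_SELECTION,
    converter_sel: AtomSelection = CONVERTER_SELECTION,
) -> StateMetrics:
    """Measure every available metric for one structure; rotation and
    displacement metrics require the corresponding reference."""
    inner, outer = cleft_distances(structure, chain=chain)
    m = StateMetrics(inner_cleft=inner, outer_cleft=outer)
    if reference_pps is not None:
        m.converter_rotation_vs_pps = domain_rotation_angle(
            structure, reference_pps, core_sel, converter_sel
        )
        m.ploop_shift = ploop_displacement(structure, reference_pps, core_sel)
        _, _, m.global_rmsd_vs_reference = superpose(
            structure,
            reference_pps,
            AtomSelection(atom_names=frozenset({"CA"})),
        )
    if reference_rigor is not None:
        m.converter_rotation_vs_rigor = domain_rotation_angle(
            structure, reference_rigor, core_sel, converter_sel
        )
    return m
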