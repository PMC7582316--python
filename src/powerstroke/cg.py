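"""Coarse-grained Langevin dynamics with TMD and SMD biasing.

The protein is a Ca-bead elastic network: one bead per residue, stiff
virtual bonds between chain neighbours, and harmonic contacts between all
bead pairs (|i-j| >= 3) within a cutoff at their build-time separations.
An optional ligand (one bead per ADP moiety: adenine, ribose, alpha- and
beta-phosphate) is coupled to nearby protein beads by native-contact
springs that can be flagged breakable for unbinding runs.

Two biasing potentials drive conformational transitions:

* targeted MD (TMD): a harmonic penalty on the gap between the current
  best-fit RMSD to a target and a scheduled reference RMSD*,

      V = (k / 2N) * [RMSD(t) - RMSD*(t)]^2

  with the superposition recomputed at every evaluation.  The gradient is
  taken at the per-step optimal superposition; because the fit parameters
  are stationary at the optimum this equals the full best-fit gradient.

* steered MD (SMD): a harmonic spring between the pulled group's centre
  of mass, projected on a unit reaction coordinate, and a reference point
  moving at constant velocity, V = k/2 (v t - s)^2.  The spring force is
  the recorded pulling force (reported in pN).

Internal units: kcal/mol, Angstrom, amu, ps.  Integration uses the BAOAB
splitting of Langevin dynamics, which reduces to velocity Verlet at zero
friction and is seeded/bitwise-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure import AtomSelection, Structure, WATER_NAMES, selection_indices
from .trajectory import Trajectory

__all__ = [
    "CGModel",
    "TMDBias",
    "SMDBias",
    "LinearSchedule",
    "ForceProfile",
    "KB_KCAL",
    "KCAL_PER_A_TO_PN",
    "build_cg_model",
    "tmd_energy_and_forces",
    "smd_energy_and_forces",
    "best_fit_rmsd",
    "run_dynamics",
    "run_release_experiment",
]

#: Boltzmann constant, kcal mol^-1 K^-1.
KB_KCAL = 0.0019872041
#: 1 kcal mol^-1 A^-1 in pN.
KCAL_PER_A_TO_PN = 69.48
#: Acceleration conversion: (kcal/mol/A)/amu -> A/ps^2.
ACC_CONV = 418.4
#: Default bead mass (average residue mass, amu).
BEAD_MASS = 110.0

#: Masses of the four ADP coarse groups (adenine, ribose, a-P, b-P), amu.
LIGAND_BEAD_MASS = {"ADE": 134.0, "RIB": 116.0, "PA": 79.0, "PB": 79.0}


@dataclass
class CGModel:
    """Elastic-network bead model.

    ``springs`` rows are (i, j, r0, k); ``breakable`` marks ligand
    native contacts that detach permanently once stretched past
    ``r0 + break_ext`` (used by unbinding simulations).
    """

    coords: np.ndarray
    masses: np.ndarray
    spring_ij: np.ndarray          # (n_springs, 2) int
    spring_r0: np.ndarray
    spring_k: np.ndarray
    breakable: np.ndarray          # bool per spring
    break_ext: np.ndarray          # per-spring rupture extension (A)
    bead_res_seq: np.ndarray
    bead_res_name: list[str]
    bead_name: list[str]
    is_ligand: np.ndarray          # bool per bead
    template: Structure            # one atom per bead, for frame export
    broken: np.ndarray = field(default=None)  # set by the integrator

    def __post_init__(self) -> None:
        if self.broken is None:
            self.broken = np.zeros(len(self.spring_r0), dtype=bool)
        self.break_ext = np.broadcast_to(
            np.asarray(self.break_ext, dtype=float), self.spring_r0.shape
        ).copy()

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    def ligand_indices(self) -> np.ndarray:
        return np.nonzero(self.is_ligand)[0]

    def protein_indices(self) -> np.ndarray:
        return np.nonzero(~self.is_ligand)[0]

    def reset_contacts(self) -> "CGModel":
        return replace(self, broken=np.zeros(len(self.spring_r0), dtype=bool))

    def spring_energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Potential energy and forces of all (unbroken) springs."""
        i, j = self.spring_ij[:, 0], self.spring_ij[:, 1]
        d = coords[i] - coords[j]
        r = np.linalg.norm(d, axis=1)
        active = ~self.broken
        dr = np.where(active, r - self.spring_r0, 0.0)
        energy = float(np.sum(0.5 * self.spring_k * dr**2))
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(r[:, None] > 1e-12, d / r[:, None], 0.0)
        f_pair = -(self.spring_k * dr)[:, None] * u
        forces = np.zeros_like(coords)
        np.add.at(forces, i, f_pair)
        np.add.at(forces, j, -f_pair)
        return energy, forces

    def update_broken(self, coords: np.ndarray) -> np.ndarray:
        """Permanently break breakable springs stretched past the break
        extension; returns indices of springs broken by this call."""
        i, j = self.spring_ij[:, 0], self.spring_ij[:, 1]
        r = np.linalg.norm(coords[i] - coords[j], axis=1)
        newly = self.breakable & ~self.broken & (r > self.spring_r0 + self.break_ext)
        self.broken = self.broken | newly
        return np.nonzero(newly)[0]


def build_cg_model(
    structure: Structure,
    contact_cutoff: float = 10.0,
    spring_k: float = 1.0,
    bond_k: float = 50.0,
    bond_seq_gap: int = 3,
    ligand_cutoff: float = 5.0,
    ligand_k: float = 2.0,
    ligand_bond_k: float = 20.0,
    break_ext: float = 1.5,
    ligand_contact_k: dict[int, float] | None = None,
    ligand_contact_ext: dict[int, float] | None = None,
    ligand_breakable: bool = True,
    stiff_ranges: Sequence[tuple[int, int]] = (),
    stiff_factor: float = 25.0,
) -> CGModel:
    """Build the elastic network from a structure.

    Protein beads sit on Ca atoms; chain neighbours get stiff bonds and
    all pairs with |i-j| >= ``bond_seq_gap`` within ``contact_cutoff``
    get network springs at their current separation.  HETATM groups named
    ADP become ligand beads, chained together and coupled to protein
    beads within ``ligand_cutoff``.  ``ligand_contact_k`` overrides the
    native-contact stiffness per protein residue number and
    ``ligand_contact_ext`` the rupture extension (together they encode
    which anchors resist unbinding longest).  ``stiff_ranges`` lists
    residue ranges that together form a rigid, well-anchored cluster:
    network springs with both beads inside the union of the ranges get
    k * ``stiff_factor`` (e.g. the compact converter domain and the core
    it docks against).
    """
    ca = [
        a
        for a in structure
        if a.atom_name == "CA"
        and not a.het
        and a.res_name not in WATER_NAMES
        and a.altloc in ("", "A")
    ]
    if not ca:
        raise ValueError("structure has no protein Ca atoms")
    residues_seen = {}
    for a in structure:
        if not a.het and a.res_name not in WATER_NAMES:
            residues_seen.setdefault(a.residue_id, False)
    for a in ca:
        residues_seen[a.residue_id] = True
    missing = [rid for rid, ok in residues_seen.items() if not ok]
    if missing:
        raise ValueError(f"protein residues missing Ca atoms: {missing[:5]}")

    lig = [a for a in structure if a.het and a.res_name == "ADP"]

    beads = ca + lig
    coords = np.stack([a.coords for a in beads])
    n_prot = len(ca)
    masses = np.array(
        [BEAD_MASS] * n_prot
        + [LIGAND_BEAD_MASS.get(a.atom_name, BEAD_MASS) for a in lig]
    )
    is_ligand = np.array([False] * n_prot + [True] * len(lig))

    ij: list[tuple[int, int]] = []
    r0: list[float] = []
    ks: list[float] = []
    brk: list[bool] = []
    exts: list[float] = []

    def add(i: int, j: int, k: float, breakable: bool = False, ext: float | None = None) -> None:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d <= 0:
            raise ValueError(f"coincident beads {i}, {j}")
        ij.append((i, j))
        r0.append(d)
        ks.append(k)
        brk.append(breakable)
        exts.append(break_ext if ext is None else ext)

    # chain bonds between consecutive residues of the same chain
    bonded = set()
    for i in range(n_prot - 1):
        a, b = ca[i], ca[i + 1]
        if a.chain_id == b.chain_id and b.res_seq - a.res_seq == 1:
            add(i, i + 1, bond_k)
            bonded.add((i, i + 1))
    # connectivity check: each chain must form one unbroken run
    for chain_id in {a.chain_id for a in ca}:
        idx = [i for i, a in enumerate(ca) if a.chain_id == chain_id]
        gaps = [
            (ca[i].res_seq, ca[j].res_seq)
            for i, j in zip(idx[:-1], idx[1:])
            if ca[j].res_seq - ca[i].res_seq != 1
        ]
        # non-unit gaps are fine in deposited structures (unresolved
        # loops) as long as the network still connects the pieces; a
        # fully disconnected chain is an input error
        if len(gaps) == len(idx) - 1 and len(idx) > 1:
            raise ValueError(f"chain {chain_id} has no consecutive residues")

    # elastic-network contacts
    def in_stiff_union(i: int) -> bool:
        return any(lo <= ca[i].res_seq <= hi for lo, hi in stiff_ranges)

    tree = cKDTree(coords[:n_prot])
    for i, j in sorted(tree.query_pairs(r=contact_cutoff)):
        if abs(ca[i].res_seq - ca[j].res_seq) >= bond_seq_gap or ca[i].chain_id != ca[j].chain_id:
            k = spring_k * stiff_factor if in_stiff_union(i) and in_stiff_union(j) else spring_k
            add(i, j, k)

    # ligand internal chain and native contacts to the protein
    for a in range(len(lig) - 1):
        add(n_prot + a, n_prot + a + 1, ligand_bond_k)
    if lig:
        ltree = cKDTree(coords[n_prot:])
        for p in range(n_prot):
            for l in ltree.query_ball_point(coords[p], r=ligand_cutoff):
                k = ligand_k
                ext = None
                if ligand_contact_k and ca[p].res_seq in ligand_contact_k:
                    k = ligand_contact_k[ca[p].res_seq]
                if ligand_contact_ext and ca[p].res_seq in ligand_contact_ext:
                    ext = ligand_contact_ext[ca[p].res_seq]
                add(p, n_prot + l, k, breakable=ligand_breakable, ext=ext)

    template = Structure(
        [replace(a, coords=a.coords.copy(), altloc="") for a in beads],
        id=f"cg:{structure.id}",
    )
    return CGModel(
        coords=coords,
        masses=masses,
        spring_ij=np.array(ij, dtype=int).reshape(-1, 2),
        spring_r0=np.array(r0),
        spring_k=np.array(ks),
        breakable=np.array(brk, dtype=bool),
        break_ext=np.array(exts, dtype=float),
        bead_res_seq=np.array([a.res_seq for a in beads]),
        bead_res_name=[a.res_name for a in beads],
        bead_name=[a.atom_name for a in beads],
        is_ligand=is_ligand,
        template=template,
    )


# ---------------------------------------------------------------------------
# Biases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearSchedule:
    """RMSD*(t) decreasing linearly from ``rmsd_start`` to ``rmsd_end``
    over ``duration_ps``, constant afterwards."""

    rmsd_start: float
    rmsd_end: float
    duration_ps: float

    def __call__(self, t_ps: float) -> float:
        if self.duration_ps <= 0:
            return self.rmsd_end
        f = min(max(t_ps / self.duration_ps, 0.0), 1.0)
        return self.rmsd_start + f * (self.rmsd_end - self.rmsd_start)


@dataclass
class TMDBias:
    """Harmonic bias on the best-fit RMSD of ``atom_indices`` to
    ``target_coords``; k in kcal mol^-1 A^-2, divided by the number of
    biased atoms N."""

    atom_indices: np.ndarray
    target_coords: np.ndarray
    k: float
    schedule: Callable[[float], float]

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.target_coords = np.asarray(self.target_coords, dtype=float)
        if self.k <= 0:
            raise ValueError("TMD force constant must be positive")
        if len(self.atom_indices) < 3:
            raise ValueError("TMD needs at least 3 biased atoms")
        if self.target_coords.shape != (len(self.atom_indices), 3):
            raise ValueError("target coords must pair with the biased atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)


@dataclass
class SMDBias:
    """Constant-velocity pulling of the centre of mass of
    ``atom_indices`` along the unit vector ``direction``."""

    atom_indices: np.ndarray
    direction: np.ndarray
    anchor: np.ndarray
    k: float = 4.0                 # kcal mol^-1 A^-2
    velocity: float = 0.005        # A ps^-1

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.direction = np.asarray(self.direction, dtype=float)
        self.anchor = np.asarray(self.anchor, dtype=float)
        if self.atom_indices.size == 0:
            raise ValueError("empty pulled selection")
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-8:
            if n == 0:
                raise ValueError("pulling direction must be a unit vector")
            self.direction = self.direction / n
        if self.k <= 0 or self.velocity <= 0:
            raise ValueError("k and velocity must be positive")


def best_fit_rmsd(
    coords: np.ndarray, target: np.ndarray
) -> tuple[float, np.ndarray]:
    """Best-fit (superposed) RMSD of ``coords`` onto ``target`` and the
    target aligned into the coordinate frame of ``coords``."""
    xc = coords - coords.mean(axis=0)
    yc = target - target.mean(axis=0)
    rot, _ = Rotation.align_vectors(xc, yc)
    aligned = yc @ rot.as_matrix().T + coords.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((coords - aligned) ** 2, axis=1))))
    return rmsd, aligned


def tmd_energy_and_forces(
    coords: np.ndarray, bias: TMDBias, t_ps: float
) -> tuple[float, np.ndarray]:
    """V = (k/2N) [RMSD(t) - RMSD*(t)]^2 and its negative gradient.

    The superposition of the target onto the current biased atoms is
    recomputed at every call; the gradient is evaluated at that optimum,
    where d(RMSD)/dx_i = (x_i - y_i) / (N * RMSD).
    """
    idx = bias.atom_indices
    n = bias.n_atoms
    rmsd, aligned = best_fit_rmsd(coords[idx], bias.target_coords)
    gap = rmsd - float(bias.schedule(t_ps))
    energy = 0.5 * bias.k / n * gap**2
    forces = np.zeros_like(coords)
    if rmsd > 1e-10:
        # dV/dx = (k/N) * gap * dRMSD/dx
        grad_coeff = bias.k / n * gap / (n * rmsd)
        forces[idx] = -grad_coeff * (coords[idx] - aligned)
    return float(energy), forces


def smd_energy_and_forces(
    coords: np.ndarray,
    bias: SMDBias,
    t_ps: float,
    masses: np.ndarray,
) -> tuple[float, np.ndarray, float]:
    """Pulling-spring energy, per-bead forces (mass-weighted over the
    pulled group) and the signed applied force in pN."""
    idx = bias.atom_indices
    m = masses[idx]
    com = np.sum(coords[idx] * m[:, None], axis=0) / np.sum(m)
    s = float(np.dot(com - bias.anchor, bias.direction))
    gap = bias.velocity * t_ps - s
    energy = 0.5 * bias.k * gap**2
    f_scalar = bias.k * gap  # dV/ds with opposite sign: force along xi
    forces = np.zeros_like(coords)
    forces[idx] = f_scalar * bias.direction[None, :] * (m / np.sum(m))[:, None]
    return float(energy), forces, f_scalar * KCAL_PER_A_TO_PN


@dataclass
class PositionalRestraint:
    """Harmonic tether of selected beads to reference positions."""

    atom_indices: np.ndarray
    reference: np.ndarray
    k: float = 10.0

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        idx = np.asarray(self.atom_indices, dtype=int)
        d = coords[idx] - self.reference
        energy = float(0.5 * self.k * np.sum(d**2))
        forces = np.zeros_like(coords)
        forces[idx] = -self.k * d
        return energy, forces


# ---------------------------------------------------------------------------
# Integrator
# ---------------------------------------------------------------------------


def _total_forces(
    model: CGModel,
    coords: np.ndarray,
    biases: Sequence,
    restraints: Sequence[PositionalRestraint],
    t_ps: float,
) -> tuple[float, np.ndarray, dict]:
    energy, forces = model.spring_energy_forces(coords)
    record: dict = {}
    for b, bias in enumerate(biases):
        if isinstance(bias, TMDBias):
            e, f = tmd_energy_and_forces(coords, bias, t_ps)
            idx = bias.atom_indices
            rmsd, _ = best_fit_rmsd(coords[idx], bias.target_coords)
            record[f"tmd{b}_energy"] = e
            record[f"tmd{b}_rmsd"] = rmsd
            record[f"tmd{b}_rmsd_star"] = float(bias.schedule(t_ps))
        elif isinstance(bias, SMDBias):
            e, f, f_pn = smd_energy_and_forces(coords, bias, t_ps, model.masses)
            idx = bias.atom_indices
            m = model.masses[idx]
            com = np.sum(coords[idx] * m[:, None], axis=0) / np.sum(m)
            record[f"smd{b}_energy"] = e
            record[f"smd{b}_force_pN"] = f_pn
            record[f"smd{b}_s_A"] = float(np.dot(com - bias.anchor, bias.direction))
        else:
            raise TypeError(f"unknown bias type {type(bias)!r}")
        energy += e
        forces += f
    for r in restraints:
        e, f = r.energy_forces(coords)
        energy += e
        forces += f
    return energy, forces, record


def run_dynamics(
    model: CGModel,
    biases: Sequence = (),
    n_steps: int = 1000,
    dt_fs: float = 2.0,
    temperature: float = 310.0,
    friction_ps: float = 1.0,
    seed: int = 0,
    restraints: Sequence[PositionalRestraint] = (),
    record_every: int = 10,
    energy_abort: float = 1e8,
    start_coords: np.ndarray | None = None,
    t0_ps: float = 0.0,
) -> Trajectory:
    """BAOAB Langevin dynamics.

    Zero friction and zero temperature reduce the scheme to velocity
    Verlet (energy-conserving).  The run is a pure function of its
    arguments (seeded Gaussian noise), so trajectories are reproducible
    bitwise.  Raises on numeric blow-up with a stage diagnostic.

    dt stability: the stiffest default spring (chain bonds, 50
    kcal mol^-1 A^-2 on 110 amu beads) has period ~2pi/sqrt(k*418.4/m)
    ~ 0.45 ps, so the default 2 fs step is ~1/230 of a period.
    """
    coords = np.array(model.coords if start_coords is None else start_coords, dtype=float)
    rng = np.random.default_rng(seed)
    dt = dt_fs * 1e-3  # ps
    m = model.masses[:, None]
    vel = np.zeros_like(coords)
    if temperature > 0:
        sigma_v = np.sqrt(KB_KCAL * temperature * ACC_CONV / model.masses)
        vel = rng.normal(size=coords.shape) * sigma_v[:, None]

    gamma = friction_ps
    if gamma > 0:
        c1 = np.exp(-gamma * dt)
    else:
        c1 = 1.0
    c2 = np.sqrt((1.0 - c1**2) * KB_KCAL * max(temperature, 0.0) * ACC_CONV / model.masses)

    frames = [coords.copy()]
    times = [t0_ps]
    energy, forces, rec = _total_forces(model, coords, biases, restraints, t0_ps)
    rec["potential_kcal"] = energy
    rec["kinetic_kcal"] = float(0.5 * np.sum(m * vel**2) / ACC_CONV)
    rec["ruptures"] = []
    records = [rec]

    pending_ruptures: list[tuple[float, int, int]] = []
    for step in range(1, n_steps + 1):
        t = t0_ps + step * dt
        # B: half kick
        vel = vel + 0.5 * dt * forces / m * ACC_CONV
        # A: half drift
        coords = coords + 0.5 * dt * vel
        # O: Ornstein-Uhlenbeck
        if gamma > 0:
            vel = c1 * vel + c2[:, None] * rng.normal(size=vel.shape)
        # A: half drift
        coords = coords + 0.5 * dt * vel
        # rupture bookkeeping before the closing force evaluation
        for s in model.update_broken(coords):
            pending_ruptures.append(
                (t, int(model.spring_ij[s, 0]), int(model.spring_ij[s, 1]))
            )
        # B: half kick with fresh forces
        energy, forces, rec = _total_forces(model, coords, biases, restraints, t)
        vel = vel + 0.5 * dt * forces / m * ACC_CONV
        if not np.isfinite(energy) or energy > energy_abort:
            raise FloatingPointError(
                f"dynamics blew up at step {step} (t={t:.3f} ps): "
                f"potential {energy:.3g} kcal/mol; reduce dt or spring k"
            )
        if step % record_every == 0 or step == n_steps:
            rec["potential_kcal"] = energy
            rec["kinetic_kcal"] = float(0.5 * np.sum(m * vel**2) / ACC_CONV)
            rec["ruptures"] = [(rt, i, j) for rt, i, j in pending_ruptures]
            pending_ruptures.clear()
            frames.append(coords.copy())
            times.append(t)
            records.append(rec)

    return Trajectory(
        template=model.template,
        coords=np.stack(frames),
        times_ps=np.array(times),
        records=records,
    )


# ---------------------------------------------------------------------------
# Release experiment
# ---------------------------------------------------------------------------


@dataclass
class ForceProfile:
    """Pulling-force record of one SMD run."""

    vector: np.ndarray
    replicate: int
    times_ps: np.ndarray
    force_pN: np.ndarray
    displacement_A: np.ndarray
    peak_force_pN: float
    ruptures: list[tuple[float, int, str]]  # (t_ps, res_seq, res_name)
    #: residues whose native contacts never broke during the pull (the
    #: anchors that outlast the run entirely)
    unbroken_residues: list[int] = field(default_factory=list)

    @property
    def last_broken(self) -> list[tuple[int, str]]:
        """Residues of the latest-breaking ligand contacts."""
        if not self.ruptures:
            return []
        t_last = max(t for t, _, _ in self.ruptures)
        return [(rs, rn) for t, rs, rn in self.ruptures if t >= t_last - 1e-9]

    def tail_residues(self, n_events: int = 4) -> list[int]:
        """Residue numbers of the last ``n_events`` rupture events."""
        return [rs for _, rs, _ in sorted(self.ruptures)[-n_events:]]

    def persistent_anchors(self, n_events: int = 4) -> set[int]:
        """Residues whose contacts outlast all others: the last rupture
        events plus any contacts never broken during the pull."""
        return set(self.tail_residues(n_events)) | set(self.unbroken_residues)

    def work_kcal(self) -> float:
        """Integral of the pulling force over COM displacement."""
        f_kcal = self.force_pN / KCAL_PER_A_TO_PN
        return float(np.trapezoid(f_kcal, self.displacement_A))


def run_release_experiment(
    model: CGModel,
    vectors: Sequence[np.ndarray],
    replicates: int = 2,
    seed: int = 0,
    smd_k: float = 4.0,
    smd_velocity: float = 0.005,
    n_steps: int = 20000,
    dt_fs: float = 2.0,
    temperature: float = 310.0,
    friction_ps: float = 1.0,
    record_every: int = 10,
    restraints: Sequence[PositionalRestraint] = (),
) -> list[ForceProfile]:
    """Pull the ligand COM along each release vector (x replicates),
    recording force profiles and the residues whose native contacts break
    (the unbinding order)."""
    lig = model.ligand_indices()
    if lig.size == 0:
        raise ValueError("model has no ligand beads to pull")
    profiles: list[ForceProfile] = []
    for v, vector in enumerate(vectors):
        vector = np.asarray(vector, dtype=float)
        vector = vector / np.linalg.norm(vector)
        for rep in range(replicates):
            run_model = model.reset_contacts()
            m = run_model.masses[lig]
            anchor = np.sum(run_model.coords[lig] * m[:, None], axis=0) / np.sum(m)
            bias = SMDBias(
                atom_indices=lig,
                direction=vector,
                anchor=anchor,
                k=smd_k,
                velocity=smd_velocity,
            )
            traj = run_dynamics(
                run_model,
                biases=[bias],
                n_steps=n_steps,
                dt_fs=dt_fs,
                temperature=temperature,
                friction_ps=friction_ps,
                seed=seed + 1000 * v + rep,
                restraints=restraints,
                record_every=record_every,
            )
            times = traj.times_ps
            force = np.array([r.get("smd0_force_pN", 0.0) for r in traj.records])
            disp = np.array([r.get("smd0_s_A", 0.0) for r in traj.records])
            ruptures: list[tuple[float, int, str]] = []
            for rec in traj.records:
                for rt, i, j in rec.get("ruptures", []):
                    prot = int(i if not run_model.is_ligand[i] else j)
                    ruptures.append(
                        (
                            float(rt),
                            int(run_model.bead_res_seq[prot]),
                            run_model.bead_res_name[prot],
                        )
                    )
            still = run_model.breakable & ~run_model.broken
            unbroken = sorted(
                {
                    int(run_model.bead_res_seq[
                        i if not run_model.is_ligand[i] else j
                    ])
                    for (i, j) in run_model.spring_ij[still]
                }
            )
            profiles.append(
                ForceProfile(
                    vector=vector,
                    replicate=rep,
                    times_ps=times,
                    force_pN=force,
                    displacement_A=disp,
                    peak_force_pN=float(np.max(np.abs(force))),
                    ruptures=ruptures,
                    unbroken_residues=unbroken,
                )
            )
    return profiles
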