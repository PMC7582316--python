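"""End-to-end release-pathway reconstruction on the toy complex.

The driver mirrors the computational protocol used to reconstruct the
second step of the power stroke and ADP release:

1. build a Ca elastic-network model of the ligand-bound start structure;
2. stage-1 TMD: close the actin-binding cleft (bias on the cleft blocks)
   to reach a strong-ADP-like intermediate;
3. stage-2 TMD: rotate the converter toward the down position, biasing
   the converter and the P-loop while the cleft is positionally
   restrained; the nucleotide follows its pocket unbiased;
4. unbiased relaxation;
5. SMD unbinding along four release vectors (in duplicate), recording
   force profiles and the order in which native ligand contacts break;
6. interaction-energy profile over the concatenated pathway with minima
   detection, and state metrics on the start/intermediate/end frames.

Every stage is seeded; the manifest records the resolved configuration,
seeds, and a sha256 checksum per artifact, which makes full-pipeline
determinism directly checkable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cg, energy, metrics
from .structure import AtomSelection
from .synthetic import ToyMotorSpec, make_toy_motor
from .trajectory import Trajectory

__all__ = ["RunConfig", "run_pipeline", "load_config"]

# Named functional regions (author numbering), used for selections.
REGIONS = {
    "ploop": (179, 186),
    "switch1": (232, 238),
    "switch2": (454, 459),
    "purine_loop": (126, 136),
    "inner_cleft_pair": (272, 465),
    "outer_cleft_pair": (416, 589),
}


@dataclass
class RunConfig:
    """Declarative pipeline configuration (flat, YAML-serializable)."""

    out_dir: str = "powerstroke_run"
    seed: int = 1
    # toy-complex geometry: open-cleft start, closed-cleft strong-ADP
    # target, rotated-converter release target with the P-loop shifted
    # toward the front entrance of the active site
    n_residues: int = 100
    start_cleft: tuple[float, float] = (12.6, 13.4)
    closed_cleft: tuple[float, float] = (10.7, 10.2)
    converter_target_deg: float = 55.0
    ploop_shift_target: tuple[float, float, float] = (0.0, -5.0, 4.0)
    # CG model
    contact_cutoff: float = 10.0
    spring_k: float = 1.0
    ligand_contact_k: dict = field(default_factory=lambda: {131: 6.0, 186: 6.0})
    ligand_contact_ext: dict = field(default_factory=lambda: {131: 3.0, 186: 3.0})
    # dynamics
    temperature_K: float = 310.0
    friction_ps: float = 1.0
    dt_fs: float = 2.0
    n_steps_relax0: int = 2000
    n_steps_stage1: int = 4000
    n_steps_stage2: int = 6000
    n_steps_relax: int = 4000
    record_every: int = 10
    # TMD force constant: the all-atom protocol's 200 kcal/mol/A^2 scaled
    # by a x10 CG calibration factor so the bias dominates the soft
    # elastic network the way it dominates the all-atom force field
    tmd_k: float = 2000.0
    restraint_k: float = 10.0
    # selections (residue ranges)
    stage1_ranges: tuple = ((268, 275), (412, 420), (454, 465), (585, 592))
    stage2_ranges: tuple = ((126, 136), (179, 187), (690, 750))
    restrain_ranges: tuple = ((268, 275), (412, 420), (454, 465), (585, 592))
    # SMD release (desk-scale pulling speed; see docs/methods.md)
    smd_k: float = 4.0
    smd_velocity: float = 0.5
    smd_steps: int = 20000
    n_vectors: int = 4
    smd_replicates: int = 2
    smd_restraint_k: float = 5.0
    # rigid subdomains of the CG network (compact folded regions)
    stiff_ranges: tuple = ((690, 750), (2, 13))
    stiff_factor: float = 25.0
    # profile
    profile_window: int = 75
    min_prominence_kJmol: float = 2.0

    def to_yaml(self) -> str:
        d = asdict(self)
        d["ligand_contact_k"] = {int(k): float(v) for k, v in d["ligand_contact_k"].items()}
        d["ligand_contact_ext"] = {int(k): float(v) for k, v in d["ligand_contact_ext"].items()}
        return yaml.safe_dump(json.loads(json.dumps(d)), sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**raw)
    cfg.ligand_contact_k = {int(k): float(v) for k, v in cfg.ligand_contact_k.items()}
    cfg.ligand_contact_ext = {int(k): float(v) for k, v in cfg.ligand_contact_ext.items()}
    for name in ("start_cleft", "closed_cleft", "ploop_shift_target"):
        setattr(cfg, name, tuple(getattr(cfg, name)))
    cfg.stage1_ranges = tuple(tuple(r) for r in cfg.stage1_ranges)
    cfg.stiff_ranges = tuple(tuple(r) for r in cfg.stiff_ranges)
    cfg.stage2_ranges = tuple(tuple(r) for r in cfg.stage2_ranges)
    cfg.restrain_ranges = tuple(tuple(r) for r in cfg.restrain_ranges)
    return cfg


def _bead_indices(model: cg.CGModel, ranges) -> np.ndarray:
    mask = np.zeros(model.n_beads, dtype=bool)
    for lo, hi in ranges:
        mask |= (
            (model.bead_res_seq >= lo)
            & (model.bead_res_seq <= hi)
            & ~model.is_ligand
        )
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError(f"no beads in residue ranges {ranges}")
    return idx


def _target_coords_for(model: cg.CGModel, target, idx: np.ndarray) -> np.ndarray:
    """Target Ca coordinates for the biased beads, looked up by residue."""
    by_res = {}
    for a in target:
        if a.atom_name == "CA":
            by_res[(a.chain_id, a.res_seq)] = a.coords
    out = []
    for i in idx:
        key = (model.template[int(i)].chain_id, int(model.bead_res_seq[i]))
        if key not in by_res:
            raise ValueError(f"target structure lacks Ca for residue {key}")
        out.append(by_res[key])
    return np.stack(out)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _release_vectors(model: cg.CGModel, n: int = 4, cone_deg: float = 25.0) -> list[np.ndarray]:
    """Release directions: a cone of ``n`` unit vectors around the
    outward axis from the protein centre of mass through the ligand."""
    from scipy.spatial.transform import Rotation

    lig, prot = model.ligand_indices(), model.protein_indices()
    u0 = model.coords[lig].mean(axis=0) - model.coords[prot].mean(axis=0)
    u0 = u0 / np.linalg.norm(u0)
    # orthonormal frame around u0
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, u0)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u0, a)
    e1 /= np.linalg.norm(e1)
    vectors = []
    for i in range(n):
        axis = Rotation.from_rotvec(u0 * (2 * np.pi * i / n)).apply(e1)
        v = Rotation.from_rotvec(axis * np.deg2rad(cone_deg)).apply(u0)
        vectors.append(v / np.linalg.norm(v))
    return vectors


def _tmd_stage(
    model: cg.CGModel,
    idx: np.ndarray,
    target_xyz: np.ndarray,
    start_coords: np.ndarray,
    cfg: RunConfig,
    n_steps: int,
    seed: int,
    restraints=(),
    t0_ps: float = 0.0,
) -> Trajectory:
    rmsd0, _ = cg.best_fit_rmsd(start_coords[idx], target_xyz)
    duration = n_steps * cfg.dt_fs * 1e-3
    bias = cg.TMDBias(
        atom_indices=idx,
        target_coords=target_xyz,
        k=cfg.tmd_k,
        schedule=cg.LinearSchedule(rmsd0, 0.0, duration),
    )
    return cg.run_dynamics(
        model,
        biases=[bias],
        n_steps=n_steps,
        dt_fs=cfg.dt_fs,
        temperature=cfg.temperature_K,
        friction_ps=cfg.friction_ps,
        seed=seed,
        restraints=restraints,
        record_every=cfg.record_every,
        start_coords=start_coords,
        t0_ps=t0_ps,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full reconstruction; returns the manifest dict (also
    written to ``out_dir/manifest.json``)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": yaml.safe_load(cfg.to_yaml()),
        "stages": {},
        "artifacts": {},
        "metrics": {},
    }
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                return False

        return _T()

    try:
        with stage("build"):
            start = make_toy_motor(
                ToyMotorSpec(
                    n_residues=cfg.n_residues,
                    inner_cleft=cfg.start_cleft[0],
                    outer_cleft=cfg.start_cleft[1],
                    converter_angle=0.0,
                    seed=cfg.seed,
                    with_ligand=True,
                )
            )
            target_strong = make_toy_motor(
                ToyMotorSpec(
                    n_residues=cfg.n_residues,
                    inner_cleft=cfg.closed_cleft[0],
                    outer_cleft=cfg.closed_cleft[1],
                    converter_angle=0.0,
                    seed=cfg.seed,
                )
            )
            target_release = make_toy_motor(
                ToyMotorSpec(
                    n_residues=cfg.n_residues,
                    inner_cleft=cfg.closed_cleft[0],
                    outer_cleft=cfg.closed_cleft[1],
                    converter_angle=cfg.converter_target_deg,
                    seed=cfg.seed,
                    ploop_shift=tuple(cfg.ploop_shift_target),
                )
            )
            model = cg.build_cg_model(
                start,
                contact_cutoff=cfg.contact_cutoff,
                spring_k=cfg.spring_k,
                ligand_contact_k=cfg.ligand_contact_k,
                ligand_contact_ext=cfg.ligand_contact_ext,
                ligand_breakable=False,
                stiff_ranges=cfg.stiff_ranges,
                stiff_factor=cfg.stiff_factor,
            )
            manifest["stages"]["build"] = {
                "n_beads": int(model.n_beads),
                "n_springs": int(len(model.spring_r0)),
            }

        lig_idx = model.ligand_indices()
        prot_idx = model.protein_indices()
        sel1 = _bead_indices(model, cfg.stage1_ranges)
        sel2 = _bead_indices(model, cfg.stage2_ranges)
        restr_idx = _bead_indices(model, cfg.restrain_ranges)
        target1_xyz = _target_coords_for(model, target_strong, sel1)
        target2_xyz = _target_coords_for(model, target_release, sel2)
        manifest["stages"]["tmd"] = {
            "stage1_n_atoms": int(sel1.size),
            "stage2_n_atoms": int(sel2.size),
            "k_kcal_mol_A2": cfg.tmd_k,
        }

        with stage("relax0"):
            traj0 = cg.run_dynamics(
                model,
                n_steps=cfg.n_steps_relax0,
                dt_fs=cfg.dt_fs,
                temperature=cfg.temperature_K,
                friction_ps=cfg.friction_ps,
                seed=cfg.seed + 11,
                record_every=cfg.record_every,
            )
        with stage("tmd_stage1"):
            traj1 = _tmd_stage(
                model, sel1, target1_xyz, traj0.coords[-1], cfg,
                cfg.n_steps_stage1, cfg.seed + 21,
            )
            rmsd1 = [r["tmd0_rmsd"] for r in traj1.records]
            manifest["stages"]["tmd"]["stage1_rmsd_start_A"] = round(rmsd1[0], 4)
            manifest["stages"]["tmd"]["stage1_rmsd_end_A"] = round(rmsd1[-1], 4)
            manifest["stages"]["tmd"]["stage1_rmsd_series_A"] = [round(v, 4) for v in rmsd1]
        with stage("tmd_stage2"):
            restraint = cg.PositionalRestraint(
                atom_indices=restr_idx,
                reference=traj1.coords[-1][restr_idx],
                k=cfg.restraint_k,
            )
            traj2 = _tmd_stage(
                model, sel2, target2_xyz, traj1.coords[-1], cfg,
                cfg.n_steps_stage2, cfg.seed + 31, restraints=[restraint],
            )
            rmsd2 = [r["tmd0_rmsd"] for r in traj2.records]
            manifest["stages"]["tmd"]["stage2_rmsd_start_A"] = round(rmsd2[0], 4)
            manifest["stages"]["tmd"]["stage2_rmsd_end_A"] = round(rmsd2[-1], 4)
            manifest["stages"]["tmd"]["stage2_rmsd_series_A"] = [round(v, 4) for v in rmsd2]
        with stage("relax"):
            # the elastic network is a single-basin model anchored at the
            # start pose; equilibration around the post-stroke state is
            # modelled by re-anchoring the network at the stage-2 endpoint
            relax_model = cg.build_cg_model(
                model.template.with_coords(traj2.coords[-1]),
                contact_cutoff=cfg.contact_cutoff,
                spring_k=cfg.spring_k,
                ligand_contact_k=cfg.ligand_contact_k,
                ligand_breakable=False,
                stiff_ranges=cfg.stiff_ranges,
                stiff_factor=cfg.stiff_factor,
            )
            traj3 = cg.run_dynamics(
                relax_model,
                n_steps=cfg.n_steps_relax,
                dt_fs=cfg.dt_fs,
                temperature=cfg.temperature_K,
                friction_ps=cfg.friction_ps,
                seed=cfg.seed + 41,
                record_every=cfg.record_every,
            )

        pathway = traj0.concat(traj1).concat(traj2).concat(traj3)

        with stage("energy_profile"):
            profile = energy.profile_along_path(
                pathway, lig_idx, prot_idx, window=cfg.profile_window
            )
            minima = energy.find_minima(profile, cfg.min_prominence_kJmol)
            manifest["stages"]["energy_profile"] = {
                "n_frames": int(len(pathway)),
                "minima_frames": [int(f) for f in minima.frames],
                "minima_prominence_kJmol": [round(float(p), 3) for p in minima.prominence_kJmol],
            }

        with stage("smd_release"):
            release_model = cg.build_cg_model(
                model.template.with_coords(pathway.coords[-1]),
                contact_cutoff=cfg.contact_cutoff,
                spring_k=cfg.spring_k,
                ligand_contact_k=cfg.ligand_contact_k,
                ligand_contact_ext=cfg.ligand_contact_ext,
                ligand_breakable=True,
                stiff_ranges=cfg.stiff_ranges,
                stiff_factor=cfg.stiff_factor,
            )
            vectors = _release_vectors(release_model, n=cfg.n_vectors)
            # hold the protein in place while pulling, as the all-atom
            # protocol restrains backbone sets against drift
            prot = release_model.protein_indices()
            smd_restraint = cg.PositionalRestraint(
                atom_indices=prot,
                reference=release_model.coords[prot].copy(),
                k=cfg.smd_restraint_k,
            )
            profiles = cg.run_release_experiment(
                release_model,
                vectors,
                replicates=cfg.smd_replicates,
                seed=cfg.seed + 51,
                smd_k=cfg.smd_k,
                smd_velocity=cfg.smd_velocity,
                n_steps=cfg.smd_steps,
                dt_fs=cfg.dt_fs,
                temperature=cfg.temperature_K,
                friction_ps=cfg.friction_ps,
                record_every=cfg.record_every,
                restraints=[smd_restraint],
            )
            manifest["stages"]["smd_release"] = {
                "peak_forces_pN": [round(p.peak_force_pN, 2) for p in profiles],
                "last_broken": [p.last_broken for p in profiles],
                "last_broken_tail": [p.tail_residues(4) for p in profiles],
                "persistent_anchors": [sorted(p.persistent_anchors(4)) for p in profiles],
            }

        with stage("state_metrics"):
            frames = {
                "start": pathway.frame_structure(0),
                "intermediate": traj1.frame_structure(len(traj1) - 1),
                "end": pathway.frame_structure(len(pathway) - 1),
            }
            ref = frames["start"]
            for name, st in frames.items():
                inner, outer = metrics.cleft_distances(st)
                rot = metrics.domain_rotation_angle(st, ref)
                manifest["metrics"][name] = {
                    "inner_cleft_A": round(inner, 3),
                    "outer_cleft_A": round(outer, 3),
                    "converter_rotation_vs_start_deg": round(rot, 3),
                }

        with stage("artifacts"):
            pathway.write_pdb(out / "pathway.pdb")
            profile.to_frame().to_csv(out / "energy_profile.tsv", sep="\t", index=False)
            rows = []
            for p in profiles:
                for t, f, s in zip(p.times_ps, p.force_pN, p.displacement_A):
                    rows.append(
                        {
                            "vector": np.array2string(p.vector, precision=3),
                            "replicate": p.replicate,
                            "t_ps": t,
                            "s_A": s,
                            "F_pN": f,
                        }
                    )
            import pandas as pd

            pd.DataFrame(rows).to_csv(out / "smd_forces.tsv", sep="\t", index=False)
            (out / "config.yaml").write_text(cfg.to_yaml())
            for artifact in ("pathway.pdb", "energy_profile.tsv", "smd_forces.tsv", "config.yaml"):
                manifest["artifacts"][artifact] = _sha256(out / artifact)
    except Exception as err:
        manifest["failed_stage"] = {
            "stage": max(timings, default="build"),
            "error": str(err),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["timings_s"] = timings
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
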