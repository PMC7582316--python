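"""Elastic-network construction, biasing potentials, and the Langevin
integrator: analytic identities, finite-difference oracles, conservation
and equipartition checks, seed reproducibility."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from powerstroke import cg
from powerstroke.structure import Atom, Structure
from powerstroke.synthetic import ToyMotorSpec, make_toy_motor

from conftest import make_chain


@pytest.fixture()
def toy_model():
    return cg.build_cg_model(make_toy_motor(ToyMotorSpec(seed=0, with_ligand=True)))


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------


def test_three_residue_collinear_chain_has_only_bonded_springs():
    chain = make_chain([1, 2, 3], atom_names=("CA",))
    model = cg.build_cg_model(chain, contact_cutoff=10.0)
    assert model.n_beads == 3
    assert len(model.spring_r0) == 2  # |i-j| >= 3 excludes all contacts
    np.testing.assert_allclose(model.spring_r0, 3.8)


def test_contact_set_matches_brute_force_enumeration(toy_model):
    st = make_toy_motor(ToyMotorSpec(seed=0, with_ligand=True))
    ca = [a for a in st if a.atom_name == "CA" and not a.het]
    want = set()
    for i in range(len(ca)):
        for j in range(i + 1, len(ca)):
            d = np.linalg.norm(ca[i].coords - ca[j].coords)
            if abs(ca[i].res_seq - ca[j].res_seq) >= 3 and d <= 10.0:
                want.add((i, j))
    got = {
        (min(i, j), max(i, j))
        for (i, j), brk in zip(map(tuple, toy_model.spring_ij), toy_model.breakable)
        if not brk
        and not toy_model.is_ligand[i]
        and not toy_model.is_ligand[j]
        and abs(toy_model.bead_res_seq[i] - toy_model.bead_res_seq[j]) >= 3
    }
    assert got == want


def test_model_energy_zero_at_build_coordinates(toy_model):
    e, f = toy_model.spring_energy_forces(toy_model.coords)
    assert e == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(f, 0.0, atol=1e-12)


def test_missing_ca_rejected():
    st = Structure(
        [
            Atom("A", 1, "", "ALA", "CA", "C", np.zeros(3)),
            Atom("A", 2, "", "ALA", "N", "N", np.array([3.8, 0, 0])),
        ]
    )
    with pytest.raises(ValueError, match="missing Ca"):
        cg.build_cg_model(st)


def test_fully_disconnected_chain_rejected():
    chain = make_chain([1, 5, 9, 13], atom_names=("CA",), spacing=30.0)
    with pytest.raises(ValueError, match="no consecutive residues"):
        cg.build_cg_model(chain)


# ---------------------------------------------------------------------------
# TMD bias
# ---------------------------------------------------------------------------


def _tmd_bias(model, n_atoms=20, k=200.0, seed=0, rmsd_star=1.0):
    rng = np.random.default_rng(seed)
    idx = np.arange(n_atoms)
    target = model.coords[idx] + rng.normal(0, 1.0, (n_atoms, 3))
    return cg.TMDBias(
        atom_indices=idx,
        target_coords=target,
        k=k,
        schedule=lambda t: rmsd_star,
    )


def test_tmd_zero_when_rmsd_matches_schedule(toy_model):
    idx = np.arange(20)
    bias = cg.TMDBias(
        atom_indices=idx,
        target_coords=toy_model.coords[idx].copy(),
        k=200.0,
        schedule=lambda t: 0.0,
    )
    e, f = cg.tmd_energy_and_forces(toy_model.coords, bias, 0.0)
    assert e == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(f, 0.0, atol=1e-9)


def test_tmd_energy_derivative_wrt_rmsd_is_analytic(toy_model):
    """dV/dRMSD = (k/N)(RMSD - RMSD*) for V = (k/2N)(RMSD - RMSD*)^2."""
    bias = _tmd_bias(toy_model, k=200.0, rmsd_star=0.4)
    idx = bias.atom_indices
    rmsd, _ = cg.best_fit_rmsd(toy_model.coords[idx], bias.target_coords)
    e, _ = cg.tmd_energy_and_forces(toy_model.coords, bias, 0.0)
    n = bias.n_atoms
    assert e == pytest.approx(0.5 * 200.0 / n * (rmsd - 0.4) ** 2, rel=1e-12)
    # numeric derivative along the rmsd coordinate via schedule shift
    h = 1e-6
    e_hi, _ = cg.tmd_energy_and_forces(
        toy_model.coords,
        cg.TMDBias(idx, bias.target_coords, 200.0, lambda t: 0.4 - h),
        0.0,
    )
    dV_dRMSD = (e_hi - e) / h
    assert dV_dRMSD == pytest.approx(200.0 / n * (rmsd - 0.4), rel=1e-4)


def test_tmd_forces_match_finite_differences(toy_model):
    bias = _tmd_bias(toy_model, n_atoms=20, k=200.0, seed=3, rmsd_star=0.2)
    coords = toy_model.coords.copy()
    e0, forces = cg.tmd_energy_and_forces(coords, bias, 0.0)
    h = 1e-6
    rng = np.random.default_rng(1)
    for i in rng.choice(20, size=6, replace=False):
        for d in range(3):
            cp, cm = coords.copy(), coords.copy()
            cp[i, d] += h
            cm[i, d] -= h
            ep, _ = cg.tmd_energy_and_forces(cp, bias, 0.0)
            em, _ = cg.tmd_energy_and_forces(cm, bias, 0.0)
            fd = -(ep - em) / (2 * h)
            assert fd == pytest.approx(forces[i, d], rel=1e-5, abs=1e-9)
    # non-TMD beads feel nothing
    np.testing.assert_allclose(forces[20:], 0.0)


def test_tmd_requires_three_atoms(toy_model):
    with pytest.raises(ValueError, match="at least 3"):
        cg.TMDBias(
            atom_indices=np.array([0, 1]),
            target_coords=np.zeros((2, 3)),
            k=1.0,
            schedule=lambda t: 0.0,
        )


def test_tmd_with_large_k_tracks_schedule_to_final_value():
    """A linear schedule driven with a large force constant lands within
    10% of the scheduled final RMSD (deterministic overdamped run)."""
    chain = make_chain(range(1, 21), atom_names=("CA",), spacing=3.8)
    # bend the chain into a zig-zag so the fit is well-conditioned
    coords = chain.coord_array()
    coords[:, 1] += 1.5 * (np.arange(20) % 2)
    chain = chain.with_coords(coords)
    model = cg.build_cg_model(chain, contact_cutoff=8.0)
    rng = np.random.default_rng(2)
    target = model.coords + rng.normal(0, 2.0, model.coords.shape)
    idx = np.arange(model.n_beads)
    rmsd0, _ = cg.best_fit_rmsd(model.coords, target)
    final = 0.5
    # the per-atom bias stiffness scales as k/N^2, so "large k" must beat
    # N^2 times the network stiffness for tight schedule tracking
    bias = cg.TMDBias(idx, target, k=5e6, schedule=cg.LinearSchedule(rmsd0, final, 40.0))
    traj = cg.run_dynamics(
        model, biases=[bias], n_steps=40000, dt_fs=1.0,
        temperature=0.0, friction_ps=5.0, seed=0, record_every=400,
    )
    rmsd_series = [r["tmd0_rmsd"] for r in traj.records]
    assert np.all(np.diff(rmsd_series) < 0.02)  # monotone tracking
    assert rmsd_series[-1] < rmsd_series[0]
    assert rmsd_series[-1] == pytest.approx(final, rel=0.10)


# ---------------------------------------------------------------------------
# SMD bias
# ---------------------------------------------------------------------------


def test_smd_zero_force_at_t0_with_com_at_anchor(toy_model):
    lig = toy_model.ligand_indices()
    m = toy_model.masses[lig]
    anchor = np.sum(toy_model.coords[lig] * m[:, None], axis=0) / m.sum()
    bias = cg.SMDBias(atom_indices=lig, direction=np.array([1.0, 0, 0]), anchor=anchor)
    e, f, f_pn = cg.smd_energy_and_forces(toy_model.coords, bias, 0.0, toy_model.masses)
    assert e == pytest.approx(0.0)
    assert f_pn == pytest.approx(0.0)
    np.testing.assert_allclose(f, 0.0)


def test_smd_force_on_pinned_com_grows_as_k_v_t(toy_model):
    lig = toy_model.ligand_indices()
    m = toy_model.masses[lig]
    anchor = np.sum(toy_model.coords[lig] * m[:, None], axis=0) / m.sum()
    bias = cg.SMDBias(
        atom_indices=lig, direction=np.array([0, 0, 1.0]), anchor=anchor,
        k=4.0, velocity=0.005,
    )
    for t in (1.0, 10.0, 50.0):
        _, _, f_pn = cg.smd_energy_and_forces(toy_model.coords, bias, t, toy_model.masses)
        assert f_pn == pytest.approx(4.0 * 0.005 * t * cg.KCAL_PER_A_TO_PN, rel=1e-12)


def test_smd_forces_match_finite_differences(toy_model):
    lig = toy_model.ligand_indices()
    bias = cg.SMDBias(
        atom_indices=lig,
        direction=np.array([0.3, -0.5, 0.81]) / np.linalg.norm([0.3, -0.5, 0.81]),
        anchor=toy_model.coords[lig].mean(axis=0) + 1.0,
    )
    coords = toy_model.coords.copy()
    _, forces, _ = cg.smd_energy_and_forces(coords, bias, 5.0, toy_model.masses)
    h = 1e-6
    for i in lig[:2]:
        for d in range(3):
            cp, cm = coords.copy(), coords.copy()
            cp[i, d] += h
            cm[i, d] -= h
            ep, _, _ = cg.smd_energy_and_forces(cp, bias, 5.0, toy_model.masses)
            em, _, _ = cg.smd_energy_and_forces(cm, bias, 5.0, toy_model.masses)
            assert -(ep - em) / (2 * h) == pytest.approx(forces[i, d], rel=1e-5, abs=1e-10)


def test_smd_empty_selection_rejected():
    with pytest.raises(ValueError, match="empty"):
        cg.SMDBias(atom_indices=np.array([], dtype=int),
                   direction=np.array([1.0, 0, 0]), anchor=np.zeros(3))


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------


def test_zero_steps_returns_initial_frame_only(toy_model):
    traj = cg.run_dynamics(toy_model, n_steps=0, seed=0)
    assert len(traj) == 1
    np.testing.assert_array_equal(traj.coords[0], toy_model.coords)


def test_energy_conservation_unbiased_unthermostatted():
    # bond rupture is non-conservative by design, so conservation is
    # checked on a model with permanent ligand contacts
    toy_model = cg.build_cg_model(
        make_toy_motor(ToyMotorSpec(seed=0, with_ligand=True)), ligand_breakable=False
    )
    rng = np.random.default_rng(0)
    start = toy_model.coords + rng.normal(0, 0.3, toy_model.coords.shape)
    traj = cg.run_dynamics(
        toy_model, n_steps=10_000, dt_fs=1.0, temperature=0.0,
        friction_ps=0.0, seed=1, start_coords=start, record_every=100,
    )
    E = np.array([r["potential_kcal"] + r["kinetic_kcal"] for r in traj.records])
    assert np.max(np.abs(E - E[0])) / abs(E[0]) <= 1e-4


def test_equipartition_at_310K(toy_model):
    traj = cg.run_dynamics(
        toy_model, n_steps=30_000, dt_fs=2.0, temperature=310.0,
        friction_ps=5.0, seed=2, record_every=20,
    )
    ke = np.array([r["kinetic_kcal"] for r in traj.records[30:]])
    per_dof = ke.mean() / (3 * toy_model.n_beads)
    assert per_dof == pytest.approx(0.5 * cg.KB_KCAL * 310.0, rel=0.05)


def test_dynamics_bitwise_reproducible_under_fixed_seed(toy_model):
    kwargs = dict(n_steps=500, dt_fs=2.0, temperature=310.0, friction_ps=1.0,
                  record_every=10)
    t1 = cg.run_dynamics(toy_model.reset_contacts(), seed=42, **kwargs)
    t2 = cg.run_dynamics(toy_model.reset_contacts(), seed=42, **kwargs)
    np.testing.assert_array_equal(t1.coords, t2.coords)
    t3 = cg.run_dynamics(toy_model.reset_contacts(), seed=43, **kwargs)
    assert not np.array_equal(t1.coords, t3.coords)


def test_blowup_aborts_with_diagnostic(toy_model):
    with pytest.raises(FloatingPointError, match="blew up"):
        cg.run_dynamics(toy_model, n_steps=2000, dt_fs=500.0,
                        temperature=310.0, friction_ps=0.0, seed=0)


# ---------------------------------------------------------------------------
# release experiment
# ---------------------------------------------------------------------------


def _single_contact_system(k_contact=4.0, break_ext=1.5):
    """One protein residue plus a one-bead ligand coupled by a single
    breakable spring: rupture force has the closed form k * break_ext."""
    atoms = [
        Atom("A", 1, "", "ALA", "CA", "C", np.zeros(3)),
        Atom("A", 900, "", "ADP", "PB", "P", np.array([3.0, 0, 0]), het=True),
    ]
    st = Structure(atoms, id="1contact")
    return cg.build_cg_model(
        st, ligand_cutoff=5.0, ligand_k=k_contact, break_ext=break_ext
    )


def test_single_spring_rupture_force_closed_form():
    k_contact, ext = 4.0, 1.5
    model = _single_contact_system(k_contact, ext)
    restraint = cg.PositionalRestraint(
        atom_indices=np.array([0]), reference=model.coords[:1].copy(), k=200.0
    )
    profiles = cg.run_release_experiment(
        model, [np.array([1.0, 0, 0])], replicates=1, seed=0,
        smd_k=20.0, smd_velocity=0.05, n_steps=40_000, dt_fs=1.0,
        temperature=0.0, friction_ps=20.0, record_every=5,
        restraints=[restraint],
    )
    p = profiles[0]
    assert len(p.ruptures) == 1
    expected_pN = k_contact * ext * cg.KCAL_PER_A_TO_PN
    assert p.peak_force_pN == pytest.approx(expected_pN, rel=0.15)
    # after rupture the only resistance is friction: force collapses
    assert p.force_pN[-1] < 0.25 * p.peak_force_pN


def test_release_with_no_contacts_has_near_zero_force():
    atoms = [
        Atom("A", 1, "", "ALA", "CA", "C", np.zeros(3)),
        Atom("A", 900, "", "ADP", "PB", "P", np.array([30.0, 0, 0]), het=True),
    ]
    model = cg.build_cg_model(Structure(atoms, id="free"), ligand_cutoff=5.0)
    profiles = cg.run_release_experiment(
        model, [np.array([1.0, 0, 0])], replicates=1, seed=0,
        smd_k=4.0, smd_velocity=0.05, n_steps=10_000, dt_fs=1.0,
        temperature=0.0, friction_ps=1.0, record_every=10,
    )
    # free ligand: only friction drag and the start-up transient remain,
    # orders of magnitude below any contact-rupture force
    assert profiles[0].peak_force_pN <= 10.0
    assert profiles[0].ruptures == []


def test_smd_work_internal_consistency(toy_model):
    lig = toy_model.ligand_indices()
    prot = toy_model.protein_indices()
    restraint = cg.PositionalRestraint(
        atom_indices=prot, reference=toy_model.coords[prot].copy(), k=5.0
    )
    profiles = cg.run_release_experiment(
        toy_model.reset_contacts(), [np.array([0, -1.0, 0])], replicates=1,
        seed=3, smd_velocity=0.5, n_steps=5000, dt_fs=2.0, temperature=0.0,
        friction_ps=1.0, record_every=1, restraints=[restraint],
    )
    p = profiles[0]
    f = p.force_pN / cg.KCAL_PER_A_TO_PN
    ds = np.diff(p.displacement_A)
    riemann = float(np.sum(0.5 * (f[:-1] + f[1:]) * ds))
    trapz = p.work_kcal()
    assert riemann == pytest.approx(trapz, rel=1e-3)
    left = float(np.sum(f[:-1] * ds))
    assert left == pytest.approx(trapz, rel=1e-3, abs=1e-3)


def test_release_experiment_requires_ligand():
    chain = make_chain(range(1, 8), atom_names=("CA",))
    model = cg.build_cg_model(chain)
    with pytest.raises(ValueError, match="ligand"):
        cg.run_release_experiment(model, [np.array([1.0, 0, 0])])
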