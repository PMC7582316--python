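from pathlib import Path

import numpy as np
import pytest

from powerstroke import pipeline
from powerstroke.structure import Atom, Structure
from powerstroke.synthetic import ToyMotorSpec, make_toy_motor

DEPOSITED_DIR = Path(__file__).parent / "data" / "deposited"


@pytest.fixture(scope="session")
def toy_motor():
    """Default toy motor (closed cleft, converter up, no ligand)."""
    return make_toy_motor(ToyMotorSpec(seed=0))


@pytest.fixture(scope="session")
def toy_motor_ligand():
    return make_toy_motor(ToyMotorSpec(seed=0, with_ligand=True))


@pytest.fixture(scope="session")
def toy_motor_rotated():
    return make_toy_motor(ToyMotorSpec(seed=0, converter_angle=55.0))


def make_chain(
    residues,
    chain_id="A",
    atom_names=("N", "CA", "C", "O"),
    res_name="ALA",
    spacing=3.8,
):
    """Straight poly-residue chain with backbone atoms, for selection and
    counting tests (residue numbers need not be contiguous)."""
    atoms = []
    for k, res_seq in enumerate(residues):
        base = np.array([spacing * k, 0.0, 0.0])
        for m, name in enumerate(atom_names):
            atoms.append(
                Atom(
                    chain_id=chain_id,
                    res_seq=int(res_seq),
                    icode="",
                    res_name=res_name,
                    atom_name=name,
                    element=name[0],
                    coords=base + np.array([0.0, 0.4 * m, 0.1 * m]),
                )
            )
    return Structure(atoms, id="chain-fixture")


@pytest.fixture(scope="session")
def pipeline_manifest(tmp_path_factory):
    """One default-configuration pipeline run shared by all tests that
    inspect the reconstructed pathway."""
    out = tmp_path_factory.mktemp("pipeline_run")
    cfg = pipeline.RunConfig(out_dir=str(out), seed=1)
    manifest = pipeline.run_pipeline(cfg)
    manifest["_out_dir"] = str(out)
    return manifest


def load_deposited(accession: str):
    """Deposited structures are a one-time download (see
    scripts/fetch_structures.py); their absence fails the dependent test
    rather than skipping it."""
    from powerstroke.structure import read_pdb

    path = DEPOSITED_DIR / f"{accession.lower()}.pdb"
    if not path.exists():
        pytest.fail(
            f"deposited structure {accession} not found at {path}; "
            "run scripts/fetch_structures.py (requires network) first"
        )
    return read_pdb(path)
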