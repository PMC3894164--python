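import numpy as np
import pytest
import biotite.structure as struc

from cgap.structure_io import AnnotatedStructure


def make_atoms(records):
    """Build an AtomArray from (chain, resid, resname, atom_name, element, xyz)."""
    n = len(records)
    atoms = struc.AtomArray(n)
    atoms.coord = np.array([r[5] for r in records], dtype=np.float32)
    atoms.chain_id = np.array([r[0] for r in records], dtype="U4")
    atoms.res_id = np.array([r[1] for r in records])
    atoms.res_name = np.array([r[2] for r in records], dtype="U5")
    atoms.atom_name = np.array([r[3] for r in records], dtype="U6")
    atoms.element = np.array([r[4] for r in records], dtype="U2")
    return atoms


def backbone_residue(chain, resid, resname, origin):
    """Four backbone atoms in a plausible local geometry."""
    ox, oy, oz = origin
    return [
        (chain, resid, resname, "N", "N", (ox, oy, oz)),
        (chain, resid, resname, "CA", "C", (ox + 1.46, oy, oz)),
        (chain, resid, resname, "C", "C", (ox + 2.0, oy + 1.4, oz)),
        (chain, resid, resname, "O", "O", (ox + 1.4, oy + 2.4, oz + 0.2)),
    ]


def annotated(records, label="structured"):
    atoms = make_atoms(records)
    atoms.set_annotation("region", np.full(atoms.array_length(), label, dtype="U20"))
    return AnnotatedStructure(atoms)


@pytest.fixture
def tripeptide_pdb(tmp_path):
    """Minimal 3-residue PDB file on disk."""
    from biotite.structure.io.pdb import PDBFile

    records = []
    for k, resname in enumerate(["ALA", "GLY", "SER"], start=1):
        records += backbone_residue("A", k, resname, (3.8 * k, 0.0, 0.0))
    atoms = make_atoms(records)
    path = tmp_path / "tri.pdb"
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))
    return path


@pytest.fixture(scope="session")
def helix_structure():
    """8-residue all-atom helix-like chain for contact detection tests."""
    records = []
    for k in range(1, 9):
        ang = np.deg2rad(100.0) * k
        origin = (2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * k)
        records += backbone_residue("A", k, "ALA", origin)
    return annotated(records, "structured")


@pytest.fixture(scope="session")
def toy_dimer():
    from cgap.fixtures import ToyDimerSpec, make_toy_dimer

    return make_toy_dimer(ToyDimerSpec(psite_tethers={"A": [8]}, seed=7))


@pytest.fixture(scope="session")
def unit_systems():
    from cgap.fixtures import make_unit_systems

    return make_unit_systems()
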