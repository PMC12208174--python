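import numpy as np
import pytest

from pocketatlas import generate_synthetic_complex


def pdb_atom_line(serial, name, resname, chain, resnum, x, y, z,
                  element, het=False, altloc=" ", occ=1.0):
    record = "HETATM" if het else "ATOM  "
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record}{serial:>5d} {name_field}{altloc}{resname:>3s} {chain}"
            f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {element:>2s}")


@pytest.fixture
def two_residue_pdb():
    """Hand-written 2-residue chain with one LIG group and a water."""
    lines = [
        pdb_atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
        pdb_atom_line(2, "CA", "ALA", "A", 1, 1.4, 0.3, 0.1, "C"),
        pdb_atom_line(3, "CB", "ALA", "A", 1, 2.1, 1.5, 0.4, "C"),
        pdb_atom_line(4, "N", "GLY", "A", 2, 2.4, -0.9, -0.3, "N"),
        pdb_atom_line(5, "CA", "GLY", "A", 2, 3.8, -0.8, -0.2, "C"),
        pdb_atom_line(6, "C1", "LIG", "A", 101, 2.0, 3.0, 1.0, "C", het=True),
        pdb_atom_line(7, "C2", "LIG", "A", 101, 3.0, 3.5, 1.2, "C", het=True),
        pdb_atom_line(8, "O", "HOH", "A", 201, 9.0, 9.0, 9.0, "O", het=True),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def two_chain_atp_pdb():
    """ATP present once in chain A and once in chain B."""
    lines = [
        pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
        pdb_atom_line(2, "CA", "GLY", "A", 2, 3.8, 0.1, 0.0, "C"),
        pdb_atom_line(3, "CA", "SER", "B", 1, 20.0, 0.0, 0.0, "C"),
        pdb_atom_line(4, "CA", "THR", "B", 2, 23.8, 0.1, 0.0, "C"),
        pdb_atom_line(5, "PA", "ATP", "A", 90, 1.0, 2.0, 0.5, "P", het=True),
        pdb_atom_line(6, "PA", "ATP", "B", 91, 21.0, 2.0, 0.5, "P", het=True),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def standard_truth():
    """The module's reference synthetic complex: 20 residues, planted
    interface {5, 6, 9}, 6 Å truncation."""
    return generate_synthetic_complex(20, {5, 6, 9}, 6.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
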