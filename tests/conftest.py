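import numpy as np
import pytest

from halo_adapt import asr
from halo_adapt.structure_io import Atom, Residue, Structure, VDW_RADII


def pdb_atom_line(serial, name, res, chain, resseq, x, y, z,
                  occ=1.0, element=None, altloc=" ", record="ATOM  ",
                  icode=" "):
    element = element or name[0]
    return (f"{record}{serial:>5d} {name:<4s}"[:16].ljust(16)
            + f"{altloc}{res:>3s} {chain}{resseq:>4d}{icode}   "
            + f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            + f"          {element:>2s}")


def make_structure(positions, elements=None, res_type="ALA",
                   struct_id="toy") -> Structure:
    """One chain, one residue per position (a single atom each)."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    elements = elements or ["C"] * len(positions)
    structure = Structure(id=struct_id)
    structure.chains["A"] = [
        Residue("A", i + 1, res_type, atoms=[
            Atom("CA", el, pos, VDW_RADII.get(el, 1.70))])
        for i, (pos, el) in enumerate(zip(positions, elements))
    ]
    return structure


@pytest.fixture(scope="session")
def cprev():
    return asr.build_cprev()


@pytest.fixture
def three_atom_pdb(tmp_path):
    lines = [
        pdb_atom_line(1, "N", "ALA", "A", 1, 11.104, 6.134, -6.504),
        pdb_atom_line(2, "CA", "ALA", "A", 1, 11.639, 6.071, -5.147,
                      element="C"),
        pdb_atom_line(3, "C", "ALA", "A", 1, 10.730, 6.830, -4.185),
        "END",
    ]
    path = tmp_path / "three_atom.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def tripeptide_pdb(tmp_path):
    """Ala-Gly-Lys with Cα atoms only."""
    lines = [
        pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, element="C"),
        pdb_atom_line(2, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0, element="C"),
        pdb_atom_line(3, "CA", "LYS", "A", 3, 7.6, 0.0, 0.0, element="C"),
        "END",
    ]
    path = tmp_path / "tripeptide.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
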