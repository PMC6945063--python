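"""Shared fixtures: small peptides and geometric test structures.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write to tmp_path.
"""
from __future__ import annotations

import numpy as np
import pytest

from phosbind.structures import Atom, ParamStructure


from phosbind.synthetic import gen_peptide as make_peptide


@pytest.fixture
def ala_ser_ala() -> ParamStructure:
    return make_peptide(["ALA", "SER", "ALA"])


@pytest.fixture
def gly_tripeptide() -> ParamStructure:
    return make_peptide(["GLY", "GLY", "GLY"])


def make_shell(center_atom_radius: float = 1.9, shell_radius: float = 6.0,
               n_shell: int = 200, shell_atom_radius: float = 2.0
               ) -> ParamStructure:
    """A central atom fully enclosed by a dense sphere of shell atoms."""
    from phosbind.sasa import _fibonacci_sphere

    atoms = [Atom(serial=1, name="C1", res_name="CEN", res_seq=1, chain_id="A",
                  xyz=np.zeros(3), radius=center_atom_radius, element="C")]
    for i, v in enumerate(_fibonacci_sphere(n_shell)):
        atoms.append(Atom(serial=2 + i, name=f"S{i + 1}", res_name="SHL",
                          res_seq=2, chain_id="A", xyz=shell_radius * v,
                          radius=shell_atom_radius, element="C"))
    return ParamStructure(atoms, title="shell fixture")


TOY_PDB = """\
TITLE     three-atom toy
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.150   1.300   0.000  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  GLY A   1       1.000   0.000   0.000  1.00  0.00           C
ENDMDL
END
"""
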