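"""Shared fixtures: hand-built point structures and synthetic chains."""

import numpy as np
import pytest

from revtemplate.structure import Atom, Residue, Structure
from revtemplate.synthetic import make_synthetic_structure


def point_structure(coords, res_types, structure_id="PTS", atom_name="CA"):
    """A structure of single-atom residues at the given coordinates."""
    residues = [
        Residue(
            chain_id="A",
            seq_id=i + 1,
            res_type=rt,
            atoms=(Atom(atom_name, "C", np.asarray(c, dtype=float)),),
        )
        for i, (c, rt) in enumerate(zip(coords, res_types))
    ]
    return Structure(id=structure_id, residues=residues)


@pytest.fixture
def helix30():
    return make_synthetic_structure(30, "helix", seed=2)


@pytest.fixture
def coil_decoys():
    return [make_synthetic_structure(25, "coil", seed=100 + i, structure_id=f"D{i}")
            for i in range(5)]


@pytest.fixture
def two_res_pdb():
    return (
        "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C\n"
        "ATOM      3  N   SER A   2       8.000   6.000  -5.000  1.00  0.00           N\n"
        "ATOM      4  CA  SER A   2       8.500   6.500  -4.000  1.00  0.00           C\n"
        "END\n"
    )
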