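import numpy as np
import pytest

from angmut import Config, ang_model
from angmut.structio import Atom, Residue, Structure


@pytest.fixture(scope="session")
def ang():
    """Synthetic idealized angiogenin model (session-cached, treat as read-only)."""
    return ang_model()


@pytest.fixture()
def cfg():
    return Config()


def make_structure(residue_specs):
    """Build a Structure from [(number, name, [(atom, element, xyz), ...]), ...]."""
    s = Structure()
    serial = 0
    for number, name, atoms in residue_specs:
        res = Residue("A", number, name)
        for atom_name, element, xyz in atoms:
            serial += 1
            res.atoms.append(Atom(serial, atom_name, element, np.asarray(xyz, float)))
        s.residues.append(res)
    return s


@pytest.fixture()
def gly_pair_builder():
    """Two glycines whose only close donor/acceptor contact is O(1)...N(2)."""

    def _build(distance):
        far = 50.0
        return make_structure([
            (1, "GLY", [
                ("N", "N", (0.0, far, 0.0)),
                ("CA", "C", (1.5, far, 0.0)),
                ("C", "C", (3.0, far, 0.0)),
                ("O", "O", (0.0, 0.0, 0.0)),
            ]),
            (2, "GLY", [
                ("N", "N", (distance, 0.0, 0.0)),
                ("CA", "C", (distance + 1.5, -far, 0.0)),
                ("C", "C", (distance + 3.0, -far, 0.0)),
                ("O", "O", (distance + 4.5, -far, 0.0)),
            ]),
        ])

    return _build
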