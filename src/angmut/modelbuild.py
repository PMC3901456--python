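"""Idealized peptide model building.

Builds all-heavy-atom peptide models from a sequence with standard bond
lengths/angles and a repeating backbone conformation, placing each side
chain from the ideal-geometry residue templates bundled with biotite.
These models are *synthetic*: they carry correct covalent topology and
residue identities but no energetics, and stand in for crystal structures
where tests and examples need a concrete protein.
"""

from __future__ import annotations

import numpy as np

from .constants import ANG_SEQUENCE, ONE_TO_THREE
from .geometry import kabsch_superpose, apply_transform, place_atom
from .structio import Atom, Residue, Structure
from .structio import _sidechain_template  # idealized CCD heavy-atom coords

# Engh-Huber-like backbone internal coordinates.
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.2, 121.7, 120.8
_OMEGA = 180.0


def build_peptide(
    sequence: str,
    phi: float = -120.0,
    psi: float = 130.0,
    chain: str = "A",
) -> Structure:
    """Build an idealized-geometry peptide in a repeating (phi, psi) state.

    The default conformation is an extended strand, which keeps residues
    distal in sequence also distal in space — convenient for fixtures whose
    contacts are meant to be injected explicitly rather than inherited from
    the fold.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty sequence")
    for c in sequence:
        if c not in ONE_TO_THREE:
            raise ValueError(f"unknown amino-acid code {c!r}")

    # Backbone trace by sequential NeRF placement.
    n_res = len(sequence)
    bb = np.zeros((n_res, 3, 3))  # (residue, [N, CA, C], xyz)
    bb[0, 0] = (0.0, 0.0, 0.0)
    bb[0, 1] = (_N_CA, 0.0, 0.0)
    bb[0, 2] = place_atom(
        (0.0, 1.0, 0.0), bb[0, 0], bb[0, 1], _CA_C, _ANG_N_CA_C, psi - 180.0
    )
    for i in range(1, n_res):
        bb[i, 0] = place_atom(bb[i - 1, 0], bb[i - 1, 1], bb[i - 1, 2],
                              _C_N, _ANG_CA_C_N, psi)
        bb[i, 1] = place_atom(bb[i - 1, 1], bb[i - 1, 2], bb[i, 0],
                              _N_CA, _ANG_C_N_CA, _OMEGA)
        bb[i, 2] = place_atom(bb[i - 1, 2], bb[i, 0], bb[i, 1],
                              _CA_C, _ANG_N_CA_C, phi)

    structure = Structure(title="idealized synthetic peptide model")
    serial = 0

    def _add(res: Residue, name: str, element: str, coords) -> None:
        nonlocal serial
        serial += 1
        res.atoms.append(Atom(serial, name, element, np.asarray(coords, float)))

    for i, one in enumerate(sequence):
        resname = ONE_TO_THREE[one]
        res = Residue(chain, i + 1, resname)
        n_xyz, ca_xyz, c_xyz = bb[i]
        _add(res, "N", "N", n_xyz)
        _add(res, "CA", "C", ca_xyz)
        _add(res, "C", "C", c_xyz)
        # Carbonyl O antiperiplanar to the next amide N (or to psi's
        # continuation for the C terminus).
        o_ref = bb[i + 1, 0] if i + 1 < n_res else place_atom(
            n_xyz, ca_xyz, c_xyz, _C_N, _ANG_CA_C_N, psi
        )
        o_dih = _dihedral_from_point(n_xyz, ca_xyz, c_xyz, o_ref) + 180.0
        _add(res, "O", "O", place_atom(n_xyz, ca_xyz, c_xyz, _C_O, _ANG_CA_C_O, o_dih))

        tmpl = _sidechain_template(resname)
        side_names = [n for n in tmpl if n not in ("N", "CA", "C", "O")]
        if side_names:
            anchors = ("N", "CA", "C")
            rot, trans, _ = kabsch_superpose(
                np.array([tmpl[a] for a in anchors]),
                np.array([n_xyz, ca_xyz, c_xyz]),
            )
            for name in side_names:
                element = "S" if name.startswith("S") else name[0]
                _add(res, name, element, apply_transform(tmpl[name], rot, trans))
        structure.residues.append(res)
    return structure


def _dihedral_from_point(a, b, c, d) -> float:
    from .geometry import dihedral

    return dihedral(a, b, c, d)


def ang_model() -> Structure:
    """Synthetic idealized model of mature human angiogenin (123 residues).

    Sequence-faithful (His13/Lys40/His114 triad, 31-33 arginines of the
    nuclear localization signal) but built in an idealized extended
    conformation: a geometric stand-in for the crystal structure, intended
    for fixture generation and testing, not for structural inference.
    """
    s = build_peptide(ANG_SEQUENCE)
    s.title = "synthetic idealized model of mature human angiogenin"
    return s
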