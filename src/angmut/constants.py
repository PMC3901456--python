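"""Chemical tables shared across the package.

Residue naming follows the PDB convention; numbering throughout the package
is the mature-angiogenin numbering in which the catalytic triad is
His13 / Lys40 / His114 and the nuclear-localization-signal arginines are
31-33.
"""

from __future__ import annotations

#: 3-letter -> 1-letter amino-acid codes (standard residues).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Average residue (monomer minus water) masses in Da.
RESIDUE_MASS_DA = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "E": 129.12, "Q": 128.13, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}

WATER_MASS_DA = 18.02

#: van der Waals radii (A) used by the surface-area calculation.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

#: Heavy atoms that can donate a hydrogen bond (bear an H in standard
#: protonation).  Backbone amide N is a donor for every residue but proline.
SIDECHAIN_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"), "ASN": ("ND2",), "GLN": ("NE2",),
    "TRP": ("NE1",),
}

#: Heavy atoms that can accept a hydrogen bond.  Backbone carbonyl O (and a
#: terminal OXT) is an acceptor for every residue.
SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",), "GLN": ("OE1",),
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "MET": ("SD",), "CYS": ("SG",),
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Mature human angiogenin, 123 residues.  Catalytic triad at 13/40/114,
#: NLS 29-IMRRRGL-35 with the monitored arginines at 31-33.
ANG_SEQUENCE = (
    "QDNSRYTHFLTQHYDAKPQGRDDRYCESIMRRRGLTSPCKDINTFIHGNKRSIKAICENKNGNPHRENLR"
    "ISKSSFQVTTCKLHGGSPWPPCQYRATAGFRNVVVACENGLPVHLDQSIFRRP"
)

#: Residue numbers of the hydrogen-bond interaction path reported for the
#: K17I mutant: Ile17-Asp15-Ile46-His13-Leu115-Gln117-Asp116-His114.
K17I_PATH = (17, 15, 46, 13, 115, 117, 116, 114)

#: The Leu115 branch of the path reported for the L35P mutant:
#: Pro35-Lys40-Gln12-His13-Leu115-Gln117-Asp116-His114.
L35P_PATH = (35, 40, 12, 13, 115, 117, 116, 114)

HIS114 = 114
LEU115 = 115
NLS_ARG = (31, 32, 33)
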