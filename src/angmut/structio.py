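"""PDB structure / multi-model trajectory I/O and in-silico point mutation.

The reader understands the narrow fixed-column PDB dialect the pipeline
needs (``ATOM``/``HETATM``/``MODEL``/``ENDMDL``/``SEQRES``/``TER``/``TITLE``);
any other record is skipped with a debug log line.  Alternate locations:
blank or "A" kept, others dropped.  Hydrogens are read and written but all
downstream detectors use heavy-atom criteria only.
"""

from __future__ import annotations

import copy
import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    ONE_TO_THREE,
    RESIDUE_MASS_DA,
    THREE_TO_ONE,
    WATER_MASS_DA,
)
from .geometry import kabsch_superpose, apply_transform

log = logging.getLogger(__name__)

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class PDBParseError(ValueError):
    """A record could not be parsed; the message names the offending line."""


class TopologyError(ValueError):
    """Models of a multi-model file do not share one topology."""


class MutationError(ValueError):
    """The requested mutation is inconsistent with the structure."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.element:
            raise ValueError(f"atom {self.name!r}: element must be non-empty")
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    chain: str
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.number}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def label(self) -> str:
        return f"{self.name.capitalize()}{self.number}"


@dataclass
class Structure:
    residues: list[Residue] = field(default_factory=list)
    title: str = ""
    seqres: list[str] | None = None

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected shape {(self.n_atoms, 3)}, got {coords.shape}")
        for atom, xyz in zip(self.atoms, coords):
            atom.coords = xyz.copy()

    def residue(self, number: int, chain: str | None = None) -> Residue:
        for r in self.residues:
            if r.number == number and (chain is None or r.chain == chain):
                return r
        raise KeyError(f"no residue numbered {number}")

    def has_residue(self, number: int) -> bool:
        return any(r.number == number for r in self.residues)

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    def atom_slices(self) -> dict[tuple[int, str], int]:
        """Flat atom index for every ``(residue number, atom name)``."""
        index = {}
        i = 0
        for r in self.residues:
            for a in r.atoms:
                index[(r.number, a.name)] = i
                i += 1
        return index


@dataclass
class Trajectory:
    """Ordered frames sharing the topology of frame 0.

    ``coords`` has shape ``(n_frames, n_atoms, 3)``; ``dt_ps`` is the frame
    interval in picoseconds (default 1 ps sampling).
    """

    topology: Structure
    coords: np.ndarray
    dt_ps: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frame coordinates {self.coords.shape} do not match "
                f"topology with {self.topology.n_atoms} atoms"
            )
        if self.dt_ps <= 0:
            raise ValueError("dt_ps must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ps

    def frame_structure(self, i: int) -> Structure:
        s = self.topology.copy()
        s.set_coords(self.coords[i])
        return s


_TOKEN_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class MutationSpec:
    """A point mutation in ``K17I`` token form (wild type, position, mutant)."""

    wt_residue: str
    position: int
    mut_residue: str

    def __post_init__(self):
        for aa in (self.wt_residue, self.mut_residue):
            if aa not in ONE_TO_THREE:
                raise MutationError(f"unknown amino-acid code {aa!r}")
        if self.wt_residue == self.mut_residue:
            raise MutationError(
                f"wild-type and mutant residue are both {self.wt_residue!r}"
            )

    @classmethod
    def parse(cls, token: str) -> "MutationSpec":
        m = _TOKEN_RE.match(token.strip().upper())
        if m is None:
            raise MutationError(f"cannot parse mutation token {token!r}")
        return cls(m.group(1), int(m.group(2)), m.group(3))

    @property
    def token(self) -> str:
        return f"{self.wt_residue}{self.position}{self.mut_residue}"


# ---------------------------------------------------------------------------
# Reading / writing


def _infer_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] in ("H", "D") and name.strip()[0].isdigit():
        return "H"
    return stripped[0]


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str, str, int]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        resnum = int(line[22:26])
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        b = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed {line[:6].strip()} record at line {lineno}: {exc}") from exc
    if not element:
        element = _infer_element(name)
    atom = Atom(serial, name, element, np.array(xyz), occ, b)
    return atom, resname, chain, resnum


def read_pdb(path, model_policy: str = "first", dt_ps: float = 1.0):
    """Read a PDB file.

    With ``model_policy="first"`` only the first model is parsed and a
    :class:`Structure` is returned.  With ``"all"`` every ``MODEL`` block
    becomes one frame of a :class:`Trajectory` (frame interval ``dt_ps``),
    all frames being checked for an identical topology.
    """
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")

    title = ""
    seqres: list[str] = []
    model_structures: list[Structure] = []
    current: Structure | None = None
    in_model = False

    def _start():
        nonlocal current
        current = Structure()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "TITLE":
                title = (title + " " + line[10:].strip()).strip()
            elif rec == "SEQRES":
                seqres.extend(line[19:].split())
            elif rec == "MODEL":
                in_model = True
                _start()
            elif rec == "ENDMDL":
                if current is not None:
                    model_structures.append(current)
                    current = None
                if model_policy == "first":
                    break
            elif rec in ("ATOM", "HETATM"):
                altloc = line[16]
                if altloc not in (" ", "A"):
                    continue
                if current is None:
                    _start()
                atom, resname, chain, resnum = _parse_atom_line(line, lineno)
                res_list = current.residues
                if (
                    not res_list
                    or res_list[-1].number != resnum
                    or res_list[-1].chain != chain
                    or res_list[-1].name != resname
                ):
                    res_list.append(
                        Residue(chain, resnum, resname, het=(rec == "HETATM"))
                    )
                res_list[-1].atoms.append(atom)
            elif rec == "TER":
                pass
            else:
                log.debug("skipping %s record at line %d", rec or "blank", lineno)

    if current is not None:  # file without MODEL records, or unterminated model
        model_structures.append(current)
    if not model_structures or not model_structures[0].residues:
        raise PDBParseError(f"{path}: no coordinates found")

    for s in model_structures:
        s.title = title
        s.seqres = seqres or None

    if model_policy == "first":
        return model_structures[0]

    topo = model_structures[0]
    signature = [(r.number, a.name) for r in topo.residues for a in r.atoms]
    frames = []
    for i, s in enumerate(model_structures):
        sig = [(r.number, a.name) for r in s.residues for a in r.atoms]
        if sig != signature:
            raise TopologyError(
                f"{path}: model {i + 1} has a different topology "
                f"({len(sig)} atoms vs {len(signature)})"
            )
        frames.append(s.coords())
    return Trajectory(topo, np.array(frames), dt_ps=dt_ps)


def _format_atom_line(atom: Atom, res: Residue) -> str:
    record = "HETATM" if res.het else "ATOM"
    name = atom.name
    # Standard PDB alignment: 1-letter elements start in column 14.
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    x, y, z = atom.coords
    return (
        f"{record:<6}{atom.serial:>5} {name:<4} {res.name:>3} {res.chain or 'A':1}"
        f"{res.number:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
        f"{atom.b_factor:6.2f}          {atom.element:>2}"
    )


def _seqres_lines(structure: Structure) -> list[str]:
    polymer = [r for r in structure.residues if not r.het]
    if not polymer:
        return []
    chain = polymer[0].chain or "A"
    names = [r.name for r in polymer]
    lines = []
    for i in range(0, len(names), 13):
        chunk = " ".join(f"{n:>3}" for n in names[i : i + 13])
        lines.append(f"SEQRES {i // 13 + 1:>3} {chain:1} {len(names):>4}  {chunk}")
    return lines


def write_pdb(obj, path) -> None:
    """Write a :class:`Structure` or (as MODEL blocks) a :class:`Trajectory`."""
    is_traj = isinstance(obj, Trajectory)
    structure = obj.topology if is_traj else obj
    lines: list[str] = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    lines.extend(_seqres_lines(structure))

    def _model_lines(s: Structure) -> list[str]:
        out = []
        serial = 0
        for res in s.residues:
            for atom in res.atoms:
                serial += 1
                out.append(_format_atom_line(
                    Atom(serial, atom.name, atom.element, atom.coords,
                         atom.occupancy, atom.b_factor), res))
        out.append("TER")
        return out

    if is_traj:
        frame = structure.copy()
        for i in range(obj.n_frames):
            frame.set_coords(obj.coords[i])
            lines.append(f"MODEL     {i + 1:>4}")
            lines.extend(_model_lines(frame))
            lines.append("ENDMDL")
    else:
        lines.extend(_model_lines(structure))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Structure editing and sequence utilities


def strip_heteroatoms(s: Structure) -> Structure:
    """Drop every HETATM-derived residue (waters, the citrate cofactor, ions).

    Polymer residues are untouched; the input is not modified.
    """
    out = s.copy()
    out.residues = [
        r for r in out.residues if not (r.het or r.name in _WATER_NAMES)
    ]
    return out


def _sidechain_template(resname: str):
    """Idealized heavy-atom coordinates for one residue type.

    Ideal coordinates come from the chemical component dictionary bundled
    with biotite; the side chain is in its deposited (common-rotamer)
    conformation.
    """
    import biotite.structure.info as strucinfo

    tmpl = strucinfo.residue(resname)
    keep = (tmpl.element != "H") & (tmpl.atom_name != "OXT")
    tmpl = tmpl[keep]
    return {str(name): coord.copy() for name, coord in zip(tmpl.atom_name, tmpl.coord)}


_BACKBONE_SET = {"N", "CA", "C", "O", "OXT"}


def mutate_residue(s: Structure, m: MutationSpec) -> Structure:
    """Replace one side chain in silico, keeping the backbone fixed.

    Backbone atoms (N, CA, C, O, plus CB when both residues have one) keep
    their original coordinates.  The new side chain comes from an
    idealized-geometry template superposed on N-CA-CB (N-CA-C when the
    original is glycine), with no energy refinement — relaxation is the
    job of whatever produces the downstream trajectory.
    """
    try:
        res = s.residue(m.position)
    except KeyError:
        raise MutationError(f"no residue at position {m.position}") from None
    expected = ONE_TO_THREE[m.wt_residue]
    if res.name != expected:
        raise MutationError(
            f"residue {m.position} is {res.name}, not {expected}: check the "
            f"numbering convention of the input structure"
        )

    new_name = ONE_TO_THREE[m.mut_residue]
    out = s.copy()
    new_res = out.residue(m.position)
    new_res.name = new_name

    kept = [a for a in new_res.atoms if a.name in ("N", "CA", "C", "O")]
    if len(kept) < 4:
        raise MutationError(
            f"residue {m.position} lacks a complete backbone (N, CA, C, O)"
        )
    tmpl = _sidechain_template(new_name)

    keep_cb = new_name != "GLY" and res.has_atom("CB")
    if keep_cb:
        kept.append(new_res.atom("CB"))

    anchor_names = ("N", "CA", "CB") if keep_cb else ("N", "CA", "C")
    mobile = np.array([tmpl[n] for n in anchor_names])
    reference = np.array([res.atom(n).coords for n in anchor_names])
    rot, trans, _ = kabsch_superpose(mobile, reference)

    next_serial = max((a.serial for r in s.residues for a in r.atoms), default=0)
    skip = _BACKBONE_SET | ({"CB"} if keep_cb else set())
    rebuilt = []
    for name, coord in tmpl.items():
        if name in skip:
            continue
        next_serial += 1
        element = "S" if name.startswith("S") else name[0]
        rebuilt.append(
            Atom(next_serial, name, element, apply_transform(coord, rot, trans))
        )
    new_res.atoms = kept + rebuilt
    return out


def sequence_of(s: Structure) -> str:
    """One-letter sequence of the polymer residues, unknown residues as X."""
    return "".join(
        THREE_TO_ONE.get(r.name, "X") for r in s.residues if not r.het
    )


def molecular_weight(seq: str) -> float:
    """Average molecular mass in Da of a peptide given as 1-letter codes.

    Sum of average residue masses plus one water (18.02 Da).
    """
    try:
        return sum(RESIDUE_MASS_DA[c] for c in seq) + WATER_MASS_DA
    except KeyError as exc:
        raise ValueError(f"unknown amino-acid code {exc.args[0]!r}") from None
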