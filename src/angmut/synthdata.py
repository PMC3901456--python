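"""Synthetic trajectory generation with independently injected markers.

The generator is a *geometric* stand-in for molecular dynamics: starting
from a base structure, it writes each frame as the base coordinates plus
controlled perturbations, one per detector:

* ``noise_sigma`` — isotropic Gaussian jitter on every atom (thermal-like
  background, A per axis);
* ``switch_fraction_target`` — in an exact count of frames, the His114
  side chain is rotated about the CA-CB bond into the rotamer bin adjacent
  to its native one (bin centres, so binning is unambiguous);
* ``path_persistence_target`` — in an exact count of frames, one
  donor/acceptor contact at 3.0 A is created for every consecutive pair of
  a named residue path by displacing a side-chain polar atom;
* ``compaction_factor`` — the side chains of the NLS arginines 31-33 are
  pulled toward their joint centroid in every frame (local folding / close
  packing);
* ``drift_amplitude`` — a per-atom random displacement field grown
  linearly over the trajectory (progressive loss of the starting fold).

No force field, thermostat or solvent is involved; frames are valid PDB
models only in the geometric sense.  The injections are exact by
construction, which is what makes the detectors testable.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass

import numpy as np

from .constants import (
    HIS114,
    K17I_PATH,
    L35P_PATH,
    NLS_ARG,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
)
from .features import Config
from .geometry import dihedral, rotation_about_axis
from .structio import Structure, Trajectory

_CONTACT_DISTANCE = 3.0  # injected donor-acceptor distance, A
_BACKBONE = ("N", "CA", "C", "O", "OXT")
_BIN_CENTRES = {"g-": 60.0, "t": 180.0, "g+": 300.0}


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic trajectory."""

    base: Structure
    n_frames: int = 100
    dt_ps: float = 1.0
    noise_sigma: float = 0.0
    switch_fraction_target: float = 0.0
    path_persistence_target: float = 0.0
    path_residues: tuple = K17I_PATH
    compaction_factor: float = 0.0
    drift_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in ("switch_fraction_target", "path_persistence_target",
                     "compaction_factor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sigma < 0 or self.drift_amplitude < 0 or self.dt_ps <= 0:
            raise ValueError("noise_sigma, drift_amplitude >= 0 and dt_ps > 0")
        self.path_residues = tuple(int(r) for r in self.path_residues)

    # -- key = value round trip (base structure travels separately as PDB) --

    _SCALARS = ("n_frames", "dt_ps", "noise_sigma", "switch_fraction_target",
                "path_persistence_target", "path_residues",
                "compaction_factor", "drift_amplitude", "seed")

    def to_text(self) -> str:
        return "".join(f"{k} = {getattr(self, k)!r}\n" for k in self._SCALARS)

    @classmethod
    def from_text(cls, text: str, base: Structure) -> "SyntheticSpec":
        kwargs = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in cls._SCALARS:
                raise ValueError(f"unknown key {key!r} in synthetic spec")
            kwargs[key] = ast.literal_eval(value.strip())
        return cls(base=base, **kwargs)


# ---------------------------------------------------------------------------
# Injection helpers


def _sidechain_indices(topology: Structure, resnum: int,
                       beyond: str = "CB") -> np.ndarray:
    """Flat indices of side-chain heavy+H atoms beyond the given atom."""
    keep_out = set(_BACKBONE) | {"CB"} if beyond == "CB" else set(_BACKBONE)
    index = topology.atom_slices()
    res = topology.residue(resnum)
    return np.array(
        [index[(resnum, a.name)] for a in res.atoms if a.name not in keep_out],
        dtype=int,
    )


def _set_chi1(coords: np.ndarray, topology: Structure, resnum: int,
              target_deg: float, cache: dict) -> None:
    """Rotate the side chain distal to CB so chi1 equals ``target_deg``."""
    if "idx" not in cache:
        index = topology.atom_slices()
        cache["idx"] = tuple(index[(resnum, n)] for n in ("N", "CA", "CB"))
        cache["distal"] = _sidechain_indices(topology, resnum, beyond="CB")
        res = topology.residue(resnum)
        gammas = [n for n in ("CG", "CG1", "OG", "OG1", "SG") if res.has_atom(n)]
        if not gammas or len(cache["distal"]) == 0:
            raise ValueError(
                f"residue {res.name}{resnum} has no rotatable side chain: "
                f"cannot inject chi1 states"
            )
        cache["gamma"] = index[(resnum, gammas[0])]
    i_n, i_ca, i_cb = cache["idx"]
    current = dihedral(coords[i_n], coords[i_ca], coords[i_cb],
                       coords[cache["gamma"]])
    rot = rotation_about_axis(coords[i_cb] - coords[i_ca], target_deg - current)
    pivot = coords[i_cb]
    distal = cache["distal"]
    coords[distal] = (coords[distal] - pivot) @ rot.T + pivot


def _polar_atoms(topology: Structure, resnum: int):
    """(atom name, role, is_sidechain) for the H-bond-capable heavy atoms."""
    res = topology.residue(resnum)
    out = []
    for a in res.atoms:
        if a.is_hydrogen:
            continue
        if a.name == "N" and res.name != "PRO":
            out.append((a.name, "donor", False))
        if a.name in ("O", "OXT"):
            out.append((a.name, "acceptor", False))
        if a.name in SIDECHAIN_DONORS.get(res.name, ()):
            out.append((a.name, "donor", True))
        if a.name in SIDECHAIN_ACCEPTORS.get(res.name, ()):
            out.append((a.name, "acceptor", True))
    return out


def _plan_path_contacts(topology: Structure, path_residues) -> list[tuple[int, int]]:
    """One (mobile side-chain atom, fixed partner atom) pair per path edge.

    The mobile atom will be displaced to ``_CONTACT_DISTANCE`` from the
    fixed one in path-bearing frames; donor/acceptor complementarity is
    respected and no atom is moved twice.
    """
    for num in path_residues:
        if not topology.has_residue(num):
            raise ValueError(f"path residue {num} absent from the structure")
    index = topology.atom_slices()
    moved: set[int] = set()
    plan = []
    for a, b in zip(path_residues, path_residues[1:]):
        found = None
        for mob_res, fix_res in ((a, b), (b, a)):
            for mob_name, mob_role, mob_side in sorted(_polar_atoms(topology, mob_res)):
                if not mob_side:
                    continue
                i_mob = index[(mob_res, mob_name)]
                if i_mob in moved:
                    continue
                want = "acceptor" if mob_role == "donor" else "donor"
                for fix_name, fix_role, _ in sorted(_polar_atoms(topology, fix_res)):
                    i_fix = index[(fix_res, fix_name)]
                    if fix_role == want and i_fix not in moved:
                        found = (i_mob, i_fix)
                        break
                if found:
                    break
            if found:
                break
        if found is None:
            raise ValueError(
                f"cannot plan a hydrogen-bond contact for path edge "
                f"{a}-{b}: no movable polar side-chain atom"
            )
        plan.append(found)
        moved.add(found[0])
    return plan


# ---------------------------------------------------------------------------
# Generation


def generate(spec: SyntheticSpec) -> Trajectory:
    """Produce the trajectory a :class:`SyntheticSpec` describes.

    Exactly ``round(switch_fraction_target * n_frames)`` frames carry the
    His114 rotamer switch and ``round(path_persistence_target * n_frames)``
    frames carry the injected interaction-path contacts; which frames is a
    seeded random choice, so the injections are scattered rather than
    blocked.  Identical specs produce identical trajectories.
    """
    topo = spec.base
    base = topo.coords()
    n_atoms = base.shape[0]
    n = spec.n_frames
    rng = np.random.default_rng(spec.seed)

    # Frame memberships (drawn first so later options don't shift them).
    # Frame 0 defines the native rotamer state, so it never switches.
    n_switch = round(spec.switch_fraction_target * n)
    if n_switch > n - 1:
        raise ValueError(
            "switch_fraction_target leaves no native frame 0 to define the "
            "reference rotamer state"
        )
    switch_frames = set((1 + rng.choice(n - 1, size=n_switch, replace=False)).tolist())
    n_path = round(spec.path_persistence_target * n)
    path_frames = set(rng.choice(n, size=n_path, replace=False).tolist())
    drift_dirs = rng.standard_normal((n_atoms, 3))
    drift_dirs /= np.linalg.norm(drift_dirs, axis=1, keepdims=True)

    chi_cache: dict = {}
    needs_chi = topo.has_residue(HIS114)
    if needs_chi:
        index = topo.atom_slices()
        native_chi1 = dihedral(*(base[index[(HIS114, nm)]]
                                 for nm in ("N", "CA", "CB", "CG")))
        cfg = Config()
        native_bin = cfg.chi1_state(native_chi1)
        labels = [b[0] for b in cfg.chi1_bins]
        adjacent = labels[(labels.index(native_bin) + 1) % len(labels)]
    elif spec.switch_fraction_target > 0:
        raise ValueError("switch injection requested but residue 114 is absent")

    contact_plan = (
        _plan_path_contacts(topo, spec.path_residues) if n_path > 0 else []
    )

    compact_idx = None
    if spec.compaction_factor > 0:
        for num in NLS_ARG:
            if not topo.has_residue(num):
                raise ValueError(f"compaction requested but residue {num} is absent")
        compact_idx = np.concatenate(
            [_sidechain_indices(topo, num, beyond="CA") for num in NLS_ARG]
        )

    frames = np.empty((n, n_atoms, 3))
    for k in range(n):
        coords = base.copy()
        if spec.noise_sigma > 0:
            coords += rng.normal(0.0, spec.noise_sigma, size=coords.shape)
        if spec.drift_amplitude > 0:
            coords += spec.drift_amplitude * (k / (n - 1)) * drift_dirs
        if compact_idx is not None:
            sub = coords[compact_idx]
            centroid = sub.mean(axis=0)
            coords[compact_idx] = sub + spec.compaction_factor * (centroid - sub)
        if needs_chi:
            target_bin = adjacent if k in switch_frames else native_bin
            _set_chi1(coords, topo, HIS114, _BIN_CENTRES[target_bin], chi_cache)
        if k in path_frames:
            for i_mob, i_fix in contact_plan:
                direction = coords[i_mob] - coords[i_fix]
                norm = np.linalg.norm(direction)
                if norm < 1e-9:
                    direction, norm = np.array([1.0, 0.0, 0.0]), 1.0
                coords[i_mob] = coords[i_fix] + _CONTACT_DISTANCE * direction / norm
        frames[k] = coords
    return Trajectory(topology=topo.copy(), coords=frames, dt_ps=spec.dt_ps)


PRESETS = ("wt_like", "k17i_like", "l35p_like", "destabilized")

#: Mutation token each preset emulates (None for the wild-type control).
PRESET_MUTATIONS = {
    "wt_like": None,
    "k17i_like": "K17I",
    "l35p_like": "L35P",
    "destabilized": "K17I",
}


def make_preset(name: str, base: Structure, seed: int = 0,
                n_frames: int = 100) -> SyntheticSpec:
    """Named study conditions for the desk-scale case studies.

    ``wt_like`` carries only background jitter; ``k17i_like`` injects
    His114 switching (0.4) plus the Ile17->His114 interaction path (0.4);
    ``l35p_like`` adds NLS-arginine compaction (0.3) with the
    Pro35->His114 path; ``destabilized`` injects a 3 A progressive drift.
    """
    common = dict(base=base, n_frames=n_frames, seed=seed, noise_sigma=0.05)
    if name == "wt_like":
        return SyntheticSpec(**common)
    if name == "k17i_like":
        return SyntheticSpec(**common, switch_fraction_target=0.4,
                             path_persistence_target=0.4,
                             path_residues=K17I_PATH)
    if name == "l35p_like":
        return SyntheticSpec(**common, switch_fraction_target=0.4,
                             path_persistence_target=0.4,
                             path_residues=L35P_PATH,
                             compaction_factor=0.3)
    if name == "destabilized":
        return SyntheticSpec(**common, drift_amplitude=3.0)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
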