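"""Trajectory markers: backbone RMSD, His114 rotamer switching,
hydrogen-bond interaction paths, and SASA/compaction of the NLS arginines.

Four independent detectors read a :class:`~angmut.structio.Trajectory`:

* ``backbone_rmsd_series`` — stability: RMSD of backbone N/CA/C/O atoms
  versus frame 0 after optimal rigid superposition, one value per frame.
* ``chi_series`` — conformational switching of the catalytic His114 side
  chain, quantified as occupancy of chi1 rotamer bins relative to the
  frame-0 (native) bin.
* ``hbond_graph`` / ``find_interaction_path`` / ``path_persistence`` — a
  per-frame residue-level hydrogen-bond network (donor-acceptor heavy-atom
  distance <= 3.2 A by default) searched for a path from the mutation site
  to His114 passing through Leu115.
* ``shrake_rupley_sasa`` / ``nls_features`` — solvent-accessible surface
  area and side-chain compaction of the nuclear-localization-signal
  arginines 31-33.

``extract_features`` bundles all four into a :class:`FeatureSet`.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .constants import (
    BACKBONE_ATOMS,
    HIS114,
    LEU115,
    NLS_ARG,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    VDW_RADII,
)
from .geometry import dihedral, kabsch_superpose, sphere_points
from .structio import MutationSpec, Structure, Trajectory

__all__ = [
    "Config",
    "RMSDSeries",
    "ChiStateSeries",
    "InteractionPath",
    "SASASeries",
    "FeatureSet",
    "kabsch_superpose",
    "backbone_rmsd_series",
    "chi_series",
    "hbond_graph",
    "find_interaction_path",
    "path_persistence",
    "shrake_rupley_sasa",
    "nls_features",
    "extract_features",
    "write_hbond_edgelist",
]


_DEFAULT_BINS = (("g-", 0.0, 120.0), ("t", 120.0, 240.0), ("g+", 240.0, 360.0))


@dataclass(frozen=True)
class Config:
    """Detector thresholds and numerical settings.

    ``hbond_cutoff`` (A) is the donor-acceptor heavy-atom distance
    criterion.  The decision thresholds (``switch_threshold`` etc.) are
    declared, configurable defaults: they parameterize the qualitative
    rules, and sensible values depend on trajectory length and system.
    """

    hbond_cutoff: float = 3.2
    sasa_probe_radius: float = 1.4
    sasa_sphere_points: int = 960
    chi1_bins: tuple = _DEFAULT_BINS
    switch_threshold: float = 0.20
    path_threshold: float = 0.10
    sasa_reduction_threshold: float = 0.20
    fold_threshold: float = 0.10
    rmsd_margin: float = 1.0
    analysis_window: float = 0.5
    ribo_rule: str = "and"
    hbond_angle_min: float | None = None  # optional D-H...A filter, degrees

    def __post_init__(self):
        if self.hbond_cutoff <= 0 or self.rmsd_margin <= 0:
            raise ValueError("hbond_cutoff and rmsd_margin must be > 0")
        for name in ("switch_threshold", "path_threshold",
                     "sasa_reduction_threshold", "fold_threshold",
                     "analysis_window"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.ribo_rule not in ("and", "or"):
            raise ValueError("ribo_rule must be 'and' or 'or'")
        edges = sorted((lo, hi) for _, lo, hi in self.chi1_bins)
        if edges[0][0] != 0.0 or edges[-1][1] != 360.0 or any(
            edges[i][1] != edges[i + 1][0] for i in range(len(edges) - 1)
        ):
            raise ValueError("chi1_bins must partition [0, 360)")

    def chi1_state(self, chi1_deg: float) -> str:
        x = chi1_deg % 360.0
        for label, lo, hi in self.chi1_bins:
            if lo <= x < hi:
                return label
        raise ValueError(f"chi1 {chi1_deg} falls in no bin")  # pragma: no cover

    def window_slice(self, n: int) -> slice:
        """Index slice of the final ``analysis_window`` fraction of frames."""
        start = min(int(round(n * (1.0 - self.analysis_window))), n - 1)
        return slice(start, n)


@dataclass
class RMSDSeries:
    times: np.ndarray  # ps
    values: np.ndarray  # A

    def window_mean(self, cfg: Config) -> float:
        return float(np.mean(self.values[cfg.window_slice(len(self.values))]))


@dataclass
class ChiStateSeries:
    residue_number: int
    residue_name: str
    chi1: np.ndarray  # degrees, per frame
    chi2: np.ndarray | None
    states: list[str]
    native_state: str
    switch_fraction: float


@dataclass
class InteractionPath:
    """A simple path in a hydrogen-bond graph from source to target."""

    residues: tuple
    names: tuple
    mediated_by_leu115: bool
    trivial: bool = False

    def label(self) -> str:
        return "-".join(
            f"{n.capitalize()}{r}" for n, r in zip(self.names, self.residues)
        )


@dataclass
class SASASeries:
    times: np.ndarray
    per_residue: dict  # residue number -> per-frame SASA array (A^2)
    rrr_gyration: np.ndarray  # per-frame Rg of the three Arg side chains (A)
    mean_total: float  # window mean of summed R31+R32+R33 SASA
    mean_gyration: float

    @property
    def total(self) -> np.ndarray:
        return np.sum(list(self.per_residue.values()), axis=0)


@dataclass
class FeatureSet:
    rmsd: RMSDSeries
    his114: ChiStateSeries
    nls: SASASeries
    path_persistence: float | None = None
    best_path: InteractionPath | None = None
    mutation: str | None = None
    config: Config = field(default_factory=Config)

    def to_dict(self) -> dict:
        return {
            "mutation": self.mutation,
            "rmsd": {
                "times_ps": self.rmsd.times.tolist(),
                "values_A": self.rmsd.values.tolist(),
                "window_mean_A": self.rmsd.window_mean(self.config),
            },
            "his114": {
                "native_state": self.his114.native_state,
                "switch_fraction": self.his114.switch_fraction,
                "states": self.his114.states,
                "chi1_deg": self.his114.chi1.tolist(),
            },
            "path": None if self.path_persistence is None else {
                "persistence": self.path_persistence,
                "best_path": None if self.best_path is None else {
                    "residues": list(self.best_path.residues),
                    "label": self.best_path.label(),
                    "mediated_by_leu115": self.best_path.mediated_by_leu115,
                },
            },
            "nls": {
                "per_residue_sasa_A2": {
                    str(k): v.tolist() for k, v in self.nls.per_residue.items()
                },
                "rrr_gyration_A": self.nls.rrr_gyration.tolist(),
                "mean_total_sasa_A2": self.nls.mean_total,
                "mean_gyration_A": self.nls.mean_gyration,
            },
            "config": asdict(self.config),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# Backbone RMSD


def _backbone_indices(topology: Structure) -> np.ndarray:
    index = topology.atom_slices()
    idx = []
    for res in topology.residues:
        if res.het:
            continue
        for name in BACKBONE_ATOMS:
            if (res.number, name) not in index:
                raise ValueError(
                    f"residue {res.name}{res.number} lacks backbone atom {name}"
                )
            idx.append(index[(res.number, name)])
    return np.array(idx, dtype=int)


def backbone_rmsd_series(t: Trajectory) -> RMSDSeries:
    """Backbone (N, CA, C, O) RMSD of every frame versus frame 0.

    Each frame is optimally superposed on frame 0 before the deviation is
    measured, so rigid-body motion contributes nothing.
    """
    if t.n_frames == 0:
        raise ValueError("empty trajectory")
    idx = _backbone_indices(t.topology)
    ref = t.coords[0][idx]
    values = np.empty(t.n_frames)
    for i in range(t.n_frames):
        _, _, rmsd = kabsch_superpose(t.coords[i][idx], ref)
        values[i] = rmsd
    return RMSDSeries(times=t.times_ps, values=values)


# ---------------------------------------------------------------------------
# Side-chain dihedral states

_GAMMA_NAMES = ("CG", "CG1", "OG", "OG1", "SG")


def chi_series(t: Trajectory, residue_number: int = HIS114,
               cfg: Config | None = None) -> ChiStateSeries:
    """Chi1 (and, for His, chi2) dihedrals and rotamer-bin occupancy.

    The native state is the chi1 bin of frame 0; ``switch_fraction`` is the
    fraction of frames found outside it.
    """
    cfg = cfg or Config()
    res = t.topology.residue(residue_number)
    index = t.topology.atom_slices()

    def _idx(name: str) -> int:
        if (residue_number, name) not in index:
            raise ValueError(
                f"residue {res.name}{residue_number} lacks side-chain atom {name}"
            )
        return index[(residue_number, name)]

    gamma = next((g for g in _GAMMA_NAMES if res.has_atom(g)), None)
    if gamma is None:
        raise ValueError(
            f"residue {res.name}{residue_number} has no gamma heavy atom: "
            f"chi1 undefined"
        )
    i_n, i_ca, i_cb, i_g = _idx("N"), _idx("CA"), _idx("CB"), _idx(gamma)

    chi1 = np.array([
        dihedral(c[i_n], c[i_ca], c[i_cb], c[i_g]) for c in t.coords
    ])
    chi2 = None
    if res.name == "HIS" and res.has_atom("ND1"):
        i_nd1 = _idx("ND1")
        chi2 = np.array([
            dihedral(c[i_ca], c[i_cb], c[i_g], c[i_nd1]) for c in t.coords
        ])
    states = [cfg.chi1_state(x) for x in chi1]
    native = states[0]
    switch_fraction = float(np.mean([s != native for s in states]))
    return ChiStateSeries(
        residue_number=residue_number,
        residue_name=res.name,
        chi1=chi1,
        chi2=chi2,
        states=states,
        native_state=native,
        switch_fraction=switch_fraction,
    )


# ---------------------------------------------------------------------------
# Hydrogen-bond graphs and interaction paths


class _HBondRoles:
    """Pre-indexed donor/acceptor heavy atoms of one topology."""

    def __init__(self, topology: Structure):
        donors, acceptors = [], []   # (flat atom index, residue number)
        hydrogens = []               # (flat index, residue number)
        i = 0
        self.residue_numbers = []
        self.residue_names = {}
        for res in topology.residues:
            if not res.het:
                self.residue_numbers.append(res.number)
                self.residue_names[res.number] = res.name
            for a in res.atoms:
                if a.is_hydrogen:
                    hydrogens.append((i, res.number))
                elif not res.het:
                    if a.name == "N" and res.name != "PRO":
                        donors.append((i, res.number))
                    if a.name in ("O", "OXT"):
                        acceptors.append((i, res.number))
                    if a.name in SIDECHAIN_DONORS.get(res.name, ()):
                        donors.append((i, res.number))
                    if a.name in SIDECHAIN_ACCEPTORS.get(res.name, ()):
                        acceptors.append((i, res.number))
                i += 1
        self.donor_idx = np.array([d[0] for d in donors], dtype=int)
        self.donor_res = np.array([d[1] for d in donors], dtype=int)
        self.acceptor_idx = np.array([a[0] for a in acceptors], dtype=int)
        self.acceptor_res = np.array([a[1] for a in acceptors], dtype=int)
        self.hydrogen_idx = np.array([h[0] for h in hydrogens], dtype=int)
        self.hydrogen_res = np.array([h[1] for h in hydrogens], dtype=int)


def hbond_graph(frame: np.ndarray, topology: Structure, cfg: Config | None = None,
                frame_index: int = 0, _roles: _HBondRoles | None = None) -> nx.Graph:
    """Residue-level hydrogen-bond graph of one frame.

    Nodes are residue numbers of all polymer residues (name stored as a
    node attribute); an undirected edge joins residues i != j whenever a
    donor heavy atom (N/O/S bearing an H in standard chemistry) of one lies
    within ``cfg.hbond_cutoff`` of an acceptor heavy atom (N/O/S) of the
    other.  Each edge stores the minimum qualifying distance.  When
    ``cfg.hbond_angle_min`` is set and explicit hydrogens are present on
    the donor, pairs additionally need a D-H...A angle above it.
    """
    cfg = cfg or Config()
    roles = _roles if _roles is not None else _HBondRoles(topology)
    coords = np.asarray(frame, dtype=float)

    g = nx.Graph(frame_index=frame_index, cutoff=cfg.hbond_cutoff)
    for num in roles.residue_numbers:
        g.add_node(num, name=roles.residue_names[num])

    if len(roles.donor_idx) == 0 or len(roles.acceptor_idx) == 0:
        return g

    don_xyz = coords[roles.donor_idx]
    acc_xyz = coords[roles.acceptor_idx]
    pairs = cKDTree(don_xyz).query_ball_tree(cKDTree(acc_xyz), cfg.hbond_cutoff)
    best: dict[tuple[int, int], float] = {}
    for di, acc_list in enumerate(pairs):
        rd = roles.donor_res[di]
        for ai in acc_list:
            ra = roles.acceptor_res[ai]
            if rd == ra:
                continue
            d = float(np.linalg.norm(don_xyz[di] - acc_xyz[ai]))
            if d > cfg.hbond_cutoff:
                continue
            if cfg.hbond_angle_min is not None and not _angle_ok(
                coords, roles, roles.donor_idx[di], rd,
                roles.acceptor_idx[ai], cfg.hbond_angle_min
            ):
                continue
            key = (min(rd, ra), max(rd, ra))
            if d < best.get(key, np.inf):
                best[key] = d
    for (a, b), d in best.items():
        g.add_edge(a, b, distance=d)
    return g


def _angle_ok(coords, roles: _HBondRoles, donor_atom: int, donor_res: int,
              acceptor_atom: int, angle_min: float) -> bool:
    """D-H...A angle filter; permissive when no explicit H is bonded to D."""
    mask = roles.hydrogen_res == donor_res
    if not mask.any():
        return True
    h_xyz = coords[roles.hydrogen_idx[mask]]
    d_xyz = coords[donor_atom]
    bonded = h_xyz[np.linalg.norm(h_xyz - d_xyz, axis=1) < 1.25]
    if len(bonded) == 0:
        return True
    a_xyz = coords[acceptor_atom]
    for h in bonded:
        v1 = d_xyz - h
        v2 = a_xyz - h
        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        if np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))) >= angle_min:
            return True
    return False


def _lex_shortest_path(g: nx.Graph, source, target) -> list | None:
    """Lexicographically smallest shortest path (by node order)."""
    try:
        d_s = nx.single_source_shortest_path_length(g, source)
        d_t = nx.single_source_shortest_path_length(g, target)
    except nx.NodeNotFound:
        return None
    if target not in d_s:
        return None
    length = d_s[target]
    path = [source]
    v = source
    while v != target:
        nxt = min(
            w for w in g.neighbors(v)
            if d_s.get(w) == d_s[v] + 1
            and d_t.get(w, np.inf) == length - d_s[v] - 1
        )
        path.append(nxt)
        v = nxt
    return path


def _via_constrained_shortest(g: nx.Graph, source, target, via) -> list | None:
    """Minimum-length simple path source->target with ``via`` interior.

    Equivalent to a pair of node-disjoint (except at ``via``) shortest
    paths via->source and via->target; solved exactly as a unit-capacity
    min-cost flow on the node-split digraph.
    """
    d = nx.DiGraph()
    for v in sorted(g.nodes):
        cap = 0 if v in (source, target, via) else 1
        d.add_edge((v, "in"), (v, "out"), capacity=cap, weight=0)
    for u, v in sorted(map(lambda e: tuple(sorted(e)), g.edges())):
        d.add_edge((u, "out"), (v, "in"), capacity=1, weight=1)
        d.add_edge((v, "out"), (u, "in"), capacity=1, weight=1)
    d.add_edge((source, "in"), "SINK", capacity=1, weight=0)
    d.add_edge((target, "in"), "SINK", capacity=1, weight=0)
    d.nodes[(via, "out")]["demand"] = -2
    d.nodes["SINK"]["demand"] = 2
    try:
        _, flow = nx.network_simplex(d)
    except nx.NetworkXUnfeasible:
        return None

    def _walk() -> list:
        leg = [via]
        node = (via, "out")
        while True:
            nxts = sorted(
                (w for w, f in flow[node].items() if f > 0),
                key=lambda w: (w == "SINK", w),
            )
            w = nxts[0]
            flow[node][w] -= 1
            if w == "SINK":
                return leg
            leg.append(w[0])
            node = (w[0], "out") if w[1] == "in" else w
            if w[1] == "in":
                # pass through the split node unless this is an endpoint
                if w[0] in (source, target):
                    flow[(w[0], "in")]["SINK"] -= 1
                    return leg

    leg_a = _walk()
    leg_b = _walk()
    if leg_a[-1] == source:
        to_source, to_target = leg_a, leg_b
    else:
        to_source, to_target = leg_b, leg_a
    return list(reversed(to_source)) + to_target[1:]


def find_interaction_path(g: nx.Graph, source, target,
                          via=None) -> InteractionPath | None:
    """Shortest hydrogen-bond path between two residues.

    With ``via`` given, the search returns the shortest simple path that
    contains ``via`` as an *interior* node (``None`` when no such path
    exists, including when ``via`` is absent from the graph).  Ties are
    broken deterministically, preferring smaller residue numbers.
    """
    if source not in g or target not in g:
        raise ValueError(f"source {source} or target {target} not in graph")
    if source == target:
        return InteractionPath(
            residues=(source,), names=(_node_name(g, source),),
            mediated_by_leu115=False, trivial=True,
        )
    if via is None:
        nodes = _lex_shortest_path(g, source, target)
    else:
        if via not in g or via in (source, target):
            return None
        nodes = _via_constrained_shortest(g, source, target, via)
    if nodes is None:
        return None
    return InteractionPath(
        residues=tuple(nodes),
        names=tuple(_node_name(g, v) for v in nodes),
        mediated_by_leu115=LEU115 in nodes[1:-1],
    )


def _node_name(g: nx.Graph, v) -> str:
    return str(g.nodes[v].get("name", v))


def path_persistence(t: Trajectory, m: MutationSpec, cfg: Config | None = None):
    """Fraction of frames with a Leu115-mediated H-bond path site->His114.

    Returns ``(fraction, best_path)`` where ``best_path`` is the modal path
    among qualifying frames (ties: lexicographically smallest residue
    sequence), or ``None`` when no frame qualifies.
    """
    cfg = cfg or Config()
    if t.n_frames == 0:
        raise ValueError("empty trajectory")
    roles = _HBondRoles(t.topology)
    counts: Counter = Counter()
    paths: dict[tuple, InteractionPath] = {}
    n_hit = 0
    for i in range(t.n_frames):
        g = hbond_graph(t.coords[i], t.topology, cfg, frame_index=i, _roles=roles)
        path = find_interaction_path(g, m.position, HIS114, via=LEU115)
        if path is not None:
            n_hit += 1
            counts[path.residues] += 1
            paths.setdefault(path.residues, path)
    if n_hit == 0:
        return 0.0, None
    best_key = min(counts, key=lambda k: (-counts[k], k))
    return n_hit / t.n_frames, paths[best_key]


# ---------------------------------------------------------------------------
# Solvent-accessible surface area


def shrake_rupley_sasa(frame: np.ndarray, topology: Structure,
                       cfg: Config | None = None,
                       residue_numbers=None) -> dict[int, float]:
    """Per-residue Shrake-Rupley SASA (A^2) of one frame.

    Heavy atoms only; each atom is sampled with ``cfg.sasa_sphere_points``
    quasi-uniform sphere points at radius ``r_vdw + probe`` and a point is
    buried when it falls inside any neighbour's probe-expanded sphere.
    The point lattice is anchored in a molecule-intrinsic principal-axes
    frame, so the (discretized) areas are invariant under global rigid
    motion of the frame.  Restricting ``residue_numbers`` computes the
    (environment-aware) SASA of those residues only.
    """
    cfg = cfg or Config()
    coords = _canonical_orientation(np.asarray(frame, dtype=float))
    probe = cfg.sasa_probe_radius

    heavy_idx, radii, res_of = [], [], []
    i = 0
    for res in topology.residues:
        for a in res.atoms:
            if not a.is_hydrogen:
                if a.element not in VDW_RADII:
                    raise ValueError(
                        f"no van der Waals radius for element {a.element!r} "
                        f"({res.name}{res.number} atom {a.name})"
                    )
                heavy_idx.append(i)
                radii.append(VDW_RADII[a.element])
                res_of.append(res.number)
            i += 1
    heavy_idx = np.array(heavy_idx, dtype=int)
    radii = np.array(radii) + probe
    res_of = np.array(res_of, dtype=int)
    xyz = coords[heavy_idx]

    if residue_numbers is None:
        targets = np.arange(len(heavy_idx))
    else:
        wanted = set(residue_numbers)
        targets = np.nonzero(np.isin(res_of, list(wanted)))[0]

    pts = sphere_points(cfg.sasa_sphere_points)
    tree = cKDTree(xyz)
    r_max = radii.max()
    out: dict[int, float] = {n: 0.0 for n in np.unique(res_of[targets])}
    for ti in targets:
        r_i = radii[ti]
        surface = xyz[ti] + r_i * pts
        neighbours = [j for j in tree.query_ball_point(xyz[ti], r_i + r_max)
                      if j != ti]
        exposed = np.ones(len(pts), dtype=bool)
        for j in neighbours:
            exposed &= (
                np.einsum("ij,ij->i", surface - xyz[j], surface - xyz[j])
                >= radii[j] ** 2
            )
            if not exposed.any():
                break
        area = 4.0 * np.pi * r_i**2 * exposed.mean()
        out[res_of[ti]] += area
    return out


def _canonical_orientation(coords: np.ndarray) -> np.ndarray:
    """Express coordinates in a molecule-fixed principal-axes frame.

    Axis signs are fixed by the third moment of the projections (falling
    back to the raw axis when a projection is near-symmetric), and the
    frame is kept right-handed, so any global rotation + translation of
    the input maps to the same canonical coordinates.
    """
    if len(coords) < 2:
        return coords - coords.mean(axis=0) if len(coords) else coords
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    axes = vt.copy()
    for i in range(2):
        proj = centered @ axes[i]
        if proj @ (proj * proj) < 0.0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return centered @ axes.T


_ARG_SIDECHAIN = ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2")


def nls_features(t: Trajectory, cfg: Config | None = None) -> SASASeries:
    """SASA and compaction of the NLS arginines 31-33, per frame.

    ``mean_total`` and ``mean_gyration`` average the summed SASA and the
    joint side-chain radius of gyration over the analysis window (final
    ``cfg.analysis_window`` fraction of frames).
    """
    cfg = cfg or Config()
    if t.n_frames == 0:
        raise ValueError("empty trajectory")
    for num in NLS_ARG:
        try:
            res = t.topology.residue(num)
        except KeyError:
            raise ValueError(f"no residue numbered {num}: unexpected numbering") from None
        if res.name != "ARG":
            raise ValueError(
                f"residue {num} is {res.name}, expected ARG: the input does "
                f"not use mature-angiogenin numbering"
            )
    index = t.topology.atom_slices()
    side_idx = np.array(
        [index[(num, name)] for num in NLS_ARG for name in _ARG_SIDECHAIN
         if (num, name) in index],
        dtype=int,
    )

    per_res = {num: np.empty(t.n_frames) for num in NLS_ARG}
    gyration = np.empty(t.n_frames)
    for i in range(t.n_frames):
        sasa = shrake_rupley_sasa(t.coords[i], t.topology, cfg,
                                  residue_numbers=NLS_ARG)
        for num in NLS_ARG:
            per_res[num][i] = sasa[num]
        sc = t.coords[i][side_idx]
        gyration[i] = np.sqrt(np.mean(np.sum((sc - sc.mean(axis=0)) ** 2, axis=1)))

    win = cfg.window_slice(t.n_frames)
    total = np.sum([per_res[n] for n in NLS_ARG], axis=0)
    return SASASeries(
        times=t.times_ps,
        per_residue=per_res,
        rrr_gyration=gyration,
        mean_total=float(total[win].mean()),
        mean_gyration=float(gyration[win].mean()),
    )


# ---------------------------------------------------------------------------
# Aggregation and export


def extract_features(t: Trajectory, m: MutationSpec | None = None,
                     cfg: Config | None = None) -> FeatureSet:
    """Run all four detectors on one trajectory.

    For a wild-type trajectory pass ``m=None``: the interaction-path
    detector needs a mutation site as source and is skipped.
    """
    cfg = cfg or Config()
    if t.n_frames == 0:
        raise ValueError("empty trajectory")
    fs = FeatureSet(
        rmsd=backbone_rmsd_series(t),
        his114=chi_series(t, HIS114, cfg),
        nls=nls_features(t, cfg),
        mutation=m.token if m is not None else None,
        config=cfg,
    )
    if m is not None:
        fs.path_persistence, fs.best_path = path_persistence(t, m, cfg)
    return fs


def write_hbond_edgelist(g: nx.Graph, path) -> None:
    """Write a graph as ``residue_a<TAB>residue_b<TAB>distance_A`` lines."""
    with open(path, "w") as fh:
        fh.write("residue_a\tresidue_b\tdistance_A\n")
        for a, b, d in sorted(g.edges(data="distance")):
            fh.write(
                f"{_node_name(g, a).capitalize()}{a}\t"
                f"{_node_name(g, b).capitalize()}{b}\t{d:.3f}\n"
            )
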