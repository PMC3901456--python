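import networkx as nx
import numpy as np
import pytest

from angmut import (
    Config,
    MutationSpec,
    Trajectory,
    backbone_rmsd_series,
    chi_series,
    extract_features,
    find_interaction_path,
    hbond_graph,
    nls_features,
    path_persistence,
    shrake_rupley_sasa,
)
from angmut.constants import K17I_PATH
from angmut.synthdata import SyntheticSpec, generate, make_preset

from conftest import make_structure
from oracles import enumerate_shortest_path, random_graph, two_sphere_sasa


def _rigid(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y*y + z*z), 2 * (x*y - w*z), 2 * (x*z + w*y)],
        [2 * (x*y + w*z), 1 - 2 * (x*x + z*z), 2 * (y*z - w*x)],
        [2 * (x*z - w*y), 2 * (y*z + w*x), 1 - 2 * (x*x + y*y)],
    ])
    return rot, rng.standard_normal(3) * 20


# ---------------------------------------------------------------------------
# Backbone RMSD


def test_rmsd_zero_for_identical_and_rigidly_moved_frames(ang):
    base = ang.coords()
    rng = np.random.default_rng(0)
    frames = [base]
    for _ in range(4):
        rot, trans = _rigid(rng)
        frames.append(base @ rot.T + trans)
    t = Trajectory(ang, np.array(frames))
    series = backbone_rmsd_series(t)
    assert series.values[0] == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(series.values, 0.0, atol=1e-6)
    np.testing.assert_allclose(series.times, np.arange(5))


def test_rmsd_recovers_isotropic_noise_level(ang):
    """Gaussian jitter sigma per axis on every atom gives a predictable
    mean RMSD: sigma*sqrt(3)*sqrt(1 - k/(3N)) with k=6 fitted DOF."""
    sigma = 0.5
    rng = np.random.default_rng(11)
    base = ang.coords()
    frames = [base] + [
        base + rng.normal(0, sigma, base.shape) for _ in range(60)
    ]
    t = Trajectory(ang, np.array(frames))
    series = backbone_rmsd_series(t)
    n_bb = 4 * len(ang.residues)
    expected = sigma * np.sqrt(3.0) * np.sqrt(1.0 - 6.0 / (3.0 * n_bb))
    assert series.values[1:].mean() == pytest.approx(expected, rel=0.05)


def test_rmsd_requires_complete_backbone(ang):
    broken = ang.copy()
    res = broken.residue(50)
    res.atoms = [a for a in res.atoms if a.name != "O"]
    t = Trajectory(broken, broken.coords()[None])
    with pytest.raises(ValueError, match="50"):
        backbone_rmsd_series(t)


# ---------------------------------------------------------------------------
# Chi series


def test_chi_series_static_trajectory_never_switches(ang, cfg):
    t = Trajectory(ang, np.repeat(ang.coords()[None], 5, axis=0))
    cs = chi_series(t, 114, cfg)
    assert cs.switch_fraction == 0.0
    assert len(set(cs.states)) == 1
    assert cs.chi2 is not None  # His has a chi2
    assert np.all(cs.chi1 == cs.chi1[0])


def test_chi_series_recovers_injected_fraction(ang, cfg):
    spec = SyntheticSpec(base=ang, n_frames=40, noise_sigma=0.05,
                         switch_fraction_target=0.30, seed=5)
    cs = chi_series(generate(spec), 114, cfg)
    assert cs.switch_fraction == pytest.approx(0.30, abs=1e-12)


def test_chi_series_missing_sidechain_atom(ang, cfg):
    gly = make_structure([(1, "GLY", [
        ("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
        ("C", "C", (3, 0, 0)), ("O", "O", (3.5, 1, 0)),
    ])])
    t = Trajectory(gly, gly.coords()[None])
    with pytest.raises(ValueError, match="chi1"):
        chi_series(t, 1, cfg)


# ---------------------------------------------------------------------------
# Hydrogen-bond graphs


@pytest.mark.parametrize("distance, expect_edge", [
    (3.1, True), (3.2, True), (3.21, False), (3.3, False),
])
def test_hbond_cutoff_semantics(gly_pair_builder, cfg, distance, expect_edge):
    s = gly_pair_builder(distance)
    g = hbond_graph(s.coords(), s, cfg)
    assert g.has_edge(1, 2) is expect_edge
    if expect_edge:
        assert g.edges[1, 2]["distance"] == pytest.approx(distance)


def test_hbond_graph_single_residue_empty(cfg):
    s = make_structure([(1, "SER", [
        ("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
        ("C", "C", (3, 0, 0)), ("O", "O", (3.5, 1, 0)),
        ("CB", "C", (1.5, 1.5, 0)), ("OG", "O", (1.5, 2.9, 0)),
    ])])
    g = hbond_graph(s.coords(), s, cfg)
    assert g.number_of_edges() == 0
    assert set(g.nodes) == {1}


def test_hbond_graph_monotone_in_cutoff(ang):
    coords = ang.coords()
    edges_small = set(hbond_graph(coords, ang, Config(hbond_cutoff=2.8)).edges)
    edges_large = set(hbond_graph(coords, ang, Config(hbond_cutoff=3.6)).edges)
    norm = lambda es: {tuple(sorted(e)) for e in es}
    assert norm(edges_small) <= norm(edges_large)


# ---------------------------------------------------------------------------
# Interaction paths


def _graph_from_chain(chain):
    g = nx.Graph()
    g.add_nodes_from(chain)
    nx.add_path(g, chain)
    return g


def test_reported_k17i_path_is_returned_verbatim():
    g = _graph_from_chain(K17I_PATH)
    path = find_interaction_path(g, 17, 114, via=115)
    assert path is not None
    assert path.residues == K17I_PATH
    assert path.mediated_by_leu115


def test_via_absent_from_graph_gives_none():
    g = nx.Graph()
    g.add_edge(17, 114)
    assert find_interaction_path(g, 17, 114, via=115) is None


def test_source_equals_target_is_trivial():
    g = nx.Graph()
    g.add_node(114)
    path = find_interaction_path(g, 114, 114, via=115)
    assert path.trivial and path.residues == (114,)


def test_path_search_matches_bruteforce_on_random_graphs():
    rng = np.random.default_rng(2024)
    n_checked = 0
    for _ in range(100):
        adj = random_graph(rng)
        g = nx.Graph()
        g.add_nodes_from(adj)
        g.add_edges_from((u, v) for u in adj for v in adj[u] if u < v)
        nodes = sorted(adj)
        source, target, via = rng.choice(nodes, size=3, replace=False)
        expected = enumerate_shortest_path(adj, source, target, via=via)
        got = find_interaction_path(g, int(source), int(target), via=int(via))
        if expected is None:
            assert got is None
        else:
            assert got is not None
            assert len(got.residues) == len(expected)
            assert got.residues[0] == source and got.residues[-1] == target
            assert via in got.residues[1:-1]
            n_checked += 1
        # unconstrained search agrees with enumeration too
        exp_free = enumerate_shortest_path(adj, source, target)
        got_free = find_interaction_path(g, int(source), int(target))
        assert (got_free is None) == (exp_free is None)
        if exp_free is not None:
            assert len(got_free.residues) == len(exp_free)
    assert n_checked > 10  # the suite actually exercised constrained paths


def test_path_persistence_zero_without_paths(ang, cfg):
    spec = SyntheticSpec(base=ang, n_frames=10, noise_sigma=0.05, seed=1)
    frac, best = path_persistence(generate(spec), MutationSpec.parse("K17I"), cfg)
    assert frac == 0.0 and best is None


def test_path_persistence_recovers_injection(ang, cfg):
    spec = SyntheticSpec(base=ang, n_frames=40, noise_sigma=0.05,
                         path_persistence_target=0.40,
                         path_residues=K17I_PATH, seed=9)
    frac, best = path_persistence(generate(spec), MutationSpec.parse("K17I"), cfg)
    assert frac == pytest.approx(0.40, abs=1e-12)
    assert best is not None and best.mediated_by_leu115
    assert best.residues[0] == 17 and best.residues[-1] == 114


# ---------------------------------------------------------------------------
# SASA


def test_sasa_isolated_atom_is_probe_expanded_sphere(cfg):
    s = make_structure([(1, "UNK", [("C1", "C", (0, 0, 0))])])
    area = shrake_rupley_sasa(s.coords(), s, cfg)[1]
    assert area == pytest.approx(4 * np.pi * 3.1**2, rel=0.01)


def test_sasa_distant_atoms_unperturbed(cfg):
    s = make_structure([
        (1, "UNK", [("C1", "C", (0, 0, 0))]),
        (2, "UNK", [("C1", "C", (20.0, 0, 0))]),
    ])
    areas = shrake_rupley_sasa(s.coords(), s, cfg)
    iso = 4 * np.pi * 3.1**2
    assert areas[1] == pytest.approx(iso, rel=0.01)
    assert areas[2] == pytest.approx(iso, rel=0.01)


@pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
def test_sasa_overlapping_pair_matches_cap_formula(cfg, d):
    s = make_structure([
        (1, "UNK", [("C1", "C", (0, 0, 0))]),
        (2, "UNK", [("N1", "N", (d, 0, 0))]),
    ])
    areas = shrake_rupley_sasa(s.coords(), s, cfg)
    a1, a2 = two_sphere_sasa(1.70, 1.55, d, probe=1.4)
    assert areas[1] == pytest.approx(a1, rel=0.02)
    assert areas[2] == pytest.approx(a2, rel=0.02)


def test_sasa_unknown_element_rejected(cfg):
    s = make_structure([(1, "UNK", [("FE", "FE", (0, 0, 0))])])
    with pytest.raises(ValueError, match="FE"):
        shrake_rupley_sasa(s.coords(), s, cfg)


def test_sasa_agrees_with_biotite(ang, cfg):
    struc = pytest.importorskip("biotite.structure")
    from angmut.constants import VDW_RADII

    arr = struc.AtomArray(ang.n_atoms)
    arr.coord = ang.coords()
    radii = np.empty(ang.n_atoms)
    i = 0
    for r in ang.residues:
        for a in r.atoms:
            arr.chain_id[i] = "A"
            arr.res_id[i] = r.number
            arr.res_name[i] = r.name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
            radii[i] = VDW_RADII[a.element]
            i += 1
    reference = struc.sasa(arr, probe_radius=cfg.sasa_probe_radius,
                           point_number=960, vdw_radii=radii)
    ours = shrake_rupley_sasa(ang.coords(), ang, cfg, residue_numbers=(31, 32, 33))
    for num in (31, 32, 33):
        assert ours[num] == pytest.approx(
            float(reference[arr.res_id == num].sum()), rel=0.02
        )


def test_sasa_invariant_under_rigid_motion(cfg):
    rng = np.random.default_rng(5)
    s = make_structure([
        (1, "UNK", [("C1", "C", (0, 0, 0)), ("N1", "N", (2.5, 0, 0))]),
        (2, "UNK", [("O1", "O", (1.0, 2.0, 0.5))]),
    ])
    before = shrake_rupley_sasa(s.coords(), s, cfg)
    rot, trans = _rigid(rng)
    after = shrake_rupley_sasa(s.coords() @ rot.T + trans, s, cfg)
    for key in before:
        assert after[key] == pytest.approx(before[key], rel=1e-6)


# ---------------------------------------------------------------------------
# NLS features and aggregation


def test_nls_constant_for_static_trajectory(ang, cfg):
    t = Trajectory(ang, np.repeat(ang.coords()[None], 4, axis=0))
    series = nls_features(t, cfg)
    for num in (31, 32, 33):
        assert np.ptp(series.per_residue[num]) == pytest.approx(0.0, abs=1e-9)
    assert np.ptp(series.rrr_gyration) == pytest.approx(0.0, abs=1e-12)
    assert series.mean_total == pytest.approx(series.total[0])


def test_nls_compaction_lowers_sasa_and_gyration(ang, cfg):
    plain = SyntheticSpec(base=ang, n_frames=6, noise_sigma=0.05, seed=3)
    packed = SyntheticSpec(base=ang, n_frames=6, noise_sigma=0.05, seed=3,
                           compaction_factor=0.3)
    a = nls_features(generate(plain), cfg)
    b = nls_features(generate(packed), cfg)
    assert b.mean_total < a.mean_total
    assert b.mean_gyration < a.mean_gyration


def test_nls_rejects_wrong_numbering(cfg):
    from angmut.modelbuild import build_peptide

    s = build_peptide("GGGG")  # residues 1-4, no arginines at 31-33
    t = Trajectory(s, s.coords()[None])
    with pytest.raises(ValueError, match="numbering"):
        nls_features(t, cfg)


def test_extract_features_wild_type_has_no_path_fields(ang, cfg):
    t = generate(SyntheticSpec(base=ang, n_frames=6, noise_sigma=0.05, seed=2))
    fs = extract_features(t, None, cfg)
    assert fs.path_persistence is None and fs.best_path is None
    assert fs.his114.switch_fraction == 0.0
    assert fs.mutation is None


def test_extract_features_rejects_empty_trajectory(ang, cfg):
    t = Trajectory(ang, np.empty((0, ang.n_atoms, 3)))
    with pytest.raises(ValueError, match="empty"):
        extract_features(t, None, cfg)


def test_features_invariant_under_global_rigid_motion(ang, cfg):
    rng = np.random.default_rng(8)
    t = generate(SyntheticSpec(base=ang, n_frames=5, noise_sigma=0.05,
                               switch_fraction_target=0.4, seed=4))
    rot, trans = _rigid(rng)
    moved = Trajectory(ang.copy(), t.coords @ rot.T + trans, dt_ps=t.dt_ps)
    a = extract_features(t, None, cfg)
    b = extract_features(moved, None, cfg)
    np.testing.assert_allclose(b.rmsd.values, a.rmsd.values, atol=1e-6)
    np.testing.assert_allclose(b.his114.chi1, a.his114.chi1, atol=1e-6)
    np.testing.assert_allclose(b.nls.rrr_gyration, a.nls.rrr_gyration, rtol=1e-9)
    assert b.nls.mean_total == pytest.approx(a.nls.mean_total, rel=1e-6)
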