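"""Independent reference implementations used only to check the package.

These deliberately share no code with the implementation under test:
superposition RMSD via the quaternion characteristic-polynomial method,
path search via exhaustive simple-path enumeration, and sphere overlap via
the closed-form spherical-cap area.
"""

import itertools

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over rigid motions via the quaternion (Horn) method."""
    x = np.asarray(mobile, float)
    y = np.asarray(reference, float)
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    n = len(x)
    m = x.T @ y
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = (x**2).sum() + (y**2).sum()
    return float(np.sqrt(max(e0 - 2.0 * lam, 0.0) / n))


def enumerate_shortest_path(graph, source, target, via=None):
    """Shortest simple path by exhaustive enumeration; None if unreachable.

    With ``via`` set, only paths with ``via`` strictly interior qualify.
    ``graph`` is an adjacency mapping node -> iterable of neighbours.
    """
    best = None
    nodes = sorted(graph)
    if source not in nodes or target not in nodes:
        return None

    def extend(path):
        nonlocal best
        tip = path[-1]
        if tip == target:
            if via is None or via in path[1:-1]:
                if best is None or len(path) < len(best):
                    best = list(path)
            return
        if best is not None and len(path) >= len(best):
            return
        for nxt in sorted(graph[tip]):
            if nxt not in path:
                path.append(nxt)
                extend(path)
                path.pop()

    extend([source])
    return best


def two_sphere_sasa(r1: float, r2: float, d: float, probe: float):
    """Analytic accessible areas of two overlapping probe-expanded spheres."""
    e1, e2 = r1 + probe, r2 + probe
    full1, full2 = 4 * np.pi * e1**2, 4 * np.pi * e2**2
    if d >= e1 + e2:
        return full1, full2
    # cap heights from the radical plane
    h1 = e1 - (d**2 + e1**2 - e2**2) / (2 * d)
    h2 = e2 - (d**2 + e2**2 - e1**2) / (2 * d)
    return full1 - 2 * np.pi * e1 * h1, full2 - 2 * np.pi * e2 * h2


def random_graph(rng, max_nodes=15, p=0.25):
    n = rng.integers(4, max_nodes + 1)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            adj[i].add(j)
            adj[j].add(i)
    return adj
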