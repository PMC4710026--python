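"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a different, slower route than the
implementation under test (exhaustive enumeration, flood-fill,
closed-form geometry) so agreement is a meaningful check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def mesh_graph(mesh) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(mesh.n_vertices))
    g.add_edges_from(map(tuple, mesh.edges_unique))
    return g


def brute_superlevel_pairs(mesh, values):
    """Persistence pairs of the superlevel filtration by incremental
    recomputation of connected components with networkx.

    Returns ``(pairs, merged_into)`` where pairs is a set of
    ``(max_vertex, saddle_vertex, persistence)`` and merged_into maps each
    paired maximum to the older maximum whose component absorbed it.
    """
    n = len(values)
    order = sorted(range(n), key=lambda v: (values[v], v), reverse=True)
    g_full = mesh_graph(mesh)
    active = set()
    sub = nx.Graph()
    comp_of = {}
    pairs = set()
    merged = {}
    rank = {v: (values[v], v) for v in range(n)}
    for v in order:
        sub.add_node(v)
        for u in g_full.neighbors(v):
            if u in active:
                sub.add_edge(v, u)
        active.add(v)
        # recompute components from scratch (the slow, independent route)
        comps = list(nx.connected_components(sub))
        # identify maxima of each component: highest (value, index) vertex
        new_comp_of = {}
        for comp in comps:
            m = max(comp, key=lambda x: rank[x])
            for x in comp:
                new_comp_of[x] = m
        # a merge happened if v's component contains >1 previous maxima
        prev_maxima = {comp_of[u] for u in sub.neighbors(v) if u in comp_of}
        if len(prev_maxima) >= 2:
            winner = max(prev_maxima, key=lambda x: rank[x])
            for m in prev_maxima:
                if m != winner:
                    pairs.add((m, v, values[m] - values[v]))
                    merged[m] = winner
        comp_of = new_comp_of
    return pairs, merged


def brute_ascent_labels(mesh, values):
    """Steepest-ascent assignment recomputed vertex by vertex."""
    adj = {v: set() for v in range(mesh.n_vertices)}
    for a, b in mesh.edges_unique:
        adj[int(a)].add(int(b))
        adj[int(b)].add(int(a))
    rank = lambda v: (values[v], v)
    out = np.empty(mesh.n_vertices, dtype=np.int64)
    for v in range(mesh.n_vertices):
        cur = v
        while True:
            best = max(adj[cur] | {cur}, key=rank)
            if best == cur:
                break
            cur = best
        out[v] = cur
    return out


def brute_maximal_cliques(graph: nx.Graph, min_size: int = 3):
    """All maximal cliques by 2^n subset enumeration."""
    nodes = list(graph.nodes)
    n = len(nodes)
    cliques = []
    for mask in range(1, 1 << n):
        sub = [nodes[i] for i in range(n) if mask >> i & 1]
        if len(sub) < min_size:
            continue
        if all(graph.has_edge(a, b) for a, b in itertools.combinations(sub, 2)):
            # maximal?
            others = [x for x in nodes if x not in sub]
            if not any(
                all(graph.has_edge(o, s) for s in sub) for o in others
            ):
                cliques.append(frozenset(sub))
    return set(cliques)


def brute_nearest_rmsd(a_pts, b_pts, symmetric=True):
    """All-pairs nearest-neighbor RMS distance, O(n*m)."""
    a_pts = np.asarray(a_pts)
    b_pts = np.asarray(b_pts)
    d_ab = np.sqrt(((a_pts[:, None, :] - b_pts[None, :, :]) ** 2).sum(axis=2))
    fwd = d_ab.min(axis=1)
    if not symmetric:
        return float(np.sqrt(np.mean(fwd**2)))
    bwd = d_ab.min(axis=0)
    d = np.concatenate([fwd, bwd])
    return float(np.sqrt(np.mean(d**2)))


def implicit_mean_curvature(grad, hess):
    """Mean curvature of an implicit surface F=0 from gradient and
    Hessian, with the convention that convex surfaces (outward gradient)
    have positive H.  Closed form:

        H = -(g^T Hf g - |g|^2 tr(Hf)) / (2 |g|^3)
    """
    g = np.asarray(grad, dtype=float)
    Hf = np.asarray(hess, dtype=float)
    gn = np.linalg.norm(g)
    return -(g @ Hf @ g - gn**2 * np.trace(Hf)) / (2.0 * gn**3)


def ellipsoid_mean_curvature(p, abc):
    """Closed-form mean curvature of x^2/a^2+y^2/b^2+z^2/c^2=1 at a
    surface point, positive convex."""
    a, b, c = abc
    x, y, z = p
    grad = np.array([2 * x / a**2, 2 * y / b**2, 2 * z / c**2])
    hess = np.diag([2 / a**2, 2 / b**2, 2 / c**2])
    return implicit_mean_curvature(grad, hess)
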