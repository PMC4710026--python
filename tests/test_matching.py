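"""Descriptor correspondences, consistency graph, maximal cliques."""

import itertools

import networkx as nx
import numpy as np
import pytest

from curvalign import build_graph, landmark_correspondences, maximal_cliques
from curvalign.curvature import MultiScaleDescriptor
from curvalign.matching import CorrespondenceGraph, iter_cliques
from curvalign.topology import Landmark

from oracles import brute_maximal_cliques


def make_landmark(vertex, position, normal=(0, 0, 1), descriptor=None, area=1.0):
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    if descriptor is not None:
        descriptor = MultiScaleDescriptor(
            vertex=vertex,
            scales=np.linspace(1.0, 2.0, len(descriptor)),
            values=np.asarray(descriptor, dtype=float),
        )
    return Landmark(
        vertex=vertex,
        position=np.asarray(position, dtype=float),
        normal=normal,
        value=1.0,
        persistence=1.0,
        area=area,
        descriptor=descriptor,
    )


def random_landmarks(rng, n, start=0):
    out = []
    for i in range(n):
        nrm = rng.standard_normal(3)
        out.append(
            make_landmark(
                start + i,
                rng.uniform(-10, 10, 3),
                nrm,
                rng.uniform(0, 1, 15),
            )
        )
    return out


class TestCorrespondences:
    def test_self_match_includes_identity_pairs(self):
        rng = np.random.default_rng(0)
        lms = random_landmarks(rng, 5)
        corr = landmark_correspondences(lms, lms, t_ms=1e-6, curvature_scale=1.0)
        keys = {(c.p.vertex, c.q.vertex) for c in corr}
        assert {(l.vertex, l.vertex) for l in lms} <= keys

    def test_exact_threshold_excluded(self):
        a = make_landmark(0, [0, 0, 0], descriptor=np.zeros(15))
        vals = np.zeros(15)
        vals[7] = 0.05  # difference exactly t_ms * scale
        b = make_landmark(1, [1, 0, 0], descriptor=vals)
        corr = landmark_correspondences([a], [b], t_ms=0.1, curvature_scale=0.5)
        assert corr == []
        corr = landmark_correspondences([a], [b], t_ms=0.1, curvature_scale=0.5 + 1e-9)
        assert len(corr) == 1

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(42)
        lp = random_landmarks(rng, 5)
        lq = random_landmarks(rng, 6, start=100)
        t_ms, scale = 0.3, 1.2
        got = {
            (c.p.vertex, c.q.vertex)
            for c in landmark_correspondences(lp, lq, t_ms, scale)
        }
        expect = set()
        for p in lp:
            for q in lq:
                if np.max(np.abs(p.descriptor.values - q.descriptor.values)) < t_ms * scale:
                    expect.add((p.vertex, q.vertex))
        assert got == expect

    def test_empty_side_warns(self):
        with pytest.warns(UserWarning):
            assert landmark_correspondences([], [], 0.1, 1.0) == []


class TestConsistencyGraph:
    def _identity_corr(self, rng, n):
        from curvalign.matching import Correspondence

        return [Correspondence(p=l, q=l) for l in random_landmarks(rng, n)]

    def test_identity_correspondences_complete_graph(self):
        rng = np.random.default_rng(1)
        corr = self._identity_corr(rng, 6)
        g = build_graph(corr, t_mrd=1.0)
        n = len(corr)
        assert g.n_edges == n * (n - 1) // 2

    def test_distance_bound_strict(self):
        a1 = make_landmark(0, [0, 0, 0])
        a2 = make_landmark(1, [10, 0, 0])
        b1 = make_landmark(10, [0, 0, 0])
        t_mrd = 0.5
        from curvalign.matching import Correspondence

        for gap, expect_edge in ((t_mrd, False), (t_mrd - 1e-9, True)):
            b2 = make_landmark(11, [10 + gap, 0, 0])
            g = build_graph(
                [Correspondence(a1, b1), Correspondence(a2, b2)], t_mrd
            )
            assert (g.n_edges == 1) == expect_edge

    def test_normal_angle_bound(self):
        from curvalign.matching import Correspondence

        a1 = make_landmark(0, [0, 0, 0], normal=[0, 0, 1])
        a2 = make_landmark(1, [5, 0, 0], normal=[0, 0, 1])  # angle 0 on P
        b1 = make_landmark(10, [0, 0, 0], normal=[0, 0, 1])
        b2 = make_landmark(11, [5, 0, 0], normal=[0, 0, -1])  # angle pi on Q
        g = build_graph([Correspondence(a1, b1), Correspondence(a2, b2)], 10.0)
        assert g.n_edges == 0  # |0 - pi| >= pi/2

    def test_shared_landmark_never_connected(self):
        from curvalign.matching import Correspondence

        p = make_landmark(0, [0, 0, 0])
        q1 = make_landmark(10, [0, 0, 0])
        q2 = make_landmark(11, [0.1, 0, 0])
        g = build_graph([Correspondence(p, q1), Correspondence(p, q2)], 10.0)
        assert g.n_edges == 0

    def test_adjacency_matches_bruteforce(self):
        from curvalign.matching import Correspondence

        rng = np.random.default_rng(7)
        lp = random_landmarks(rng, 8)
        lq = random_landmarks(rng, 8, start=100)
        corr = [Correspondence(p, q) for p, q in zip(lp, lq)]
        t_mrd = 3.0
        g = build_graph(corr, t_mrd)
        for i, j in itertools.combinations(range(len(corr)), 2):
            ci, cj = corr[i], corr[j]
            dp = np.linalg.norm(ci.p.position - cj.p.position)
            dq = np.linalg.norm(ci.q.position - cj.q.position)
            ang_p = np.arccos(np.clip(ci.p.normal @ cj.p.normal, -1, 1))
            ang_q = np.arccos(np.clip(ci.q.normal @ cj.q.normal, -1, 1))
            expect = (
                abs(dp - dq) < t_mrd
                and abs(ang_p - ang_q) < np.pi / 2
                and ci.p.vertex != cj.p.vertex
                and ci.q.vertex != cj.q.vertex
            )
            assert g.graph.has_edge(i, j) == expect

    def test_monotonic_in_t_mrd(self):
        from curvalign.matching import Correspondence

        rng = np.random.default_rng(9)
        corr = [
            Correspondence(p, q)
            for p, q in zip(
                random_landmarks(rng, 10), random_landmarks(rng, 10, 100)
            )
        ]
        e_small = set(build_graph(corr, 1.0).graph.edges)
        e_big = set(build_graph(corr, 5.0).graph.edges)
        assert e_small <= e_big


def graph_from_nx(g: nx.Graph) -> CorrespondenceGraph:
    return CorrespondenceGraph(
        correspondences=list(range(g.number_of_nodes())), graph=g, t_mrd=1.0
    )


class TestMaximalCliques:
    def test_complete_graph_single_clique(self):
        g = graph_from_nx(nx.complete_graph(5))
        res = maximal_cliques(g)
        assert not res.truncated
        assert len(res.cliques) == 1
        assert res.cliques[0].size == 5

    def test_five_cycle_has_no_triangle(self):
        g = graph_from_nx(nx.cycle_graph(5))
        res = maximal_cliques(g)
        assert res.cliques == []

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 16))
        g = nx.gnp_random_graph(n, 0.5, seed=seed)
        res = maximal_cliques(graph_from_nx(g))
        got = {frozenset(c.correspondences) for c in res.cliques}
        assert got == brute_maximal_cliques(g)

    def test_every_reported_clique_is_maximal(self):
        g = nx.gnp_random_graph(12, 0.6, seed=3)
        res = maximal_cliques(graph_from_nx(g))
        for c in res.cliques:
            members = set(c.correspondences)
            outside = set(g.nodes) - members
            assert not any(
                all(g.has_edge(o, m) for m in members) for o in outside
            )

    def test_cap_sets_truncation_flag(self):
        g = graph_from_nx(nx.complete_multipartite_graph(2, 2, 2, 2))
        full = maximal_cliques(g)
        capped = maximal_cliques(g, max_cliques=3)
        assert not full.truncated
        assert capped.truncated
        assert len(capped.cliques) == 3

    def test_mirror_symmetry_under_role_swap(self):
        from curvalign.matching import Correspondence

        rng = np.random.default_rng(15)
        lp = random_landmarks(rng, 7)
        lq = random_landmarks(rng, 7, start=100)
        corr = [Correspondence(p, q) for p, q in zip(lp, lq)]
        mirror = [Correspondence(c.q, c.p) for c in corr]
        res_f = maximal_cliques(build_graph(corr, 4.0))
        res_m = maximal_cliques(build_graph(mirror, 4.0))
        keys_f = {
            frozenset((c.p.vertex, c.q.vertex) for c in cl.correspondences)
            for cl in res_f.cliques
        }
        keys_m = {
            frozenset((c.q.vertex, c.p.vertex) for c in cl.correspondences)
            for cl in res_m.cliques
        }
        assert keys_f == keys_m
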