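"""Landmark correspondence search and geometric-consistency cliques.

Two landmarks correspond when their multi-scale curvature descriptors
agree at every scale to within ``T_ms`` times a curvature scale (the mean
of the two surfaces' average positive-maximum curvatures, keeping the
criterion symmetric in P and Q).  Correspondences become nodes of a
consistency graph: an edge joins two correspondences when the pairwise
landmark distances agree within ``T_mrd`` and the pairwise normal angles
agree within pi/2, and the correspondences share no landmark.  Every
maximal clique of that graph with at least three members is a candidate
correspondence set for a rigid fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterator, NamedTuple

import networkx as nx
import numpy as np

from .topology import Landmark

MIN_CLIQUE_SIZE = 3
MAX_CLIQUES = 10**6
NORMAL_ANGLE_TOL = math.pi / 2


@dataclass(frozen=True)
class Correspondence:
    p: Landmark
    q: Landmark

    @property
    def key(self):
        return (self.p.vertex, self.q.vertex)


class CorrespondenceGraph:
    """Consistency graph over correspondences (thin networkx wrapper)."""

    def __init__(self, correspondences, graph: nx.Graph, t_mrd: float):
        self.correspondences = list(correspondences)
        self.graph = graph
        self.t_mrd = t_mrd

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class MaximalCorrespondenceSet:
    """A maximal clique of mutually consistent correspondences."""

    correspondences: list

    @property
    def size(self) -> int:
        return len(self.correspondences)

    @property
    def key(self):
        return tuple(
            sorted(
                c.key if isinstance(c, Correspondence) else c
                for c in self.correspondences
            )
        )


class CliqueEnumeration(NamedTuple):
    cliques: list
    truncated: bool


def landmark_correspondences(
    lp: list[Landmark],
    lq: list[Landmark],
    t_ms: float,
    curvature_scale: float,
) -> list[Correspondence]:
    """All landmark pairs whose descriptors differ by less than
    ``t_ms * curvature_scale`` at every scale (strict inequality)."""
    if not lp or not lq:
        warnings.warn("empty landmark list: no correspondences")
        return []
    dp = np.array([lm.descriptor.values for lm in lp])
    dq = np.array([lm.descriptor.values for lm in lq])
    if dp.shape[1] != dq.shape[1]:
        raise ValueError("descriptor lengths differ between surfaces")
    diff = np.abs(dp[:, None, :] - dq[None, :, :]).max(axis=2)
    keep = diff < t_ms * curvature_scale
    out = []
    for i, j in zip(*np.nonzero(keep)):
        out.append(Correspondence(p=lp[i], q=lq[j]))
    return out


def build_graph(
    correspondences: list[Correspondence], t_mrd: float
) -> CorrespondenceGraph:
    """Consistency graph: edges satisfy the relative-distance bound
    (strict ``< t_mrd``), the normal-angle bound (strict ``< pi/2``) and
    landmark disjointness."""
    n = len(correspondences)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if n:
        pp = np.array([c.p.position for c in correspondences])
        qq = np.array([c.q.position for c in correspondences])
        pn = np.array([c.p.normal for c in correspondences])
        qn = np.array([c.q.normal for c in correspondences])
        pv = np.array([c.p.vertex for c in correspondences])
        qv = np.array([c.q.vertex for c in correspondences])
        dpp = np.linalg.norm(pp[:, None, :] - pp[None, :, :], axis=2)
        dqq = np.linalg.norm(qq[:, None, :] - qq[None, :, :], axis=2)
        ok_dist = np.abs(dpp - dqq) < t_mrd
        ang_p = np.arccos(np.clip(pn @ pn.T, -1.0, 1.0))
        ang_q = np.arccos(np.clip(qn @ qn.T, -1.0, 1.0))
        ok_ang = np.abs(ang_p - ang_q) < NORMAL_ANGLE_TOL
        distinct = (pv[:, None] != pv[None, :]) & (qv[:, None] != qv[None, :])
        adj = ok_dist & ok_ang & distinct
        iu, ju = np.nonzero(np.triu(adj, k=1))
        g.add_edges_from(zip(iu.tolist(), ju.tolist()))
    return CorrespondenceGraph(correspondences, g, t_mrd)


def iter_cliques(
    graph: CorrespondenceGraph, min_size: int = MIN_CLIQUE_SIZE
) -> Iterator[MaximalCorrespondenceSet]:
    """Yield maximal cliques of at least ``min_size`` correspondences.

    Enumeration is Bron-Kerbosch with pivoting (networkx ``find_cliques``),
    deterministic given node order.
    """
    nodes = graph.correspondences
    for clique in nx.find_cliques(graph.graph):
        if len(clique) >= min_size:
            members = [nodes[i] for i in sorted(clique)]
            yield MaximalCorrespondenceSet(correspondences=members)


def maximal_cliques(
    graph: CorrespondenceGraph,
    max_cliques: int = MAX_CLIQUES,
    min_size: int = MIN_CLIQUE_SIZE,
) -> CliqueEnumeration:
    """Collect maximal cliques up to a cap; sets ``truncated`` instead of
    raising when the cap is reached."""
    out = []
    truncated = False
    for i, cl in enumerate(iter_cliques(graph, min_size)):
        if i >= max_cliques:
            truncated = True
            break
        out.append(cl)
    out.sort(key=lambda c: c.key)
    return CliqueEnumeration(cliques=out, truncated=truncated)
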