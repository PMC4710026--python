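"""Landmark extraction from the curvature field by discrete Morse theory.

Protrusions are the maxima of the mean-curvature field.  Their
significance is topological persistence: sweeping the superlevel sets of
the field from high to low, each non-global maximum dies at the saddle
where its component merges into a component born earlier, and its
persistence is the value gap between the two.  Maxima whose persistence
falls below ``T_s`` times the average curvature over the initial positive
maxima are cancelled; each cancelled maximum hands its descending
manifold (the vertices whose steepest-ascent paths reach it) to the
surviving maximum it merged into, following the pairing chain.  The
survivors with positive curvature are the landmarks, each carrying its
region area and a multi-scale curvature descriptor.

Ties in field value are broken by vertex index (simulation of
simplicity), so every step is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .curvature import (
    CurvatureField,
    MultiScaleDescriptor,
    N_SCALES,
    multiscale_descriptors,
)


@dataclass(frozen=True)
class CriticalPoint:
    vertex: int
    kind: str  # "maximum" | "saddle" | "minimum"
    value: float


@dataclass(frozen=True)
class PersistencePair:
    """A maximum paired with the saddle where its superlevel component
    merges into an older one; ``merged_into`` is that older maximum."""

    maximum: CriticalPoint
    saddle: CriticalPoint
    persistence: float
    merged_into: int

    def __post_init__(self):
        if self.persistence < 0:
            raise ValueError("persistence must be non-negative")


@dataclass
class Landmark:
    """A persistence-surviving positive-curvature maximum."""

    vertex: int
    position: np.ndarray
    normal: np.ndarray
    value: float
    persistence: float  # inf for the global maximum
    area: float  # descending-manifold area, merged regions included
    descriptor: MultiScaleDescriptor | None = None


@dataclass
class SurfaceLandmarks:
    """Landmarks of one surface plus the per-surface normalisation data
    needed downstream (total area and the positive-maxima curvature mean
    that scales the T_s / T_ms thresholds)."""

    landmarks: list
    total_area: float
    curvature_scale: float
    radius: float


def _total_order_ranks(field: CurvatureField) -> np.ndarray:
    """Bijective rank of each vertex under the (interior, value, index)
    total order.

    Open-boundary vertices have incomplete 1-rings, so comparing them as
    if they were interior makes the mesh rim sprout spurious maxima that
    capture descending-manifold area without representing any real
    protrusion.  Sorting every boundary vertex below every interior one
    makes the boundary flow inward — the usual convention for gradient
    fields on surfaces with boundary — while meshes without boundary
    (and all-boundary fixtures like open strips) reduce to the plain
    (value, index) order.
    """
    n = len(field.H)
    interior = ~field.mesh.boundary_vertices
    order = np.lexsort((np.arange(n), field.H, interior))
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return ranks


def _steepest_ascent_successor(field: CurvatureField, ranks: np.ndarray) -> np.ndarray:
    """For each vertex, the 1-ring neighbor (or itself) with highest rank."""
    mesh = field.mesh
    indptr, nbrs = mesh.vertex_adjacency
    n = mesh.n_vertices
    best = ranks.copy()
    counts = np.diff(indptr)
    owner = np.repeat(np.arange(n), counts)
    nbr_rank = ranks[nbrs]
    np.maximum.at(best, owner, nbr_rank)
    order = np.empty(n, dtype=np.int64)
    order[ranks] = np.arange(n)  # rank -> vertex
    return order[best]


def find_critical_maxima(field: CurvatureField) -> list[CriticalPoint]:
    """All strict 1-ring maxima under the (value, index) total order."""
    ranks = _total_order_ranks(field)
    succ = _steepest_ascent_successor(field, ranks)
    vids = np.nonzero(succ == np.arange(len(succ)))[0]
    return [
        CriticalPoint(vertex=int(v), kind="maximum", value=float(field.H[v]))
        for v in vids
    ]


def persistence_pairs(field: CurvatureField) -> list[PersistencePair]:
    """Superlevel-set filtration pairing by union-find.

    Vertices are processed in decreasing (value, index) order.  When the
    current vertex joins two or more existing components, each younger
    component's maximum is paired with the current vertex (the saddle);
    the component whose maximum is oldest survives.  The global maximum
    never pairs (infinite persistence).
    """
    mesh = field.mesh
    H = field.H
    ranks = _total_order_ranks(field)
    n = mesh.n_vertices
    order = np.empty(n, dtype=np.int64)
    order[ranks] = np.arange(n)
    sweep = order[::-1]  # decreasing rank

    indptr, nbrs = mesh.vertex_adjacency
    parent = np.arange(n)

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    comp_max = np.full(n, -1, dtype=np.int64)  # root -> maximum vertex
    processed = np.zeros(n, dtype=bool)
    pairs: list[PersistencePair] = []

    for v in sweep:
        roots = []
        for u in nbrs[indptr[v] : indptr[v + 1]]:
            if processed[u]:
                r = find(u)
                if r not in roots:
                    roots.append(r)
        processed[v] = True
        if not roots:
            comp_max[v] = v
            continue
        if len(roots) == 1:
            r = roots[0]
            parent[v] = r
            continue
        # merge event at saddle v
        maxima = [comp_max[r] for r in roots]
        winner = max(maxima, key=lambda m: ranks[m])
        saddle = CriticalPoint(vertex=int(v), kind="saddle", value=float(H[v]))
        for r, m in zip(roots, maxima):
            if m != winner:
                pairs.append(
                    PersistencePair(
                        maximum=CriticalPoint(
                            vertex=int(m), kind="maximum", value=float(H[m])
                        ),
                        saddle=saddle,
                        persistence=float(H[m] - H[v]),
                        merged_into=int(winner),
                    )
                )
        new_root = roots[0]
        for r in roots[1:]:
            parent[r] = new_root
        parent[v] = new_root
        comp_max[new_root] = winner
    return pairs


def steepest_ascent_labels(field: CurvatureField) -> np.ndarray:
    """Maximum reached from each vertex by iterated steepest ascent."""
    ranks = _total_order_ranks(field)
    succ = _steepest_ascent_successor(field, ranks)
    # pointer doubling until fixpoint
    while True:
        nxt = succ[succ]
        if np.array_equal(nxt, succ):
            return succ
        succ = nxt


def positive_maxima_mean(field: CurvatureField) -> float:
    """Mean curvature over the initial local maxima with H > 0 — the
    normalisation basis for the T_s and T_ms thresholds."""
    vals = np.array([c.value for c in find_critical_maxima(field)])
    vals = vals[vals > 0]
    if len(vals) == 0:
        return 0.0
    return float(vals.mean())


def extract_landmarks(
    field: CurvatureField,
    t_s: float,
    n_scales: int = N_SCALES,
    with_descriptors: bool = True,
) -> list[Landmark]:
    """Persistence-simplified positive-curvature maxima with region areas.

    The simplification threshold is ``t_s`` times the mean curvature over
    the initial positive local maxima.  Maxima with persistence at or
    below the threshold are cancelled and their descending-manifold areas
    merge into the surviving maximum reached through the pairing chain.
    """
    if t_s < 0:
        raise ValueError("t_s must be non-negative")
    mesh = field.mesh
    H = field.H
    maxima = find_critical_maxima(field)
    basis = positive_maxima_mean(field)
    if basis <= 0:
        warnings.warn("no positive-curvature maximum: empty landmark list")
        return []
    threshold = t_s * basis

    pairs = persistence_pairs(field)
    pers = {c.vertex: np.inf for c in maxima}
    merge_target = {}
    for p in pairs:
        pers[p.maximum.vertex] = p.persistence
        merge_target[p.maximum.vertex] = p.merged_into

    survivors = {v for v, p in pers.items() if p > threshold}

    def resolve(m):
        while m not in survivors:
            m = merge_target[m]
        return m

    labels = steepest_ascent_labels(field)
    areas = {v: 0.0 for v in survivors}
    va = mesh.vertex_areas
    resolved_cache = {}
    for m in pers:
        resolved_cache[m] = resolve(m)
    label_area = {}
    for m in pers:
        label_area[m] = 0.0
    # accumulate vertex areas per initial maximum, then merge via chains
    uniq, inv = np.unique(labels, return_inverse=True)
    sums = np.zeros(len(uniq))
    np.add.at(sums, inv, va)
    for m, s in zip(uniq, sums):
        areas[resolved_cache[int(m)]] += float(s)

    landmark_vertices = sorted(v for v in survivors if H[v] > 0)
    descriptors = {}
    if with_descriptors and landmark_vertices:
        for d in multiscale_descriptors(
            mesh, landmark_vertices, field.radius, n_scales
        ):
            descriptors[d.vertex] = d
    out = []
    for v in landmark_vertices:
        out.append(
            Landmark(
                vertex=int(v),
                position=mesh.vertices[v].copy(),
                normal=mesh.vertex_normals[v].copy(),
                value=float(H[v]),
                persistence=float(pers[v]),
                area=areas[v],
                descriptor=descriptors.get(v),
            )
        )
    return out


def compute_landmarks(
    mesh,
    r_c: float,
    t_s: float,
    n_scales: int = N_SCALES,
    field: CurvatureField | None = None,
) -> SurfaceLandmarks:
    """Full stage i-ii run for one surface: curvature field, landmarks,
    and the per-surface normalisation scalars used by the matcher."""
    from .curvature import mean_curvature_field

    if field is None:
        field = mean_curvature_field(mesh, r_c)
    landmarks = extract_landmarks(field, t_s, n_scales=n_scales)
    return SurfaceLandmarks(
        landmarks=landmarks,
        total_area=mesh.total_area,
        curvature_scale=positive_maxima_mean(field),
        radius=field.radius,
    )


def landmark_table(landmarks: list[Landmark]) -> str:
    """Tabular text export: one row per landmark (vertex id, position,
    normal, H, persistence, area, descriptor values)."""
    lines = []
    header = (
        ["vertex", "x", "y", "z", "nx", "ny", "nz", "H", "persistence", "area"]
        + [f"d{k}" for k in range(N_SCALES)]
    )
    lines.append("\t".join(header))
    for lm in landmarks:
        row = [str(lm.vertex)]
        row += [f"{c:.9g}" for c in lm.position]
        row += [f"{c:.9g}" for c in lm.normal]
        row += [f"{lm.value:.9g}", f"{lm.persistence:.9g}", f"{lm.area:.9g}"]
        if lm.descriptor is not None:
            row += [f"{v:.9g}" for v in lm.descriptor.values]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
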