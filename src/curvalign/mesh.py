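"""Triangle-mesh data model, standard-format I/O and derived geometry.

The mesh is the fundamental container of the pipeline: an oriented triangle
surface in Angstrom units with per-vertex outward normals and barycentric
vertex areas.  Density maps (cryo-EM style scalar grids) are supported as a
second input route; a molecular surface is obtained from them as the
iso-surface at a stated density value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import MeshFormatError, OrientationError

_MERGE_TOL = 1e-9  # vertex dedup radius, Angstrom
_AREA_TOL = 1e-14  # faces below this area (A^2) are dropped as degenerate


class TriangleMesh:
    """An oriented triangle surface with cached derived geometry.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in Angstrom.
    faces : (m, 3) int array
        Vertex index triples with consistent winding (outward normals for
        closed surfaces).
    """

    def __init__(self, vertices, faces):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face index out of range")
        self._cache: dict = {}

    # -- basic counts -----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    # -- cached derived quantities ---------------------------------------
    def _get(self, key, builder):
        if key not in self._cache:
            self._cache[key] = builder()
        return self._cache[key]

    @property
    def face_normals(self) -> np.ndarray:
        """(m, 3) unit normals following the winding of each face."""

        def build():
            v = self.vertices
            f = self.faces
            n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            norm = np.linalg.norm(n, axis=1)
            norm[norm == 0] = 1.0
            return n / norm[:, None]

        return self._get("face_normals", build)

    @property
    def face_areas(self) -> np.ndarray:
        def build():
            v = self.vertices
            f = self.faces
            n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            return 0.5 * np.linalg.norm(n, axis=1)

        return self._get("face_areas", build)

    @property
    def total_area(self) -> float:
        return float(self.face_areas.sum())

    @property
    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas: one third of incident triangle areas.

        These partition the surface exactly: their sum equals the total
        triangle area.
        """

        def build():
            va = np.zeros(self.n_vertices)
            contrib = np.repeat(self.face_areas / 3.0, 3)
            np.add.at(va, self.faces.ravel(), contrib)
            return va

        return self._get("vertex_areas", build)

    @property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""

        def build():
            vn = np.zeros((self.n_vertices, 3))
            w = (self.face_normals * self.face_areas[:, None]).repeat(3, axis=0)
            np.add.at(vn, self.faces.ravel(), w.reshape(-1, 3))
            norm = np.linalg.norm(vn, axis=1)
            bad = norm < 1e-300
            norm[bad] = 1.0
            vn = vn / norm[:, None]
            vn[bad] = (0.0, 0.0, 1.0)  # isolated/degenerate vertices
            return vn

        return self._get("vertex_normals", build)

    # -- edge structure ---------------------------------------------------
    def _build_edges(self):
        """Unique undirected edges, signed dihedral angles and CSR maps."""
        f = self.faces
        m = len(f)
        # directed edges in winding order, with owning face
        de = np.concatenate(
            [f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]], axis=0
        )
        de_face = np.concatenate([np.arange(m)] * 3)
        key = np.sort(de, axis=1)
        uniq, inverse, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        n_edge = len(uniq)
        beta = np.zeros(n_edge)
        # face on the (a<b) directed side and on the (b>a) side
        fwd = de[:, 0] < de[:, 1]
        face_fwd = np.full(n_edge, -1, dtype=np.int64)
        face_bwd = np.full(n_edge, -1, dtype=np.int64)
        dup_fwd = dup_bwd = False
        idx_f = inverse[fwd]
        dup_fwd = len(idx_f) != len(np.unique(idx_f))
        face_fwd[idx_f] = de_face[fwd]
        idx_b = inverse[~fwd]
        dup_bwd = len(idx_b) != len(np.unique(idx_b))
        face_bwd[idx_b] = de_face[~fwd]
        orientable = not (dup_fwd or dup_bwd) and counts.max(initial=0) <= 2
        interior = (face_fwd >= 0) & (face_bwd >= 0)
        if np.any(interior):
            n1 = self.face_normals[face_fwd[interior]]
            n2 = self.face_normals[face_bwd[interior]]
            v = self.vertices
            evec = v[uniq[interior, 1]] - v[uniq[interior, 0]]
            elen = np.linalg.norm(evec, axis=1)
            elen[elen == 0] = 1.0
            ehat = evec / elen[:, None]
            s = np.einsum("ij,ij->i", np.cross(n1, n2), ehat)
            c = np.einsum("ij,ij->i", n1, n2)
            beta[interior] = np.arctan2(s, c)
        self._cache["edges_unique"] = uniq
        self._cache["edge_beta"] = beta
        self._cache["edge_interior"] = interior
        self._cache["winding_consistent"] = orientable

    @property
    def edges_unique(self) -> np.ndarray:
        if "edges_unique" not in self._cache:
            self._build_edges()
        return self._cache["edges_unique"]

    @property
    def edge_beta(self) -> np.ndarray:
        """Signed dihedral angle per unique edge (positive convex, 0 on
        boundary edges)."""
        if "edge_beta" not in self._cache:
            self._build_edges()
        return self._cache["edge_beta"]

    @property
    def is_winding_consistent(self) -> bool:
        if "winding_consistent" not in self._cache:
            self._build_edges()
        return self._cache["winding_consistent"]

    @staticmethod
    def _csr(pairs_first, pairs_second, n):
        order = np.lexsort((pairs_second, pairs_first))
        a = pairs_first[order]
        b = pairs_second[order]
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(indptr, a + 1, 1)
        np.cumsum(indptr, out=indptr)
        return indptr, np.ascontiguousarray(b)

    @property
    def vertex_adjacency(self):
        """CSR (indptr, indices) of the 1-ring vertex adjacency."""

        def build():
            e = self.edges_unique
            a = np.concatenate([e[:, 0], e[:, 1]])
            b = np.concatenate([e[:, 1], e[:, 0]])
            return self._csr(a, b, self.n_vertices)

        return self._get("vertex_adjacency", build)

    @property
    def vertex_edges(self):
        """CSR map from vertex to incident unique-edge indices."""

        def build():
            e = self.edges_unique
            idx = np.arange(len(e))
            a = np.concatenate([e[:, 0], e[:, 1]])
            b = np.concatenate([idx, idx])
            return self._csr(a, b, self.n_vertices)

        return self._get("vertex_edges", build)

    @property
    def vertex_faces(self):
        """CSR map from vertex to incident face indices."""

        def build():
            f = self.faces
            a = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
            b = np.concatenate([np.arange(len(f))] * 3)
            return self._csr(a, b, self.n_vertices)

        return self._get("vertex_faces", build)

    @property
    def boundary_vertices(self) -> np.ndarray:
        """Boolean mask of vertices incident to an open (one-face) edge."""

        def build():
            if "edge_interior" not in self._cache:
                self._build_edges()
            mask = np.zeros(self.n_vertices, dtype=bool)
            open_edges = self.edges_unique[~self._cache["edge_interior"]]
            mask[open_edges.ravel()] = True
            return mask

        return self._get("boundary_vertices", build)

    @property
    def kdtree(self) -> cKDTree:
        return self._get("kdtree", lambda: cKDTree(self.vertices))

    @property
    def mean_edge_length(self) -> float:
        def build():
            e = self.edges_unique
            v = self.vertices
            return float(
                np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1).mean()
            )

        return self._get("mean_edge_length", build)

    @property
    def max_edge_length(self) -> float:
        def build():
            e = self.edges_unique
            if len(e) == 0:
                return 0.0
            v = self.vertices
            return float(
                np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1).max()
            )

        return self._get("max_edge_length", build)

    # -- transforms and conversion ----------------------------------------
    def transformed(self, R, t) -> "TriangleMesh":
        """Return a copy with vertices mapped to ``R @ v + t``."""
        R = np.asarray(R, dtype=np.float64)
        t = np.asarray(t, dtype=np.float64)
        return TriangleMesh(self.vertices @ R.T + t, self.faces.copy())

    def flipped(self) -> "TriangleMesh":
        """Return a copy with reversed winding (inward normals)."""
        return TriangleMesh(self.vertices.copy(), self.faces[:, ::-1].copy())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def save(self, path, file_type=None, vertex_quality=None) -> None:
        """Write the mesh (OFF/PLY/OBJ by extension or explicit type).

        PLY output is binary little-endian with double-precision
        coordinates, so a write/read round-trip is lossless.
        ``vertex_quality`` optionally attaches a per-vertex scalar as the
        PLY ``quality`` property, e.g. for curvature color maps.
        """
        kind = (file_type or str(path).rsplit(".", 1)[-1]).lower()
        if kind == "ply":
            self._save_ply_double(path, vertex_quality)
            return
        tm = self.to_trimesh()
        tm.export(str(path), file_type=file_type)

    def _save_ply_double(self, path, vertex_quality=None) -> None:
        # trimesh exports PLY vertices as float32 only; fixtures need a
        # lossless round-trip, so write the (simple) format directly
        header = [
            "ply",
            "format binary_little_endian 1.0",
            f"element vertex {self.n_vertices}",
            "property double x",
            "property double y",
            "property double z",
        ]
        if vertex_quality is not None:
            header.append("property double quality")
        header += [
            f"element face {self.n_faces}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
        if vertex_quality is not None:
            vdata = np.column_stack(
                [self.vertices, np.asarray(vertex_quality, dtype=np.float64)]
            ).astype("<f8")
        else:
            vdata = self.vertices.astype("<f8")
        fdata = np.zeros(
            self.n_faces,
            dtype=[("n", "u1"), ("idx", "<i4", (3,))],
        )
        fdata["n"] = 3
        fdata["idx"] = self.faces.astype("<i4")
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            fh.write(vdata.tobytes())
            fh.write(fdata.tobytes())

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"TriangleMesh({self.n_vertices} vertices, {self.n_faces} faces)"


@dataclass
class DensityMap:
    """A 3D scalar grid in physical coordinates.

    ``grid[i, j, k]`` sits at ``origin + (i, j, k) * spacing`` (Angstrom).
    """

    grid: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=np.float64), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("grid must be 3D with at least 2 samples per axis")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on every axis")


# ---------------------------------------------------------------------------
# construction / cleanup


def clean_mesh(vertices, faces, merge_tol: float = _MERGE_TOL) -> TriangleMesh:
    """Merge duplicate vertices, drop degenerate faces, keep winding.

    Vertices closer than ``merge_tol`` (on a snapped grid) are merged with
    the first occurrence winning; faces that collapse (repeated indices or
    near-zero area) are removed.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    if merge_tol > 0 and len(vertices):
        key = np.round(vertices / merge_tol).astype(np.int64)
        _, first, inverse = np.unique(
            key, axis=0, return_index=True, return_inverse=True
        )
        # keep original ordering of first occurrences
        order = np.argsort(first, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        vertices = vertices[np.sort(first)]
        remap = rank[inverse]
        faces = remap[faces]
    # drop collapsed faces
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[ok]
    mesh = TriangleMesh(vertices, faces)
    ok = mesh.face_areas > _AREA_TOL
    if not ok.all():
        mesh = TriangleMesh(vertices, faces[ok])
    return mesh


def load_mesh(path, file_format=None) -> TriangleMesh:
    """Load an OFF/PLY/OBJ surface and return a cleaned :class:`TriangleMesh`.

    Raises :class:`MeshFormatError` on parse failure and
    :class:`OrientationError` if the winding cannot be made consistent.
    """
    try:
        tm = trimesh.load_mesh(str(path), file_type=file_format, process=False)
    except Exception as exc:  # trimesh raises many flavours
        raise MeshFormatError(f"{path}: cannot parse mesh ({exc})") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise MeshFormatError(f"{path}: file contains no mesh geometry")
        tm = trimesh.util.concatenate(geoms)
    if tm.vertices is None or len(tm.vertices) == 0:
        raise MeshFormatError(f"{path}: file contains no vertices")
    mesh = clean_mesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    if not mesh.is_winding_consistent:
        # one repair attempt via trimesh, then give up
        tm2 = mesh.to_trimesh()
        trimesh.repair.fix_winding(tm2)
        mesh2 = clean_mesh(np.asarray(tm2.vertices), np.asarray(tm2.faces))
        if not mesh2.is_winding_consistent:
            raise OrientationError(
                f"{path}: mesh is not orientable (inconsistent winding)"
            )
        mesh = mesh2
    return mesh


def connected_component_labels(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex connected-component label (edge connectivity)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    indptr, indices = mesh.vertex_adjacency
    n = mesh.n_vertices
    adj = csr_matrix(
        (np.ones(len(indices), dtype=np.int8), indices, indptr), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def drop_small_components(mesh: TriangleMesh, min_area: float) -> TriangleMesh:
    """Remove connected components whose total area is below ``min_area``.

    Used by fixture generators and cut protocols to discard sub-voxel
    debris; plain iso-surfacing keeps every component.
    """
    if mesh.n_faces == 0 or min_area <= 0:
        return mesh
    labels = connected_component_labels(mesh)
    face_label = labels[mesh.faces[:, 0]]
    comp_area = np.zeros(labels.max() + 1)
    np.add.at(comp_area, face_label, mesh.face_areas)
    keep_faces = comp_area[face_label] >= min_area
    if keep_faces.all():
        return mesh
    faces = mesh.faces[keep_faces]
    used = np.zeros(mesh.n_vertices, dtype=bool)
    used[faces.ravel()] = True
    remap = np.cumsum(used) - 1
    return TriangleMesh(mesh.vertices[used], remap[faces])


# ---------------------------------------------------------------------------
# density maps


def load_density(path) -> DensityMap:
    """Read an MRC/CCP4 2014 density map (via gemmi), honoring voxel size
    and origin records."""
    import gemmi

    try:
        m = gemmi.read_ccp4_map(str(path))
    except Exception as exc:
        raise MeshFormatError(f"{path}: cannot parse density map ({exc})") from exc
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = np.array(m.grid, copy=True)
    cell = m.grid.unit_cell
    spacing = np.array(
        [cell.a / m.grid.nu, cell.b / m.grid.nv, cell.c / m.grid.nw]
    )
    # ORIGIN record (MRC2014 words 50-52); fall back to NxSTART offsets
    origin = np.array(
        [m.header_float(50), m.header_float(51), m.header_float(52)]
    )
    if not np.any(origin):
        start = np.array(
            [m.header_i32(5), m.header_i32(6), m.header_i32(7)], dtype=float
        )
        origin = start * spacing
    return DensityMap(grid=grid, spacing=spacing, origin=origin)


def save_density(dmap: DensityMap, path) -> None:
    """Write a :class:`DensityMap` as an MRC/CCP4 map file."""
    import gemmi

    nx, ny, nz = dmap.grid.shape
    cell = gemmi.UnitCell(
        nx * dmap.spacing[0], ny * dmap.spacing[1], nz * dmap.spacing[2],
        90, 90, 90,
    )
    grid = gemmi.FloatGrid(np.asarray(dmap.grid, dtype=np.float32), cell)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for i, w in enumerate(dmap.origin):
        m.set_header_float(50 + i, float(w))
    m.write_ccp4_map(str(path))


def extract_isosurface(dmap: DensityMap, iso_value: float) -> TriangleMesh:
    """Marching-cubes iso-surface of a density map in physical coordinates.

    All connected components are retained.  Faces are oriented so normals
    point outward (toward lower density for a blob-like map).
    """
    from skimage import measure

    gmin = float(dmap.grid.min())
    gmax = float(dmap.grid.max())
    if not (gmin < iso_value < gmax):
        raise ValueError(
            f"iso_value {iso_value} outside grid range ({gmin}, {gmax})"
        )
    verts, faces, _normals, _values = measure.marching_cubes(
        dmap.grid, level=iso_value, spacing=tuple(dmap.spacing)
    )
    verts = verts + dmap.origin
    mesh = clean_mesh(verts, faces)
    tm = mesh.to_trimesh()
    try:
        tm.fix_normals(multibody=True)
    except BaseException:  # pragma: no cover - defensive
        pass
    mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    return mesh


# ---------------------------------------------------------------------------
# distances


def surface_rmsd(a: TriangleMesh, b: TriangleMesh, mode: str = "closest_point_symmetric") -> float:
    """RMS of vertex-to-nearest-vertex distances between two surfaces.

    ``closest_vertex`` maps each vertex of ``a`` to the nearest vertex of
    ``b`` (asymmetric); ``closest_point_symmetric`` pools both directions.
    """
    if a.n_vertices == 0 or b.n_vertices == 0:
        raise ValueError("surface_rmsd requires non-empty meshes")
    d_ab, _ = b.kdtree.query(a.vertices)
    if mode == "closest_vertex":
        return float(np.sqrt(np.mean(d_ab**2)))
    if mode == "closest_point_symmetric":
        d_ba, _ = a.kdtree.query(b.vertices)
        d = np.concatenate([d_ab, d_ba])
        return float(np.sqrt(np.mean(d**2)))
    raise ValueError(f"unknown mode {mode!r}")
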