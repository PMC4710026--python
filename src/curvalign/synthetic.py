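"""Seed-reproducible synthetic surfaces for testing and benchmarking.

The generators emulate the geometric character of molecular surfaces
without any external data: spheres with Gaussian protrusions (skin-like
surfaces with atom-group bumps), sum-of-Gaussians pseudo-molecule
iso-surfaces (van-der-Waals/EM-like blobs), plane-cut partial pairs with
a calibrated overlap fraction, and noisy re-extractions where the
pseudo-atom centers are perturbed by a stated RMS amount.  Every
generator is a pure function of its arguments: the same seed yields
byte-identical meshes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import trimesh

from .mesh import (
    DensityMap,
    TriangleMesh,
    clean_mesh,
    drop_small_components,
    extract_isosurface,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative description of a synthetic fixture."""

    seed: int
    kind: str  # bumpy_sphere | gaussian_blob_surface | plane_cut_pair | noisy_pair
    parameters: dict = field(default_factory=dict)


class BumpySphere(NamedTuple):
    mesh: TriangleMesh
    bump_centers: np.ndarray  # (n_bumps, 3) points on the displaced surface
    bump_directions: np.ndarray  # (n_bumps, 3) unit vectors


class BlobSurface(NamedTuple):
    mesh: TriangleMesh
    density: DensityMap
    centers: np.ndarray
    sigmas: np.ndarray


class CutPair(NamedTuple):
    piece_a: TriangleMesh
    piece_b: TriangleMesh
    achieved_overlap: float


class NoisyPair(NamedTuple):
    mesh: TriangleMesh
    noisy_mesh: TriangleMesh
    achieved_rmsd: float


def _fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors (Fibonacci lattice)."""
    i = np.arange(n)
    ga = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    th = ga * i
    return np.stack([r * np.cos(th), r * np.sin(th), z], axis=1)


def bumpy_sphere(
    seed: int,
    radius: float = 10.0,
    n_bumps: int = 8,
    bump_height: float = 1.2,
    bump_sigma: float = 1.2,
    subdivision: int = 3,
    jitter: float = 0.15,
) -> BumpySphere:
    """Icosphere displaced radially by Gaussian bumps.

    Bump centers start on a Fibonacci lattice and are jittered by the
    seed, so the configuration is generic (no accidental symmetry).  The
    bump profile is ``height * exp(-s^2 / (2 sigma^2))`` in geodesic arc
    length ``s`` from the bump direction.
    """
    if n_bumps < 0:
        raise ValueError("n_bumps must be non-negative")
    if bump_sigma <= 0:
        raise ValueError("bump_sigma must be positive")
    rng = np.random.default_rng(seed)
    ico = trimesh.creation.icosphere(subdivisions=subdivision, radius=1.0)
    u = np.asarray(ico.vertices)
    u = u / np.linalg.norm(u, axis=1)[:, None]
    disp = np.zeros(len(u))
    if n_bumps > 0:
        dirs = _fibonacci_directions(n_bumps)
        dirs = dirs + jitter * rng.standard_normal(dirs.shape)
        dirs = dirs / np.linalg.norm(dirs, axis=1)[:, None]
        for d in dirs:
            ang = np.arccos(np.clip(u @ d, -1.0, 1.0))
            s = ang * radius
            disp += bump_height * np.exp(-(s**2) / (2.0 * bump_sigma**2))
    else:
        dirs = np.zeros((0, 3))
    verts = (radius + disp)[:, None] * u
    mesh = TriangleMesh(verts, np.asarray(ico.faces))
    centers = (radius + bump_height) * dirs if n_bumps else np.zeros((0, 3))
    return BumpySphere(mesh=mesh, bump_centers=centers, bump_directions=dirs)


def _blob_density(centers, sigmas, spacing, margin, blend_power=1.0):
    """Blend of per-atom Gaussians: (sum g_i^p)^(1/p).

    p = 1 is the plain additive sum; p > 1 approaches a union-of-balls
    blend where each surface patch follows its own atom.
    """
    lo = centers.min(axis=0) - margin
    hi = centers.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    grid = np.zeros(shape)
    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    # windowed accumulation: each pseudo-atom touches only nearby voxels
    for c, s in zip(centers, sigmas):
        cut = 4.0 * s
        idx = []
        for k in range(3):
            i0 = max(0, int(np.floor((c[k] - cut - lo[k]) / spacing)))
            i1 = min(shape[k] - 1, int(np.ceil((c[k] + cut - lo[k]) / spacing)))
            idx.append((i0, i1))
        (x0, x1), (y0, y1), (z0, z1) = idx
        dx = axes[0][x0 : x1 + 1] - c[0]
        dy = axes[1][y0 : y1 + 1] - c[1]
        dz = axes[2][z0 : z1 + 1] - c[2]
        d2 = (
            dx[:, None, None] ** 2
            + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2
        )
        grid[x0 : x1 + 1, y0 : y1 + 1, z0 : z1 + 1] += np.exp(
            -d2 / (2.0 * s * s)
        ) ** blend_power
    np.power(grid, 1.0 / blend_power, out=grid)
    return DensityMap(grid=grid, spacing=np.full(3, float(spacing)), origin=lo)


def gaussian_blob_surface(
    seed: int,
    n_atoms: int = 150,
    spacing: float = 0.6,
    iso: float = 0.5,
    margin: float = 5.0,
    sigma_range: tuple = (1.2, 1.5),
    packing: float = 1.6,
    aspect: tuple = (1.8, 1.0, 0.65),
    min_component_area: float = 2.0,
    blend_power: float = 1.0,
    centers: np.ndarray | None = None,
    sigmas: np.ndarray | None = None,
) -> BlobSurface:
    """Iso-surface of a sum-of-Gaussians pseudo-molecule.

    Pseudo-atom centers are sampled uniformly in an ellipsoid whose mean
    radius scales as ``packing * n_atoms**(1/3)``; the default packing
    treats each pseudo-atom as a protein heavy atom (~17 A^3 of body
    volume, hydrogens implicit) with semi-axis ratios ``aspect``
    (globular proteins are prolate, not spherical — this also gives
    the principal-axes frame used by the plane-cut protocol a stable
    orientation).  Atoms are clustered into groups of ~32 scattered with
    a ~3 A radius, emulating the residue/loop-scale lumps that carry the
    significant protrusions of a protein skin surface; per-atom Gaussian
    widths vary in ``sigma_range``, so at the default iso-value the
    surface also resolves single-atom texture.  Returns the mesh
    together with the density map it was extracted from.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    if centers is None:
        # hierarchical packing: atoms cluster into residue-sized groups,
        # so the surface carries multi-atom protrusions (side-chain scale)
        # on top of single-atom texture, like a real skin surface
        r_cluster = packing * n_atoms ** (1.0 / 3.0)
        semi = np.asarray(aspect, dtype=np.float64)
        semi = semi / np.prod(semi) ** (1.0 / 3.0) * r_cluster
        atoms_per_group = 32
        n_groups = max(1, n_atoms // atoms_per_group)
        # best-candidate placement: residue groups in a packed chain
        # cover the body at near-constant density, so group centers are
        # spread evenly rather than clustered at random (this also keeps
        # the realized body shape close to the nominal aspect ratios)
        groups = np.empty((n_groups, 3))
        for g in range(n_groups):
            k = 1 if g == 0 else 16
            d = rng.standard_normal((k, 3))
            d /= np.linalg.norm(d, axis=1)[:, None]
            rad = rng.random(k) ** (1.0 / 3.0)
            cand = d * rad[:, None] * semi[None, :]
            if g == 0:
                groups[0] = cand[0]
                continue
            dist = np.linalg.norm(
                cand[:, None, :] - groups[None, :g, :], axis=2
            ).min(axis=1)
            groups[g] = cand[np.argmax(dist)]
        which = rng.integers(0, n_groups, size=n_atoms)
        centers = groups[which] + 3.2 * rng.standard_normal((n_atoms, 3))
    else:
        centers = np.asarray(centers, dtype=np.float64)
    if sigmas is None:
        sigmas = rng.uniform(sigma_range[0], sigma_range[1], size=len(centers))
    else:
        sigmas = np.asarray(sigmas, dtype=np.float64)
    density = _blob_density(centers, sigmas, spacing, margin, blend_power)
    mesh = extract_isosurface(density, iso)
    # marching cubes on a noisy sum-of-Gaussians field can emit sub-voxel
    # droplet/sliver components; a surface-construction tool would not
    mesh = drop_small_components(mesh, min_component_area)
    return BlobSurface(mesh=mesh, density=density, centers=centers, sigmas=sigmas)


def _pca_frame(mesh: TriangleMesh):
    """Centroid + principal axes of the vertex cloud, deterministic signs."""
    x = mesh.vertices
    centroid = x.mean(axis=0)
    x0 = x - centroid
    cov = x0.T @ x0 / len(x0)
    w, v = np.linalg.eigh(cov)
    axes = v[:, ::-1].T  # rows: pc1, pc2, pc3 (descending variance)
    if np.allclose(w, w[0], rtol=1e-9):
        # isotropic cloud: fall back to coordinate axes, warn upstream
        axes = np.eye(3)
    for k in range(3):
        j = np.argmax(np.abs(axes[k]))
        if axes[k, j] < 0:
            axes[k] = -axes[k]
    axes[2] = np.cross(axes[0], axes[1])  # enforce right-handedness
    return centroid, axes


def _from_trimesh(tm: trimesh.Trimesh, min_component_area: float = 0.0) -> TriangleMesh:
    mesh = clean_mesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    if min_component_area > 0:
        mesh = drop_small_components(mesh, min_component_area)
    return mesh


def plane_cut_pair(
    mesh: TriangleMesh,
    overlap_fraction: float,
    tol: float = 0.005,
    max_iter: int = 50,
    min_component_area: float = 2.0,
) -> CutPair:
    """Two overlapping partial surfaces cut by rotated centroid planes.

    The base plane contains the first two principal axes of the vertex
    cloud; the second plane is the base plane rotated about the second
    principal axis until the retained half-surfaces share the requested
    fraction of their area (calibrated by bisection on the achieved
    shared-area fraction).  Cut faces are clipped at the plane with new
    boundary vertices; no original vertex moves.
    """
    if not (0 < overlap_fraction <= 1):
        raise ValueError("overlap_fraction must be in (0, 1]")
    centroid, axes = _pca_frame(mesh)
    pc1, pc2, pc3 = axes
    tm = mesh.to_trimesh()

    def normal(theta):
        return math.cos(theta) * pc3 + math.sin(theta) * pc1

    piece_a_tm = tm.slice_plane(centroid, pc3)

    def cut(theta):
        return tm.slice_plane(centroid, normal(theta))

    def achieved(theta, piece_b_tm):
        shared = piece_a_tm.slice_plane(centroid, normal(theta))
        denom = 0.5 * (piece_a_tm.area + piece_b_tm.area)
        return shared.area / denom if denom > 0 else 0.0

    if overlap_fraction >= 1.0:
        pa = _from_trimesh(piece_a_tm, min_component_area)
        return CutPair(piece_a=pa, piece_b=pa, achieved_overlap=1.0)

    lo, hi = 0.0, math.pi  # achieved is ~1 at 0 and ~0 at pi
    theta = math.pi * (1.0 - overlap_fraction)  # good initial guess
    best = None
    for _ in range(max_iter):
        pb = cut(theta)
        a = achieved(theta, pb)
        best = (theta, pb, a)
        if abs(a - overlap_fraction) < tol:
            break
        if a > overlap_fraction:
            lo = theta
        else:
            hi = theta
        theta = 0.5 * (lo + hi)
    theta, pb, a = best
    return CutPair(
        piece_a=_from_trimesh(piece_a_tm, min_component_area),
        piece_b=_from_trimesh(pb, min_component_area),
        achieved_overlap=float(a),
    )


def plane_cut_series(
    mesh: TriangleMesh,
    min_component_area: float = 2.0,
) -> tuple[list[TriangleMesh], list[float]]:
    """The five-piece partial-overlap series of the evaluation protocol.

    The base plane (containing the first two principal axes) is rotated
    about the second principal axis by 0, pi/5, ..., 4*pi/5; the piece on
    the positive side of each plane is retained.  The first piece shares
    a decreasing, approximately known fraction of its area with each of
    the other four (nominally 80/60/40/20 %; the achieved fractions
    depend on the body's shape and are returned alongside).
    """
    centroid, axes = _pca_frame(mesh)
    pc1, pc2, pc3 = axes
    tm = mesh.to_trimesh()
    pieces = []
    normals = []
    for k in range(5):
        th = k * math.pi / 5.0
        n = math.cos(th) * pc3 + math.sin(th) * pc1
        normals.append(n)
        pieces.append(tm.slice_plane(centroid, n))
    overlaps = [1.0]
    for k in range(1, 5):
        shared = pieces[0].slice_plane(centroid, normals[k])
        denom = 0.5 * (pieces[0].area + pieces[k].area)
        overlaps.append(float(shared.area / denom) if denom > 0 else 0.0)
    out = [_from_trimesh(p, min_component_area) for p in pieces]
    return out, overlaps


def noisy_pair(
    seed: int,
    noise_rmsd: float,
    n_atoms: int = 150,
    spacing: float = 0.8,
    iso: float = 0.5,
    **blob_kwargs,
) -> NoisyPair:
    """A blob surface and its re-extraction after perturbing pseudo-atom
    centers by Gaussian noise scaled to an exact center RMSD.

    Noise is applied to the generating centers (not mesh vertices) and
    the surface re-extracted, so mesh connectivity may change — as it
    would when rebuilding a molecular surface from perturbed atoms.
    """
    if noise_rmsd < 0:
        raise ValueError("noise_rmsd must be non-negative")
    blob = gaussian_blob_surface(
        seed, n_atoms=n_atoms, spacing=spacing, iso=iso, **blob_kwargs
    )
    if noise_rmsd == 0:
        return NoisyPair(mesh=blob.mesh, noisy_mesh=blob.mesh, achieved_rmsd=0.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    delta = rng.standard_normal(blob.centers.shape)
    rms = math.sqrt(float(np.mean(np.sum(delta**2, axis=1))))
    delta *= noise_rmsd / rms
    achieved = math.sqrt(float(np.mean(np.sum(delta**2, axis=1))))
    noisy = gaussian_blob_surface(
        seed,
        n_atoms=n_atoms,
        spacing=spacing,
        iso=iso,
        centers=blob.centers + delta,
        sigmas=blob.sigmas,
        **blob_kwargs,
    )
    return NoisyPair(
        mesh=blob.mesh, noisy_mesh=noisy.mesh, achieved_rmsd=achieved
    )


def generate(spec: SyntheticSpec):
    """Dispatch a :class:`SyntheticSpec` to its generator."""
    kinds = {
        "bumpy_sphere": bumpy_sphere,
        "gaussian_blob_surface": gaussian_blob_surface,
        "noisy_pair": noisy_pair,
    }
    if spec.kind not in kinds:
        raise KeyError(f"unknown synthetic kind {spec.kind!r}")
    return kinds[spec.kind](spec.seed, **spec.parameters)
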