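# Methods

`curvalign` aligns pairs of molecular surfaces by matching significant
protrusions. This note records the model, the discretisations, the
parameters that matter, and what the synthetic benchmark surfaces do and
do not capture.

## Pipeline overview

Given two triangle meshes P and Q in Å:

1. **Curvature** — signed mean curvature H at every vertex, estimated by
   a normal-cycle tensor averaged over a neighborhood of radius `r_c`.
2. **Landmarks** — maxima of the H field, simplified by topological
   persistence at threshold `t_s`; each surviving positive-curvature
   maximum carries the area of its descending manifold and a 15-scale
   curvature descriptor.
3. **Correspondences** — landmark pairs whose descriptors agree at every
   scale within `t_ms` (on a normalised curvature scale).
4. **Consistency cliques** — correspondences become graph nodes; edges
   require pairwise landmark distances on the two surfaces to agree
   within `t_mrd` and pairwise normal angles within π/2; maximal cliques
   (Bron–Kerbosch with pivoting) are candidate correspondence sets.
5. **Rigid fit and score** — each clique of ≥ 3 correspondences yields a
   least-squares proper rotation + translation (orthogonal Procrustes
   with determinant correction). Cliques are ranked by

   D′(P,Q) = sqrt( Σᵢ A(pᵢ)·‖R pᵢ + t − qᵢ‖² / A(ℂ) ) ÷ ( A(ℂ)/A_P ),

   with A(pᵢ) the landmark's descending-manifold area and A(ℂ) their
   sum; the reported score is min(D′(P,Q), D′(Q,P)) (the transform is
   always applied to the P landmarks). Cliques whose regions cover at
   least 15 % of **neither** surface's area are discarded as spurious —
   covering a sizable fraction of one surface suffices, which keeps
   partial alignments of a small surface against a much larger one
   admissible (the same reasoning that motivates the filter: it exists
   to reject near-perfect fits of a handful of landmarks, not genuine
   large partial matches). Survivors are sorted by ascending score with
   deterministic tie-breaking (larger clique, larger minimum area
   fraction, then lexicographic clique identity).

## Discrete mean curvature

The per-vertex tensor is

T(v) = (1/|B|) · Σ_e β(e) · len(e ∩ B) · ē ēᵀ,

summed over mesh edges meeting the ball B of radius `r_c` around v, with
β(e) the signed dihedral angle at e (positive convex under outward
normals), ē the unit edge direction, and |B| the mesh area inside B.
Neighborhoods are geodesic-approximating: vertices are collected by
breadth-first traversal (out to `r_c` plus one maximal edge length so
that every intersecting face and edge is a candidate), which keeps the
ball from leaking across thin necks; edges are clipped to the sphere
analytically and |B| uses exact circle–triangle intersection areas
computed with a signed per-edge sector decomposition (continuous under
perturbation, no special cases when vertices fall on the clipping
circle).

H is extracted as **half the tensor trace**: tr T = Σ β·len/|B| converges
to ∫ 2H dA / |B| for any smooth surface, giving H exactly in the sphere
and cylinder limits. The more common alternative — projecting T onto the
tangent plane and averaging its two eigenvalues — discards the curvature
mass of near-rim edges whose directions tilt out of the centre vertex's
tangent plane, a systematic O(r_c²) deficit (≈ 4 % at `r_c` = 0.4·radius
on a sphere). With the trace form, the maximum per-vertex error on a
subdivision-4 icosphere at that radius is 1.4 %, 1.0 % on a cylinder
wall, and identically zero on a flat sheet; the error decreases
monotonically under mesh refinement. A helper
(`principal_curvatures_from_tensor`) still exposes the tangent-plane
eigenvalues where principal directions are wanted.

Scale sampling for descriptors: 15 radii uniformly spanning
[`r_c`, 2·`r_c`], both endpoints included; the first descriptor value is
bitwise the field value.

## Landmark topology

All comparisons use the total order (interior, H, vertex index): ties in
H are broken by index ("simulation of simplicity"), and open-boundary
vertices rank below all interior vertices. The boundary rule makes mesh
rims flow inward, the usual convention for gradient fields on bordered
surfaces: rim vertices have incomplete 1-rings, and treating them as
maximum candidates creates spurious rim landmarks that capture
descending-manifold area without representing protrusions (on
plane-cut test surfaces these artifacts held up to 14 % of a piece's
area). On closed meshes, and on fixtures where every vertex is on a
boundary, the order reduces to plain (H, index).

Persistence pairing is the superlevel-set filtration: vertices are swept
in decreasing order with a union-find over processed neighbors; when
components merge, each younger component's maximum is paired with the
current saddle, and its descending region will merge into the older
maximum (following the pairing chain through any already-cancelled
maxima). The global maximum never pairs. The simplification threshold is
`t_s` × (mean H over the initial positive-H maxima) — using the initial
maxima makes the threshold independent of its own outcome. Descending
manifolds are computed by memoised steepest ascent (move to the
highest-ordered 1-ring neighbor until a maximum is reached), so every
vertex is assigned to exactly one surviving maximum and total assigned
area is conserved under simplification.

This is a deliberate reduction of the full Morse–Smale complex: the
pipeline consumes only maxima, their persistences and their
descending-manifold areas, so saddle–minimum arcs and the combinatorial
1-skeleton are not built.

## Parameters

| name | unit | default | meaning |
|------|------|---------|---------|
| `r_c` | Å | 3.0 | curvature averaging radius; sets the feature scale (≥ 2 vertex rings) |
| `t_s` | – | 0.1 | persistence threshold as a fraction of mean positive-maximum curvature |
| `t_ms` | – | = `t_s` | descriptor difference bound, same normalised scale |
| `t_mrd` | Å | = `r_c` | pairwise relative-distance tolerance between landmarks |
| `min_area_fraction` | – | 0.15 | spurious-clique filter: at least one surface must be covered this much |
| `min_clique_size` | – | 3 | a rigid transform needs three non-collinear correspondences |
| `max_cliques` | – | 10⁶ | enumeration cap; sets a truncation flag, never raises |
| `top_k` | – | 10 | reported alignments |

The `t_ms` bound is `t_ms` × the mean of the two surfaces' average
positive-maximum curvatures, keeping the criterion symmetric in P and Q.
Named presets: `protein` (`r_c` 3 Å, `t_mrd` 1 Å), `ligand` (`r_c`
1.2 Å, single-atom features), `em` (`r_c` 30 Å, `t_s` 0.05, `t_ms` 0.1,
`t_mrd` 30 Å, for ~20 Å-resolution density-map iso-surfaces). All
inequalities at thresholds are strict; normal-angle dot products are
clamped to [−1, 1].

## Synthetic benchmark surfaces

The `synthetic` module generates every fixture the tests and the
benchmark script use; no external data is needed, and all generators are
byte-reproducible functions of their seed.

**Bumpy spheres** (`bumpy_sphere`) — icospheres displaced radially by
Gaussian bumps at jittered Fibonacci-lattice directions. The bump
centres are exact ground truth for landmark extraction and for
end-to-end rigid-motion recovery.

**Pseudo-molecule surfaces** (`gaussian_blob_surface`) — iso-surfaces of
a sum of per-atom Gaussians on a grid (0.6 Å spacing, marching cubes).
The defaults emulate a protein-sized body: each pseudo-atom stands for
one heavy atom (~17 Å³ of body volume, hydrogens implicit), atoms
cluster into residue-scale groups of ~32 (3.2 Å scatter) placed by
best-candidate sampling inside a prolate ellipsoid (axes 1.8 : 1.0 :
0.65), per-atom widths σ ∈ [1.2, 1.5] Å and iso-value 0.5 so isolated
atoms read ~1.4–1.8 Å. The hierarchical grouping matters: it produces
multi-atom protrusions with persistence well above the `t_s` threshold,
the feature class the landmark stage is designed for. Sub-voxel
marching-cubes debris components (< 2 Å²) are dropped by the generator;
`extract_isosurface` itself keeps every component. An optional p-norm
blend (`blend_power` > 1) moves the density toward a union-of-balls
surface.

**Partial overlaps** — `plane_cut_series` reproduces the published
protocol: the plane spanned by the first two principal axes of the
vertex cloud is rotated about the second axis by k·π/5 (k = 0…4) and the
positive-side piece retained; the first piece shares a decreasing,
approximately known fraction of its area with the others. On prolate
bodies the nominal 80/60/40/20 % labels realise as roughly 70/55/45/30 %
shared area; achieved fractions are always returned. `plane_cut_pair`
instead calibrates the rotation angle by bisection until a requested
fraction is achieved (on a sphere the lune formula makes the calibration
exact). Cut faces are clipped with new boundary vertices; no original
vertex moves.

**Noise** (`noisy_pair`) — per-axis Gaussian perturbation of the
pseudo-atom centres, rescaled so the achieved centre RMSD equals the
requested value exactly, followed by re-extraction of the surface (so
mesh connectivity changes, as it would when rebuilding a molecular
surface from perturbed coordinates).

What these fixtures do **not** capture: true solvent-excluded/skin
surface geometry (smooth blend patches, cavities at probe scale),
residue identity or any physico-chemical channel, crystallographic
contacts, and the shape diversity of real protein sets. Passing the
benchmark shows the pipeline recovers known transforms on surfaces with
protein-like protrusion statistics; it does not certify behaviour on any
particular experimental structure.

## Numerical and degenerate-input choices

- Mesh cleanup merges vertices within 1 nÅ and drops zero-area faces;
  non-orientable meshes are rejected after one winding-repair attempt.
- Vertex areas are barycentric (⅓ of incident triangle areas; exact
  partition of the surface); vertex normals are area-weighted averages
  of face normals.
- PLY output is binary little-endian with double-precision coordinates
  so fixture round-trips are lossless.
- `fit_rigid` rejects cliques whose source points are collinear
  (second singular value ≤ 1e−9 of the first); degenerate cliques are
  skipped with a log entry, not fatal.
- Curvature neighborhoods that contain no mesh edge raise a dedicated
  error naming the vertex (and the scale, for descriptors). A warning is
  issued when `r_c` spans fewer than ~2 vertex rings.
- Clique enumeration and result ordering are fully deterministic;
  re-running a pipeline yields byte-identical reports.
- Iso-surfacing keeps all connected components and orients normals
  outward per closed component; density maps honour MRC/CCP4 voxel size
  and origin records.

## Problem sizes used by the shipped studies

The benchmark study (`scripts/acceptance.py`) runs five seeded
pseudo-molecules of 1500 heavy
atoms (≈ 6 000 Å² of surface, ≈ 20 000 mesh vertices per body), cut into
five pieces each, with the protein preset — twenty alignment pairs in
total. The test suite uses subdivision-3/4 icospheres for curvature
accuracy, ≤ 200-vertex meshes for exhaustive topology oracles, ≤ 15-node
graphs for exhaustive clique oracles, and 100 end-to-end rigid-motion
recoveries on bumpy spheres.

## Known limitations

- The boundary-flows-inward convention can still leave maxima on
  boundary vertices whose whole neighborhood is boundary (e.g. strip
  meshes); such fixtures behave exactly as under the plain order.
- Landmark descriptors within 2·`r_c` of an open boundary average over a
  clipped neighborhood; matching across surfaces cut at different
  places degrades gracefully but measurably near the cut.
- The area-fraction filter makes alignments of pairs sharing ≲ 20 % of
  their area intrinsically borderline: the matched regions must still
  cover 15 % of at least one side.
- No post-refinement (e.g. ICP) is applied to the clique transform;
  scores are landmark-based by construction.
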