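"""Rigid alignment from correspondence cliques and area-weighted scoring.

Each clique yields a least-squares rigid transform (orthogonal Procrustes
with determinant correction, so reflections are never returned).  The
transform error is scored by

    D'_{P,Q} = sqrt( sum_i A_P(p_i) ||R p_i + t - q_i||^2 / A_P(C) )
               / ( A_P(C) / A_P )

with A_P(p_i) the descending-manifold area of landmark p_i and A_P(C)
their sum; D'_{Q,P} swaps the area weights to the Q side (the transform
is still applied to the P landmarks), and the reported score is the
smaller of the two.  The denominator rewards cliques that cover a larger
fraction of the surface; cliques that cover at least 15 % of neither
surface's area are discarded as spurious.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateConfigurationError
from .matching import (
    MaximalCorrespondenceSet,
    build_graph,
    iter_cliques,
    landmark_correspondences,
)
from .mesh import TriangleMesh
from .params import Params
from .topology import SurfaceLandmarks, compute_landmarks

log = logging.getLogger(__name__)

_COLLINEAR_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    R: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "R", np.asarray(self.R, dtype=np.float64))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=np.float64))
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-9):
            raise ValueError("R is not orthogonal")
        if not np.isclose(np.linalg.det(self.R), 1.0, atol=1e-9):
            raise ValueError("R is not a proper rotation")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.R.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(R=self.R @ other.R, t=self.R @ other.t + self.t)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(R=self.R.T, t=-self.R.T @ self.t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(R=np.eye(3), t=np.zeros(3))

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.R
        m[:3, 3] = self.t
        return m


@dataclass
class AlignmentResult:
    transform: RigidTransform
    score: float
    clique: MaximalCorrespondenceSet
    area_fraction_P: float
    area_fraction_Q: float
    landmark_rms: float


@dataclass
class AlignmentRun:
    """Ranked alignments plus per-stage diagnostics."""

    results: list
    diagnostics: dict = field(default_factory=dict)


def fit_rigid(clique: MaximalCorrespondenceSet) -> RigidTransform:
    """Least-squares rigid transform mapping P landmarks onto Q landmarks.

    Centroid subtraction, cross-covariance SVD, determinant sign fix.
    Raises :class:`DegenerateConfigurationError` for collinear or
    coincident source points.
    """
    if clique.size < 3:
        raise DegenerateConfigurationError("need at least 3 correspondences")
    P = np.array([c.p.position for c in clique.correspondences])
    Q = np.array([c.q.position for c in clique.correspondences])
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    scale = np.abs(P0).max()
    if scale <= 0:
        raise DegenerateConfigurationError("coincident source points")
    sv = np.linalg.svd(P0, compute_uv=False)
    if sv[1] <= _COLLINEAR_TOL * sv[0]:
        raise DegenerateConfigurationError("collinear source points")
    Hm = P0.T @ Q0
    U, _s, Vt = np.linalg.svd(Hm)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return RigidTransform(R=R, t=t)


def score(
    clique: MaximalCorrespondenceSet,
    transform: RigidTransform,
    area_P: float,
    area_Q: float,
) -> AlignmentResult:
    """Area-weighted RMS alignment score (smaller is better)."""
    if area_P <= 0 or area_Q <= 0:
        raise ValueError("surface areas must be positive")
    P = np.array([c.p.position for c in clique.correspondences])
    Q = np.array([c.q.position for c in clique.correspondences])
    ap = np.array([c.p.area for c in clique.correspondences])
    aq = np.array([c.q.area for c in clique.correspondences])
    if np.any(ap <= 0) or np.any(aq <= 0):
        raise ValueError("landmark areas must be positive")
    res2 = np.sum((transform.apply(P) - Q) ** 2, axis=1)
    a_cp = float(ap.sum())
    a_cq = float(aq.sum())
    if a_cp <= 0 or a_cq <= 0:
        raise ValueError("zero total clique area")
    rms_p = float(np.sqrt(np.sum(ap * res2) / a_cp))
    rms_q = float(np.sqrt(np.sum(aq * res2) / a_cq))
    frac_p = a_cp / area_P
    frac_q = a_cq / area_Q
    d_pq = rms_p / frac_p
    d_qp = rms_q / frac_q
    if d_pq <= d_qp:
        s, rms = d_pq, rms_p
    else:
        s, rms = d_qp, rms_q
    return AlignmentResult(
        transform=transform,
        score=s,
        clique=clique,
        area_fraction_P=frac_p,
        area_fraction_Q=frac_q,
        landmark_rms=rms,
    )


def _result_sort_key(r: AlignmentResult):
    return (
        r.score,
        -r.clique.size,
        -min(r.area_fraction_P, r.area_fraction_Q),
        r.clique.key,
    )


def align_landmark_sets(
    sp: SurfaceLandmarks, sq: SurfaceLandmarks, params: Params
) -> AlignmentRun:
    """Stages iii-v given precomputed landmarks of both surfaces."""
    diagnostics = {
        "n_landmarks_P": len(sp.landmarks),
        "n_landmarks_Q": len(sq.landmarks),
        "n_correspondences": 0,
        "n_graph_edges": 0,
        "n_cliques": 0,
        "n_scored": 0,
        "n_survivors": 0,
        "n_degenerate": 0,
        "truncated": False,
        "failed_stage": None,
    }
    if not sp.landmarks or not sq.landmarks:
        diagnostics["failed_stage"] = "landmarks"
        return AlignmentRun(results=[], diagnostics=diagnostics)
    curvature_scale = 0.5 * (sp.curvature_scale + sq.curvature_scale)
    corr = landmark_correspondences(
        sp.landmarks, sq.landmarks, params.t_ms, curvature_scale
    )
    diagnostics["n_correspondences"] = len(corr)
    if not corr:
        diagnostics["failed_stage"] = "correspondences"
        return AlignmentRun(results=[], diagnostics=diagnostics)
    graph = build_graph(corr, params.t_mrd)
    diagnostics["n_graph_edges"] = graph.n_edges
    results = []
    n_cliques = 0
    for clique in iter_cliques(graph, params.min_clique_size):
        if n_cliques >= params.max_cliques:
            diagnostics["truncated"] = True
            break
        n_cliques += 1
        try:
            transform = fit_rigid(clique)
        except DegenerateConfigurationError:
            diagnostics["n_degenerate"] += 1
            log.info("skipping degenerate clique %s", clique.key)
            continue
        res = score(clique, transform, sp.total_area, sq.total_area)
        diagnostics["n_scored"] += 1
        # spurious-set filter: a few-landmark clique covering a sizable
        # fraction of neither surface is discarded; covering >= 15 % of
        # one surface suffices (partial alignments of a small surface
        # against a large one are a supported use case)
        if (
            res.area_fraction_P < params.min_area_fraction
            and res.area_fraction_Q < params.min_area_fraction
        ):
            continue
        results.append(res)
    diagnostics["n_cliques"] = n_cliques
    diagnostics["n_survivors"] = len(results)
    if not results:
        diagnostics["failed_stage"] = "cliques" if n_cliques == 0 else "area_filter"
        return AlignmentRun(results=[], diagnostics=diagnostics)
    results.sort(key=_result_sort_key)
    return AlignmentRun(results=results[: params.top_k], diagnostics=diagnostics)


def align_surfaces(
    P: TriangleMesh, Q: TriangleMesh, params: Params | None = None
) -> AlignmentRun:
    """Full pipeline: curvature, landmarks, correspondences, cliques,
    rigid fits, ranked area-weighted scores."""
    if params is None:
        params = Params()
    sp = compute_landmarks(P, params.r_c, params.t_s, n_scales=params.n_scales)
    sq = compute_landmarks(Q, params.r_c, params.t_s, n_scales=params.n_scales)
    run = align_landmark_sets(sp, sq, params)
    run.diagnostics["params"] = params.to_dict()
    return run


def run_report(run: AlignmentRun, params: Params) -> dict:
    """JSON-serialisable report: parameters, stage counts, and for each
    result a row-major 4x4 homogeneous matrix with score and diagnostics."""
    return {
        "params": params.to_dict(),
        "stages": {
            k: v for k, v in run.diagnostics.items() if k != "params"
        },
        "n_results": len(run.results),
        "results": [
            {
                "rank": i,
                "matrix": [float(x) for x in r.transform.matrix().ravel()],
                "score": r.score,
                "landmark_rms": r.landmark_rms,
                "area_fraction_P": r.area_fraction_P,
                "area_fraction_Q": r.area_fraction_Q,
                "clique_size": r.clique.size,
                "clique": [list(k) for k in r.clique.key],
            }
            for i, r in enumerate(run.results)
        ],
    }


REPORT_REQUIRED_KEYS = {"params", "stages", "n_results", "results"}
RESULT_REQUIRED_KEYS = {
    "rank",
    "matrix",
    "score",
    "landmark_rms",
    "area_fraction_P",
    "area_fraction_Q",
    "clique_size",
    "clique",
}


def validate_report(report: dict) -> None:
    """Schema check for the JSON report (raises ValueError on failure)."""
    missing = REPORT_REQUIRED_KEYS - set(report)
    if missing:
        raise ValueError(f"report missing keys: {sorted(missing)}")
    if report["n_results"] != len(report["results"]):
        raise ValueError("n_results does not match results length")
    for r in report["results"]:
        miss = RESULT_REQUIRED_KEYS - set(r)
        if miss:
            raise ValueError(f"result missing keys: {sorted(miss)}")
        if len(r["matrix"]) != 16:
            raise ValueError("matrix must have 16 entries (row-major 4x4)")
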