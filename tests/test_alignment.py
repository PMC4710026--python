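"""Rigid fits, area-weighted scoring and the end-to-end pipeline."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from curvalign import (
    Params,
    align_surfaces,
    fit_rigid,
    preset,
    run_report,
    score,
    surface_rmsd,
)
from curvalign.alignment import RigidTransform, validate_report
from curvalign.errors import DegenerateConfigurationError
from curvalign.matching import Correspondence, MaximalCorrespondenceSet

from test_matching import make_landmark


def clique_from_points(P, Q, areas_p=None, areas_q=None):
    n = len(P)
    areas_p = np.ones(n) if areas_p is None else np.asarray(areas_p, float)
    areas_q = areas_p if areas_q is None else np.asarray(areas_q, float)
    corr = []
    for i in range(n):
        corr.append(
            Correspondence(
                p=make_landmark(i, P[i], area=areas_p[i]),
                q=make_landmark(100 + i, Q[i], area=areas_q[i]),
            )
        )
    return MaximalCorrespondenceSet(correspondences=corr)


class TestFitRigid:
    def test_identity(self):
        rng = np.random.default_rng(0)
        P = rng.uniform(-5, 5, (6, 3))
        T = fit_rigid(clique_from_points(P, P))
        assert np.abs(T.R - np.eye(3)).max() < 1e-12
        assert np.abs(T.t).max() < 1e-12

    @pytest.mark.parametrize("seed", range(12))
    def test_recovers_random_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.uniform(-10, 10, (5, 3))
        R0 = Rotation.random(random_state=seed).as_matrix()
        t0 = rng.uniform(-20, 20, 3)
        T = fit_rigid(clique_from_points(P, P @ R0.T + t0))
        assert np.abs(T.R - R0).max() < 1e-9
        assert np.linalg.norm(T.t - t0) < 1e-9

    def test_mirrored_targets_never_return_reflection(self):
        rng = np.random.default_rng(3)
        P = rng.uniform(-5, 5, (4, 3))
        M = np.diag([-1.0, 1.0, 1.0])
        T = fit_rigid(clique_from_points(P, P @ M.T))
        assert np.linalg.det(T.R) == pytest.approx(1.0, abs=1e-9)
        resid = np.linalg.norm(T.apply(P) - P @ M.T, axis=1)
        assert resid.max() > 1e-3

    def test_collinear_points_raise(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.5, 0, 0]], float)
        with pytest.raises(DegenerateConfigurationError):
            fit_rigid(clique_from_points(P, P))

    def test_agrees_with_scipy_orthogonal_procrustes(self):
        # independent route: scipy's Kabsch solver on centred clouds
        rng = np.random.default_rng(8)
        P = rng.uniform(-5, 5, (7, 3))
        Q = P @ Rotation.random(random_state=1).as_matrix().T + 2.0
        Q += 0.05 * rng.standard_normal(Q.shape)  # noisy, so fit is non-trivial
        T = fit_rigid(clique_from_points(P, Q))
        rot, rssd = Rotation.align_vectors(
            Q - Q.mean(axis=0), P - P.mean(axis=0)
        )
        assert np.abs(T.R - rot.as_matrix()).max() < 1e-8

    def test_proper_rotation_invariants_enforced(self):
        with pytest.raises(ValueError):
            RigidTransform(R=np.diag([-1.0, 1.0, 1.0]), t=np.zeros(3))


class TestScore:
    def test_perfect_alignment_scores_zero(self):
        rng = np.random.default_rng(2)
        P = rng.uniform(-5, 5, (4, 3))
        c = clique_from_points(P, P, areas_p=[3, 1, 2, 5])
        res = score(c, RigidTransform.identity(), area_P=100.0, area_Q=40.0)
        assert res.score == 0.0

    def test_uniform_residual_full_coverage(self):
        P = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0]], float)
        d = 0.7
        Q = P + np.array([0, 0, d])
        c = clique_from_points(P, Q, areas_p=[2.0, 1.0, 3.0])
        res = score(c, RigidTransform.identity(), area_P=6.0, area_Q=6.0)
        # weights cancel for a uniform residual, denominator is 1
        assert res.score == pytest.approx(d, rel=1e-12)

    def test_three_correspondence_worked_example(self):
        # areas (2,1,1), residuals (1,0,1), clique covers half of P:
        # D' = sqrt((2*1 + 1*0 + 1*1)/4) / 0.5 = 2*sqrt(0.75)
        P = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], float)
        res_vec = np.array([[1, 0, 0], [0, 0, 0], [0, 1, 0]], float)
        Q = P + res_vec
        # symmetric areas: both quotients coincide, so the min equals the
        # P-side value and the closed form is exact
        c = clique_from_points(P, Q, areas_p=[2, 1, 1], areas_q=[2, 1, 1])
        res = score(c, RigidTransform.identity(), area_P=8.0, area_Q=8.0)
        assert res.area_fraction_P == pytest.approx(0.5, rel=1e-12)
        assert res.score == pytest.approx(2 * np.sqrt(0.75), rel=1e-12)
        # asymmetric Q areas: the reported score is the min of the two
        # independently evaluated quotients
        c2 = clique_from_points(P, Q, areas_p=[2, 1, 1], areas_q=[200, 100, 100])
        res2 = score(c2, RigidTransform.identity(), area_P=8.0, area_Q=410.0)
        num_p = np.sqrt((2 * 1 + 1 * 0 + 1 * 1) / 4.0)
        num_q = np.sqrt((200 * 1 + 100 * 0 + 100 * 1) / 400.0)
        d_pq = num_p / (4.0 / 8.0)
        d_qp = num_q / (400.0 / 410.0)
        assert res2.score == pytest.approx(min(d_pq, d_qp), rel=1e-12)

    def test_zero_clique_area_raises(self):
        P = np.eye(3)
        c = clique_from_points(P, P, areas_p=[0, 0, 0])
        with pytest.raises(ValueError):
            score(c, RigidTransform.identity(), 1.0, 1.0)


@pytest.fixture(scope="module")
def params():
    return Params(r_c=1.5, t_s=0.3)


class TestAlignSurfaces:

    def test_self_alignment_identity(self, bumpy6, params):
        run = align_surfaces(bumpy6.mesh, bumpy6.mesh, params)
        best = run.results[0]
        assert best.score < 1e-9
        assert np.abs(best.transform.matrix() - np.eye(4)).max() < 1e-6

    def test_recovers_applied_rigid_motion(self, bumpy6, params):
        R0 = Rotation.random(random_state=99).as_matrix()
        t0 = np.array([7.0, -2.0, 4.0])
        Q = bumpy6.mesh.transformed(R0, t0)
        run = align_surfaces(bumpy6.mesh, Q, params)
        best = run.results[0]
        composed = best.transform.R @ R0.T
        assert np.abs(composed - np.eye(3)).max() < 1e-3
        moved = bumpy6.mesh.transformed(best.transform.R, best.transform.t)
        assert surface_rmsd(moved, Q) < 0.1

    def test_partial_overlap_recovers_identity(self):
        from curvalign import synthetic

        blob = synthetic.gaussian_blob_surface(seed=5, n_atoms=400)
        cut = synthetic.plane_cut_pair(blob.mesh, 0.8)
        run = align_surfaces(cut.piece_a, cut.piece_b, preset("protein"))
        assert run.results, run.diagnostics
        best = run.results[0]
        v = cut.piece_a.vertices
        err = np.sqrt(np.mean(np.sum((best.transform.apply(v) - v) ** 2, axis=1)))
        assert err < 1.0

    def test_equivariance_under_pre_rotation(self, bumpy6, params):
        G = Rotation.from_euler("zyx", [0.4, -0.2, 1.0]).as_matrix()
        g_t = np.array([1.0, 2.0, -3.0])
        Q1 = bumpy6.mesh.transformed(np.eye(3), np.zeros(3))
        run1 = align_surfaces(bumpy6.mesh, Q1, params)
        run2 = align_surfaces(
            bumpy6.mesh, Q1.transformed(G, g_t), params
        )
        assert len(run1.results) == len(run2.results)
        # exactly tied scores (mirror cliques) may swap rank under the
        # rotated arithmetic; match results by clique identity instead
        by_key1 = {r.clique.key: r for r in run1.results}
        by_key2 = {r.clique.key: r for r in run2.results}
        assert set(by_key1) == set(by_key2)
        for key, r1 in by_key1.items():
            r2 = by_key2[key]
            expect = G @ r1.transform.R
            expect_t = G @ r1.transform.t + g_t
            assert np.abs(r2.transform.R - expect).max() < 1e-6
            assert np.abs(r2.transform.t - expect_t).max() < 1e-6
            assert r2.score == pytest.approx(r1.score, abs=1e-9)

    def test_area_filter_and_relaxation(self, bumpy6, params):
        from dataclasses import replace

        Q = bumpy6.mesh.transformed(np.eye(3), np.zeros(3))
        strict = align_surfaces(bumpy6.mesh, Q, params)
        relaxed = align_surfaces(
            bumpy6.mesh, Q, replace(params, min_area_fraction=0.0, top_k=10**6)
        )
        for r in strict.results:
            # the anti-spurious filter requires sizable coverage of at
            # least one of the two surfaces
            assert max(r.area_fraction_P, r.area_fraction_Q) >= 0.15
        strict_keys = [r.clique.key for r in strict.results]
        relaxed_keys = [r.clique.key for r in relaxed.results]
        assert set(strict_keys) <= set(relaxed_keys)

    def test_deterministic_rerun_byte_identical(self, bumpy6, params):
        import json

        Q = bumpy6.mesh.transformed(
            Rotation.random(random_state=5).as_matrix(), np.zeros(3)
        )
        r1 = run_report(align_surfaces(bumpy6.mesh, Q, params), params)
        r2 = run_report(align_surfaces(bumpy6.mesh, Q, params), params)
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)

    def test_starved_pipeline_reports_stage(self, bumpy6):
        # threshold so high only the global maximum survives: no 3-clique
        run = align_surfaces(bumpy6.mesh, bumpy6.mesh, Params(r_c=1.5, t_s=100.0))
        assert run.results == []
        assert run.diagnostics["failed_stage"] is not None

    def test_report_validates_against_schema(self, bumpy6, params):
        run = align_surfaces(bumpy6.mesh, bumpy6.mesh, params)
        report = run_report(run, params)
        validate_report(report)
        assert report["n_results"] >= 1
        assert len(report["results"][0]["matrix"]) == 16
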