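"""Weighted superposition, RMSD suite, and fold-space projection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tmbundle import (BundleSpec, CaTrace, FoldSpaceProjection, cumulative_rmsd,
                      distance_matrix, environment_weights, make_bundle,
                      make_decoys, project_foldspace, rmsd_suite,
                      weighted_superpose)
from tmbundle.compare import repair_triangle_inequality


def _rigid_copy(trace, seed=1, shift=(3.0, -4.0, 5.0)):
    R = Rotation.random(random_state=seed).as_matrix()
    return CaTrace("copy", list(trace.residue_ids),
                   trace.coords @ R.T + np.asarray(shift))


class TestEnvironmentWeights:
    def test_identical_structures_weight_one(self, bundle4):
        trace, _, _ = bundle4
        w = environment_weights(trace, _rigid_copy(trace))
        np.testing.assert_allclose(w, 1.0, atol=1e-9)

    def test_displaced_residue_gets_lowest_weight(self, bundle4):
        trace, _, _ = bundle4
        moved = trace.coords.copy()
        moved[40] += np.array([20.0, 0, 0])
        b = CaTrace("b", list(trace.residue_ids), moved)
        w = environment_weights(trace, b)
        assert np.argmin(w) == 40

    def test_matches_direct_formula(self, bundle4):
        trace, _, _ = bundle4
        noisy = make_decoys(trace, "noise", magnitude=2.0, seed=3)
        w = environment_weights(trace, noisy, sigma=4.0)
        n = len(trace)
        for i in (0, 17, 55, n - 1):
            da = np.linalg.norm(trace.coords - trace.coords[i], axis=1)
            db = np.linalg.norm(noisy.coords - noisy.coords[i], axis=1)
            delta = np.abs(da - db).sum() / (n - 1)
            assert w[i] == pytest.approx(np.exp(-delta / 4.0))

    def test_length_mismatch_rejected(self, bundle4):
        trace, _, _ = bundle4
        short = CaTrace("s", trace.residue_ids[:-1], trace.coords[:-1])
        with pytest.raises(ValueError):
            environment_weights(trace, short)


class TestWeightedSuperpose:
    def test_rigid_copy_superposes_exactly(self, bundle4, rng):
        trace, _, _ = bundle4
        w = rng.random(len(trace)) + 0.1
        _, _, wrmsd = weighted_superpose(trace, _rigid_copy(trace), w)
        assert wrmsd < 1e-6

    def test_uniform_weights_match_reference_kabsch(self, bundle4):
        # independent oracle: scipy's align_vectors implements the classic
        # unweighted optimal superposition
        trace, _, _ = bundle4
        noisy = make_decoys(trace, "noise", magnitude=3.0, seed=7)
        w = np.ones(len(trace))
        _, _, wrmsd = weighted_superpose(trace, noisy, w)
        a = trace.coords - trace.coords.mean(axis=0)
        b = noisy.coords - noisy.coords.mean(axis=0)
        rot, _ = Rotation.align_vectors(a, b)
        ref = np.sqrt(np.mean(np.sum((a - rot.apply(b)) ** 2, axis=1)))
        assert wrmsd == pytest.approx(ref, abs=1e-6)

    def test_mirror_image_keeps_residual(self, bundle4):
        trace, _, _ = bundle4
        mirror = make_decoys(trace, "mirror")
        _, _, wrmsd = weighted_superpose(trace, mirror, np.ones(len(trace)))
        assert wrmsd > 1.0

    def test_zero_weights_rejected(self, bundle4):
        trace, _, _ = bundle4
        with pytest.raises(ValueError):
            weighted_superpose(trace, trace, np.zeros(len(trace)))


class TestRmsdSuite:
    def test_identical_structures_all_zero(self, bundle4, caps4):
        trace, segments, _ = bundle4
        suite = rmsd_suite(trace, _rigid_copy(trace), segments, caps4)
        assert set(suite) == {"env_weighted", "tm_only", "tm_caps", "whole"}
        assert all(v < 1e-6 for v in suite.values())

    def test_loop_only_deviation_spares_tm(self, bundle4, caps4, rng):
        trace, segments, _ = bundle4
        in_tm = np.zeros(len(trace), bool)
        idx = trace.index_of()
        for seg in segments:
            for r in seg.residues():
                in_tm[idx[r]] = True
        for cap in caps4:
            for r in cap.n_cap + cap.c_cap:
                if r in idx:
                    in_tm[idx[r]] = True
        moved = trace.coords.copy()
        moved[~in_tm] += rng.normal(scale=6.0, size=moved[~in_tm].shape)
        b = CaTrace("loops", list(trace.residue_ids), moved)
        suite = rmsd_suite(trace, b, segments, caps4)
        assert suite["tm_only"] < suite["whole"]

    def test_symmetric(self, bundle4, caps4):
        trace, segments, _ = bundle4
        noisy = make_decoys(trace, "noise", magnitude=3.0, seed=2)
        ab = rmsd_suite(trace, noisy, segments, caps4)
        ba = rmsd_suite(noisy, trace, segments, caps4)
        for k in ab:
            assert ab[k] == pytest.approx(ba[k], abs=1e-6)


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal(self, bundle4):
        trace, _, _ = bundle4
        traces = [trace] + [make_decoys(trace, "noise", magnitude=2.0, seed=k)
                            for k in range(3)]
        d = distance_matrix(traces)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)
        assert np.all(d[~np.eye(4, dtype=bool)] > 0)

    def test_cumulative_rmsd_sorted(self, bundle4):
        trace, _, _ = bundle4
        others = [make_decoys(trace, "noise", magnitude=m, seed=1)
                  for m in (1.0, 3.0, 2.0)]
        vals = cumulative_rmsd(trace, others)
        assert vals == sorted(vals)
        assert len(vals) == 3


class TestProjectFoldspace:
    def test_metric_input_recovered_exactly(self, rng):
        pts = rng.normal(size=(12, 3)) * 5.0
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = project_foldspace(d, dim=3, seed=1)
        assert emb.stress < 1e-6
        dd = np.linalg.norm(emb.coords[:, None] - emb.coords[None, :], axis=-1)
        mask = d > 1e-9
        assert np.max(np.abs(dd[mask] - d[mask]) / d[mask]) < 1e-3

    def test_triangle_violation_repaired(self):
        # 4-point star: the hub-to-tip distances make tip-tip spans of 2,
        # but the declared tip-tip distance 9 violates the triangle bound
        d = np.array([[0, 1, 1, 1],
                      [1, 0, 9, 2],
                      [1, 9, 0, 2],
                      [1, 2, 2, 0]], float)
        fixed = repair_triangle_inequality(d)
        assert fixed[1, 2] == pytest.approx(2.0)
        n = 4
        for a in range(n):
            for b in range(n):
                for c in range(n):
                    assert fixed[a, b] <= fixed[a, c] + fixed[c, b] + 1e-9

    def test_full_dimension_embedding_near_zero_stress(self, rng):
        pts = rng.normal(size=(8, 5))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = project_foldspace(d, dim=7, seed=0)
        assert emb.stress < 1e-6

    def test_permutation_equivariant_distances(self, rng):
        pts = rng.normal(size=(10, 4)) * 3.0
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = project_foldspace(d, dim=3, seed=2)
        perm = rng.permutation(10)
        emb_p = project_foldspace(d[np.ix_(perm, perm)], dim=3, seed=2)
        dd = np.linalg.norm(emb.coords[:, None] - emb.coords[None, :], axis=-1)
        dd_p = np.linalg.norm(emb_p.coords[:, None] - emb_p.coords[None, :], axis=-1)
        np.testing.assert_allclose(dd[np.ix_(perm, perm)], dd_p, atol=1e-3)

    def test_seeded_determinism(self, rng):
        pts = rng.normal(size=(9, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        e1 = project_foldspace(d, dim=2, seed=5)
        e2 = project_foldspace(d, dim=2, seed=5)
        np.testing.assert_allclose(e1.coords, e2.coords)

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            project_foldspace(d, dim=1)

    def test_chirality_horns_separate(self):
        # 10 clockwise + 10 anticlockwise noisy bundles split into two
        # clusters in fold-space — the enantiomer "horns"
        from sklearn.metrics import silhouette_score
        traces, labels = [], []
        for k in range(10):
            t, _, _ = make_bundle(BundleSpec(handedness="clockwise", seed=k))
            traces.append(make_decoys(t, "noise", magnitude=1.0, seed=k))
            labels.append(0)
        for k in range(10):
            t, _, _ = make_bundle(BundleSpec(handedness="anticlockwise", seed=100 + k))
            traces.append(make_decoys(t, "noise", magnitude=1.0, seed=100 + k))
            labels.append(1)
        d = distance_matrix(traces)
        emb = project_foldspace(d, dim=3, seed=1)
        assert silhouette_score(emb.coords, labels) > 0.5


class TestFoldSpaceProjectionEstimator:
    def test_sklearn_style_api(self, rng):
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        est = FoldSpaceProjection(n_components=3, seed=4)
        coords = est.fit_transform(d)
        assert coords.shape == (8, 3)
        assert est.stress_ < 1e-6
        assert est.get_params()["n_components"] == 3
        est.set_params(n_components=2)
        assert est.fit(d).embedding_.shape == (8, 2)
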