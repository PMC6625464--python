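import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy.linalg import subspace_angles
from scipy.optimize import linear_sum_assignment

from olfnet.bold import BOLDRun, simulate_subject_bold
from olfnet.cohort import simulate_cohort
from olfnet.gica import (
    ComponentSet,
    Decomposition,
    GICAConfig,
    back_reconstruct,
    center_and_reduce_subject,
    cluster_restarts,
    concat_and_group_reduce,
    run_fastica,
    select_networks,
)
from olfnet.templates import DMN, ON


class TestSubjectReduction:
    def test_rank_one_data_recovers_planted_series(self):
        rng = np.random.default_rng(0)
        series = rng.standard_normal(60)
        smap = rng.standard_normal(200)
        X = np.outer(series, smap)
        reduced, proj = center_and_reduce_subject(X, k=1)
        r = np.corrcoef(proj["basis"][:, 0], series - series.mean())[0, 1]
        assert abs(r) > 1 - 1e-10

    def test_full_rank_reduction_is_lossless(self):
        # voxel-wise centering removes one temporal degree of freedom,
        # so full rank is t - 1
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 80))
        reduced, proj = center_and_reduce_subject(X, k=29)
        recon = proj["basis"] @ reduced + proj["voxel_means"]
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_truncation_error_equals_discarded_eigenvalues(self):
        # oracle: eigendecomposition of the temporal covariance
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 100))
        k = 10
        reduced, proj = center_and_reduce_subject(X, k=k)
        Xc = X - X.mean(axis=0)
        recon = proj["basis"] @ reduced
        sse = np.sum((Xc - recon) ** 2)
        evals = np.sort(np.linalg.eigvalsh(Xc @ Xc.T))[::-1]
        np.testing.assert_allclose(sse, evals[k:].sum(), rtol=1e-8)

    def test_k_beyond_rank_rejected(self):
        X = np.outer(np.arange(20.0), np.arange(50.0))  # rank 1 after centering
        with pytest.raises(ValueError, match="rank"):
            center_and_reduce_subject(X, k=5)


class TestGroupReduction:
    def test_identical_subjects_triple_the_spectrum(self):
        rng = np.random.default_rng(3)
        reduced, _ = center_and_reduce_subject(rng.standard_normal((40, 90)), k=10)
        _, proj1 = concat_and_group_reduce([reduced], K=10)
        _, proj3 = concat_and_group_reduce([reduced] * 3, K=10)
        np.testing.assert_allclose(
            proj3["eigvals"], 3.0 * proj1["eigvals"], rtol=1e-8
        )

    def test_two_source_data_spans_both_sources(self):
        rng = np.random.default_rng(4)
        s = rng.standard_normal((2, 500))
        mixes = [rng.standard_normal((20, 2)) @ s for _ in range(3)]
        Z, _ = concat_and_group_reduce(mixes, K=2)
        angles = subspace_angles(Z.T, s.T)
        assert np.degrees(angles).max() < 5

    def test_whitened_covariance_is_identity(self):
        rng = np.random.default_rng(5)
        parts = [rng.standard_normal((15, 300)) for _ in range(4)]
        Z, _ = concat_and_group_reduce(parts, K=12)
        cov = Z @ Z.T / Z.shape[1]
        np.testing.assert_allclose(cov, np.eye(12), atol=1e-6)

    def test_mismatched_grids_rejected_naming_subjects(self):
        a = np.zeros((5, 100))
        b = np.zeros((5, 90))
        with pytest.raises(ValueError, match=r"\[1\]"):
            concat_and_group_reduce([a, b], K=2)


class TestFastICA:
    def _planted_laplacian(self, seed=6, n=3, v=5000):
        rng = np.random.default_rng(seed)
        S = rng.laplace(size=(n, v))
        A = rng.standard_normal((n, n))
        return S, A @ S

    def test_planted_sources_recovered_up_to_sign_permutation(self):
        S, X = self._planted_laplacian()
        Z, _ = concat_and_group_reduce([X], K=3)
        cfg = GICAConfig(n_group_pcs=3, n_ics=3, n_restarts=2, seed=0)
        decomps = run_fastica(Z, cfg)
        got = decomps[0].maps
        C = np.abs(np.corrcoef(got, S)[:3, 3:])
        rows, cols = linear_sum_assignment(-C)
        assert (C[rows, cols] > 0.99).all()

    def test_unmixing_orthonormal(self):
        S, X = self._planted_laplacian(seed=7)
        Z, _ = concat_and_group_reduce([X], K=3)
        cfg = GICAConfig(n_group_pcs=3, n_ics=3, n_restarts=3, seed=1)
        for d in run_fastica(Z, cfg):
            np.testing.assert_allclose(
                d.unmixing @ d.unmixing.T, np.eye(3), atol=1e-6
            )

    def test_same_seed_identical_decomposition(self):
        S, X = self._planted_laplacian(seed=8)
        Z, _ = concat_and_group_reduce([X], K=3)
        cfg = GICAConfig(n_group_pcs=3, n_ics=3, n_restarts=2, seed=42)
        a = run_fastica(Z, cfg)
        b = run_fastica(Z, cfg)
        for da, db in zip(a, b):
            assert np.array_equal(da.maps, db.maps)

    def test_gaussian_input_yields_unreliable_components(self):
        # ICA is unidentifiable for Gaussian sources: restarts disagree, so
        # either convergence fails or the stability indices drop.
        rng = np.random.default_rng(9)
        X = rng.standard_normal((5, 4000))
        Z, _ = concat_and_group_reduce([X], K=5)
        cfg = GICAConfig(n_group_pcs=5, n_ics=5, n_restarts=4, seed=2)
        decomps = run_fastica(Z, cfg)
        comps = cluster_restarts(decomps, 5)
        assert (not all(d.converged for d in decomps)) or comps.stability.min() < 0.9

    def test_nonfinite_input_rejected(self):
        Z = np.full((3, 100), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            run_fastica(Z, GICAConfig(n_group_pcs=3, n_ics=3))


def _orthogonal_maps(n=4, v=400):
    """Zero-mean, mutually orthonormal maps (so between-map correlation = 0)."""
    rng = np.random.default_rng(10)
    basis = np.column_stack([np.ones(v), rng.standard_normal((v, n))])
    Q, _ = np.linalg.qr(basis)
    return Q[:, 1:].T.copy()


class TestRestartClustering:
    def test_identical_restarts_give_unit_stability(self):
        maps = _orthogonal_maps()
        decomps = [
            Decomposition(maps.copy(), np.eye(4), True, 10, s) for s in range(5)
        ]
        comps = cluster_restarts(decomps, 4)
        np.testing.assert_allclose(comps.stability, 1.0, atol=1e-6)

    def test_noise_replaced_component_has_lowest_stability(self):
        maps = _orthogonal_maps()
        rng = np.random.default_rng(11)
        decomps = []
        for s in range(6):
            m = maps.copy()
            m[3] = rng.standard_normal(m.shape[1])  # fresh noise each restart
            m[3] /= np.linalg.norm(m[3])
            decomps.append(Decomposition(m, np.eye(4), True, 10, s))
        comps = cluster_restarts(decomps, 4)
        # stable clusters carry the three intact maps; the noise cluster is last
        assert comps.stability[-1] == comps.stability.min()
        assert comps.stability[:3].min() > comps.stability[-1] + 0.2

    def test_cluster_count_matches_contract(self):
        maps = _orthogonal_maps()
        decomps = [Decomposition(maps, np.eye(4), True, 10, s) for s in range(3)]
        comps = cluster_restarts(decomps, 4)
        assert comps.n_ics == 4
        assert comps.maps.shape == (4, 400)

    def test_single_restart_rejected(self):
        maps = _orthogonal_maps()
        with pytest.raises(ValueError, match="2 restarts"):
            cluster_restarts([Decomposition(maps, np.eye(4), True, 10, 0)], 4)


class TestNetworkSelection:
    def _components_from_templates(self, templates, mask, extra=2):
        rng = np.random.default_rng(12)
        rows = [t.map[mask].astype(float) for t in templates]
        rows += [rng.standard_normal(rows[0].size) for _ in range(extra)]
        maps = np.array([r / np.linalg.norm(r) for r in rows])
        return ComponentSet(
            maps=maps,
            stability=np.linspace(1.0, 0.5, len(rows)),
            assignments=np.arange(len(rows)),
        )

    def test_exact_templates_matched_with_unit_score(self, templates):
        mask = np.ones(templates[0].map.shape, bool)
        comps = self._components_from_templates(templates, mask)
        pair = select_networks(comps, templates, mask)
        assert pair.on_index == 0 and pair.dmn_index == 1
        assert pair.match_scores[ON] == pytest.approx(1.0)
        assert pair.match_scores[DMN] == pytest.approx(1.0)
        assert all(pair.matched.values())

    def test_sign_flipped_component_reoriented(self, templates):
        mask = np.ones(templates[0].map.shape, bool)
        comps = self._components_from_templates(templates, mask)
        comps.maps[0] = -comps.maps[0]
        pair = select_networks(comps, templates, mask)
        tv = templates[0].map[mask]
        r = np.corrcoef(pair.maps[ON], tv)[0, 1]
        assert r > 0.99

    def test_all_noise_components_warn_unmatched(self, templates):
        mask = np.ones(templates[0].map.shape, bool)
        n_warned = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            maps = rng.standard_normal((4, int(mask.sum())))
            comps = ComponentSet(
                maps=maps / np.linalg.norm(maps, axis=1, keepdims=True),
                stability=np.full(4, 0.5),
                assignments=np.arange(4),
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                pair = select_networks(comps, templates, mask)
            if not all(pair.matched.values()):
                n_warned += 1
                assert any("below floor" in str(w.message) for w in caught)
        assert n_warned == 20


class TestBackReconstruction:
    def _run_from(self, maps3d, series, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        data = np.einsum("nxyz,tn->xyzt", maps3d, series)
        data = data + rng.normal(0, noise, data.shape) if noise else data
        return BOLDRun(data=data, mask=np.ones(maps3d.shape[1:4], bool), tr=2.0)

    def test_noiseless_recovery_is_exact(self, templates):
        mask = np.ones(templates[0].map.shape, bool)
        maps3d = np.stack([t.map for t in templates])
        rng = np.random.default_rng(13)
        series = rng.standard_normal((50, 2))
        run = self._run_from(maps3d, series)
        comps = ComponentSet(
            maps=np.stack([t.map[mask] for t in templates]),
            stability=np.ones(2), assignments=np.arange(2),
        )
        rec = back_reconstruct(comps, run)
        got = rec["timecourses"] * rec["scale"]
        centered = series - series.mean(axis=0)
        np.testing.assert_allclose(got, centered, atol=1e-6)

    def test_noisy_recovery_correlates_with_planted(
        self, design, templates, spec, cn_cohort
    ):
        mask = np.ones(templates[0].map.shape, bool)
        comps = ComponentSet(
            maps=np.stack([t.map[mask] for t in templates]),
            stability=np.ones(2), assignments=np.arange(2),
        )
        rs = []
        for seed in range(5):
            run, planted = simulate_subject_bold(
                cn_cohort.iloc[0], design, templates, spec,
                seed=seed, return_planted=True,
            )
            rec = back_reconstruct(comps, run)
            rs.append(np.corrcoef(rec["timecourses"][:, 0], planted["eta"][:, 0])[0, 1])
        assert np.mean(rs) >= 0.9

    def test_permuting_maps_permutes_outputs(self, templates):
        mask = np.ones(templates[0].map.shape, bool)
        maps3d = np.stack([t.map for t in templates])
        series = np.random.default_rng(14).standard_normal((40, 2))
        run = self._run_from(maps3d, series, noise=0.1, seed=1)
        flat = np.stack([t.map[mask] for t in templates])
        a = back_reconstruct(
            ComponentSet(flat, np.ones(2), np.arange(2)), run
        )
        b = back_reconstruct(
            ComponentSet(flat[::-1].copy(), np.ones(2), np.arange(2)), run
        )
        np.testing.assert_allclose(
            a["timecourses"], b["timecourses"][:, ::-1], atol=1e-10
        )

    def test_collinear_group_maps_rejected(self, templates):
        mask = np.ones(templates[0].map.shape, bool)
        flat = templates[0].map[mask]
        comps = ComponentSet(
            maps=np.stack([flat, 2 * flat]),
            stability=np.ones(2), assignments=np.arange(2),
        )
        run = self._run_from(
            np.stack([t.map for t in templates]),
            np.random.default_rng(15).standard_normal((30, 2)),
        )
        with pytest.raises(ValueError, match="rank"):
            back_reconstruct(comps, run)
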