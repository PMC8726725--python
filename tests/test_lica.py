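"""Linked factorization: standardization, recovery, ARD, objective behaviour."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

import gblica
from gblica.errors import DimensionError, ParameterError
from gblica.evaluate import match_components, planted_contributions
from gblica.lica import (
    LicaInput,
    LicaModel,
    contribution_fractions,
    fit_lica,
    reconstruct,
    standardize_modalities,
)


def raw_input(X, scales=None):
    """Wrap an already-prepared matrix list without re-standardizing."""
    K = len(X)
    n = X[0].shape[1]
    return LicaInput(
        modalities=[np.asarray(x, float) for x in X],
        modality_names=[f"m{k}" for k in range(K)],
        subject_ids=[f"s{i}" for i in range(n)],
        scales=np.ones(K) if scales is None else np.asarray(scales),
        row_means=[np.zeros(x.shape[0]) for x in X],
    )


class TestStandardize:
    def test_unit_mean_square(self):
        rng = np.random.default_rng(0)
        inp = standardize_modalities([rng.standard_normal((20, 10)) * 7 + 3])
        assert np.mean(inp.modalities[0] ** 2) == pytest.approx(1.0, abs=1e-12)

    def test_constant_feature_centered_to_zero(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((5, 8))
        X[2] = 4.2
        inp = standardize_modalities([X])
        np.testing.assert_allclose(inp.modalities[0][2], 0.0, atol=1e-12)

    def test_inverse_transform_round_trips(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 9)) * 3 + 1
        inp = standardize_modalities([X])
        np.testing.assert_allclose(inp.inverse_transform(0, inp.modalities[0]),
                                   X, atol=1e-10)

    def test_zero_variance_modality_rejected(self):
        with pytest.raises(ParameterError, match="zero variance"):
            standardize_modalities([np.ones((4, 6))])

    def test_subject_count_mismatch_rejected(self):
        with pytest.raises(DimensionError, match="subject counts"):
            standardize_modalities([np.ones((4, 6)), np.ones((4, 5))])

    def test_scale_invariance_of_fit(self):
        rng = np.random.default_rng(3)
        raw = [rng.standard_normal((30, 15)), rng.standard_normal((12, 15))]
        a = fit_lica(standardize_modalities(raw), n_components=2, seed=0)
        scaled = [raw[0] * 10, raw[1]]
        b = fit_lica(standardize_modalities(scaled), n_components=2, seed=0)
        np.testing.assert_allclose(a.H, b.H, atol=1e-8)
        np.testing.assert_allclose(contribution_fractions(a).P,
                                   contribution_fractions(b).P, atol=1e-8)


class TestFit:
    def test_rank_one_noiseless_is_exact(self):
        rng = np.random.default_rng(42)
        F, N, lam = 50, 20, 7.5
        s = rng.standard_normal(F)
        s /= np.linalg.norm(s)
        h = rng.standard_normal(N)
        h /= np.linalg.norm(h)
        X = lam * np.outer(s, h)
        m = fit_lica(raw_input([X]), n_components=1, seed=0)
        assert m.lambdas[0, 0] == pytest.approx(lam, abs=1e-6)
        assert np.abs(reconstruct(m, 0) - X).max() < 1e-6
        np.testing.assert_allclose(contribution_fractions(m).P, [[1.0]])

    def test_planted_components_recovered(self, default_cohort, default_fit):
        lica_input, model = default_fit
        perm, r = match_components(model.H, default_cohort.truth.H)
        assert sorted(perm.tolist()) == [0, 1, 2]
        assert np.all(r >= 0.9)
        P = contribution_fractions(model)
        P_true = planted_contributions(default_cohort.truth, lica_input.scales)
        assert np.abs(P.P[:, perm] - P_true).max() <= 0.1

    def test_ard_shrinks_zero_weight_modality(self):
        lam = np.array([[1.0, 1.0], [0.0, 0.0], [1.0, 1.0]])
        c = gblica.make_joint_dataset(n_components=2, lambda_matrix=lam, seed=3)
        inp = standardize_modalities(c.modalities, c.modality_names, c.subject_ids)
        m = fit_lica(inp, n_components=2, seed=3)
        assert np.all(m.lambdas[1] <= 0.05 * m.lambdas.max())

    def test_objective_trace_monotone(self, default_fit):
        _, model = default_fit
        diffs = np.diff(model.objective_trace)
        scale = 1.0 + np.abs(model.objective_trace[0])
        assert diffs.min() >= -1e-8 * scale

    def test_loading_rows_unit_norm_and_sign_fixed(self, default_fit):
        _, model = default_fit
        np.testing.assert_allclose(np.linalg.norm(model.H, axis=1), 1.0, atol=1e-9)
        for c in range(model.n_components):
            assert model.H[c, np.argmax(np.abs(model.H[c]))] > 0

    def test_components_ordered_by_explained_variance(self, default_fit):
        _, model = default_fit
        totals = np.sum(model.lambdas**2, axis=0)
        assert np.all(np.diff(totals) <= 1e-9)

    def test_noiseless_matches_rotation_search_oracle(self):
        """Sparse-source ICA at zero noise agrees with an exhaustive
        SVD-plus-rotation-grid oracle in subspace angle."""
        c = gblica.make_joint_dataset(n_subjects=25, n_components=2,
                                      noise_sd=0.0, seed=5)
        inp = standardize_modalities(c.modalities, c.modality_names, c.subject_ids)
        m = fit_lica(inp, n_components=2, seed=5)
        stacked = np.vstack(inp.modalities)
        _, _, Vt = np.linalg.svd(stacked, full_matrices=False)
        basis = Vt[:2]
        # oracle: coarse grid of rotations maximizing source sparsity (L1/L2)
        best, best_obj = basis, np.inf
        for theta in np.linspace(-np.pi / 4, np.pi / 4, 181):
            R = np.array([[np.cos(theta), np.sin(theta)],
                          [-np.sin(theta), np.cos(theta)]])
            Hc = R @ basis
            A = stacked @ Hc.T
            obj = sum(np.abs(A[:, c]).sum() / np.linalg.norm(A[:, c])
                      for c in range(2))
            if obj < best_obj:
                best, best_obj = Hc, obj
        assert subspace_angles(m.H.T, best.T).max() <= 1e-3

    def test_invalid_arguments_rejected(self):
        X = np.random.default_rng(0).standard_normal((6, 4))
        with pytest.raises(ParameterError, match="exceeds subject count"):
            fit_lica(raw_input([X]), n_components=5)
        with pytest.raises(ParameterError, match="max_iter"):
            fit_lica(raw_input([X]), n_components=2, max_iter=0)

    def test_recovery_degrades_monotonically_with_noise(self):
        """Mean matched |r| falls monotonically with the noise level over the
        range where recovery is not saturated (below noise sd ~0.3 recovery
        sits at ~0.99 and the curve is flat)."""
        means = []
        for noise_sd in [0.3, 1.0, 3.0, 10.0]:
            rs = []
            for s in range(20):
                c = gblica.make_joint_dataset(
                    n_subjects=30, n_genera=30, grid_shape=(5, 5, 5),
                    n_networks=1, n_components=2, sparsity=0.1,
                    noise_sd=noise_sd, seed=100 + s, make_counts=False,
                )
                inp = standardize_modalities(c.modalities, c.modality_names,
                                             c.subject_ids)
                m = fit_lica(inp, n_components=2, seed=s)
                _, r = match_components(m.H, c.truth.H)
                rs.append(r.mean())
            means.append(np.mean(rs))
        assert all(np.diff(means) <= 1e-3)


class TestContributions:
    def _stub_model(self, lambdas):
        lambdas = np.asarray(lambdas, float)
        K, C = lambdas.shape
        rng = np.random.default_rng(0)
        H = rng.standard_normal((C, 8))
        H /= np.linalg.norm(H, axis=1, keepdims=True)
        sources = []
        for _ in range(K):
            S = rng.standard_normal((10, C))
            S /= np.linalg.norm(S, axis=0, keepdims=True)
            sources.append(S)
        return LicaModel(
            H=H, sources=sources, lambdas=lambdas, betas=np.ones(K),
            modality_names=[f"m{k}" for k in range(K)],
            subject_ids=[f"s{i}" for i in range(8)], scales=np.ones(K),
            row_means=[np.zeros(10) for _ in range(K)],
        )

    @pytest.mark.parametrize("lam,expected", [
        ([[2.0], [0.0]], [[1.0], [0.0]]),
        ([[1.0], [1.0]], [[0.5], [0.5]]),
    ])
    def test_closed_form_columns(self, lam, expected):
        P = contribution_fractions(self._stub_model(lam))
        np.testing.assert_allclose(P.P, expected)

    def test_degenerate_column_uniform_and_flagged(self):
        P = contribution_fractions(self._stub_model([[1.0, 0.0], [1.0, 0.0]]))
        assert P.degenerate == [1]
        np.testing.assert_allclose(P.P[:, 1], 0.5)

    def test_columns_sum_to_one(self, default_fit):
        _, model = default_fit
        P = contribution_fractions(model)
        np.testing.assert_allclose(P.P.sum(axis=0), 1.0, atol=1e-9)

    def test_modality_permutation_equivariance(self):
        c = gblica.make_joint_dataset(n_subjects=25, n_components=2,
                                      noise_sd=0.0, seed=8)
        inp = standardize_modalities(c.modalities, c.modality_names, c.subject_ids)
        P = contribution_fractions(fit_lica(inp, n_components=2, seed=8))
        order = [2, 0, 1]
        inp_perm = standardize_modalities([c.modalities[k] for k in order],
                                          [c.modality_names[k] for k in order],
                                          c.subject_ids)
        P_perm = contribution_fractions(fit_lica(inp_perm, n_components=2, seed=8))
        np.testing.assert_allclose(P_perm.P, P.P[order], atol=1e-6)


class TestReconstruct:
    def test_full_subset_matches_noiseless_input(self):
        """Multi-component noiseless reconstruction is exact up to the
        posterior shrinkage implied by the spike/noise variance floors
        (~1e-4 of the unit modality scale); the rank-1 case is 1e-6."""
        c = gblica.make_joint_dataset(n_subjects=25, n_components=2,
                                      noise_sd=0.0, seed=5)
        inp = standardize_modalities(c.modalities, c.modality_names, c.subject_ids)
        m = fit_lica(inp, n_components=2, seed=5)
        for k in range(len(inp.modalities)):
            err = np.abs(reconstruct(m, k) - inp.modalities[k]).max()
            assert err < 1e-4

    def test_empty_subset_is_zero(self, default_fit):
        _, model = default_fit
        assert not np.any(reconstruct(model, 0, components=[]))

    def test_residual_variance_matches_noise_precision(self, default_fit):
        lica_input, model = default_fit
        for k in range(len(lica_input.modalities)):
            resid = lica_input.modalities[k] - reconstruct(model, k)
            ratio = np.mean(resid**2) * model.betas[k]
            assert 0.9 <= ratio <= 1.1

    def test_invalid_component_subset_rejected(self, default_fit):
        _, model = default_fit
        with pytest.raises(ParameterError, match="out of range"):
            reconstruct(model, 0, components=[99])
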