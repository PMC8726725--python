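"""Component selection, dominance/constant-map QC and report rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gblica.errors import ParameterError
from gblica.lica import ContributionMatrix, LicaModel
from gblica.report import (
    build_reports,
    flag_constant_map,
    load_reports,
    render_report,
    select_components,
    subject_dominance,
    threshold_loadings,
)


def stub_model(H=None, sources=None, lambdas=None, n_subjects=8, n_features=(20, 12),
               names=("DMN", "genus")):
    rng = np.random.default_rng(0)
    if H is None:
        C = lambdas.shape[1] if lambdas is not None else 2
        H = rng.standard_normal((C, n_subjects))
        H /= np.linalg.norm(H, axis=1, keepdims=True)
    C = H.shape[0]
    if sources is None:
        sources = []
        for F in n_features:
            S = rng.standard_normal((F, C))
            S /= np.linalg.norm(S, axis=0, keepdims=True)
            sources.append(S)
    if lambdas is None:
        lambdas = np.ones((len(sources), C))
    return LicaModel(
        H=H, sources=sources, lambdas=np.asarray(lambdas, float),
        betas=np.ones(len(sources)), modality_names=list(names),
        subject_ids=[f"sub{i}" for i in range(H.shape[1])],
        scales=np.ones(len(sources)),
        row_means=[np.zeros(S.shape[0]) for S in sources],
    )


def contributions(P, names=("brain", "genus")):
    return ContributionMatrix(P=np.asarray(P, float), modality_names=list(names))


class TestSelection:
    def test_non_marginal_on_both_sides_selected(self):
        P = contributions([[0.75], [0.25]])
        assert select_components(P, micro_modality="genus").tolist() == [True]

    def test_marginal_microbiome_not_selected(self):
        P = contributions([[0.90], [0.10]])
        assert select_components(P, micro_modality="genus").tolist() == [False]

    def test_exhaustive_grid_matches_bruteforce(self):
        grid = np.round(np.arange(0, 101) * 0.01, 2)
        cols = np.stack([1 - grid, grid])          # brain, genus fractions
        P = ContributionMatrix(P=cols, modality_names=["brain", "genus"])
        flags = select_components(P, threshold=0.2, micro_modality="genus")
        brute = [(g > 0.2) and ((1 - g) > 0.2) for g in grid]
        assert flags.tolist() == brute

    def test_invariant_under_component_reordering(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(0, 1, size=10)
        P = ContributionMatrix(P=np.stack([1 - g, g]),
                               modality_names=["brain", "genus"])
        flags = select_components(P, micro_modality="genus")
        perm = rng.permutation(10)
        P2 = ContributionMatrix(P=P.P[:, perm], modality_names=P.modality_names)
        flags2 = select_components(P2, micro_modality="genus")
        assert flags2.tolist() == flags[perm].tolist()


class TestDominance:
    def test_one_hot_row_fully_dominant(self):
        H = np.zeros((1, 6))
        H[0, 3] = 1.0
        m = stub_model(H=H)
        dom, subject, flagged = subject_dominance(m, 0)
        assert dom == 1.0 and flagged and subject == "sub3"

    def test_constant_row_is_uniform(self):
        R = 8
        H = np.full((1, R), 1 / np.sqrt(R))
        dom, _, flagged = subject_dominance(stub_model(H=H), 0)
        assert dom == pytest.approx(1 / R)
        assert not flagged

    def test_planted_spike_identified(self):
        rng = np.random.default_rng(1)
        row = rng.standard_normal(40)
        row[17] = 10 * np.sqrt(np.mean(np.delete(row, 17) ** 2))
        H = (row / np.linalg.norm(row))[None, :]
        dom, subject, flagged = subject_dominance(stub_model(H=H), 0)
        assert flagged and subject == "sub17" and dom > 0.5

    def test_zero_row_rejected(self):
        m = stub_model(H=np.ones((1, 5)) / np.sqrt(5))
        m.H = np.zeros((1, 5))
        with pytest.raises(ParameterError, match="all-zero"):
            subject_dominance(m, 0)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=20).filter(
        lambda x: any(abs(v) > 1e-3 for v in x)))
    def test_dominance_bounded(self, row):
        H = np.asarray(row)[None, :]
        H = H / np.linalg.norm(H)
        dom, _, _ = subject_dominance(stub_model(H=H), 0)
        assert 1 / len(row) - 1e-12 <= dom <= 1.0 + 1e-12


class TestConstantMap:
    def _model_with_columns(self, cols):
        S = np.column_stack(cols)
        S = S / np.maximum(np.linalg.norm(S, axis=0, keepdims=True), 1e-300)
        C = S.shape[1]
        return stub_model(H=np.eye(C, 8) * 0 + np.linalg.qr(
            np.random.default_rng(0).standard_normal((8, C)))[0].T,
            sources=[S, np.random.default_rng(1).standard_normal((12, C))],
            lambdas=np.ones((2, C)))

    def test_constant_column_flagged(self):
        rng = np.random.default_rng(0)
        m = self._model_with_columns([np.ones(30), rng.standard_normal(30)])
        assert flag_constant_map(m, 0, 0)
        assert not flag_constant_map(m, 0, 1)

    def test_tiny_noise_still_flagged_but_unit_noise_not(self):
        rng = np.random.default_rng(2)
        near_const = 1.0 + 1e-6 * rng.standard_normal(30)
        noisy = 1.0 + rng.standard_normal(30)
        m = self._model_with_columns([near_const, noisy])
        assert flag_constant_map(m, 0, 0)
        assert not flag_constant_map(m, 0, 1)


class TestThresholding:
    def test_single_outlier_survives_both_thresholds(self):
        rng = np.random.default_rng(4)
        col = rng.standard_normal(200)
        col[50] = col.mean() + 8 * col.std()
        S_brain = np.column_stack([col / np.linalg.norm(col)])
        S_micro = np.column_stack([col[:12] / np.linalg.norm(col[:12])])
        m = stub_model(H=np.ones((1, 8)) / np.sqrt(8),
                       sources=[S_brain, S_micro], lambdas=np.ones((1, 1)) * 0 + 1)
        m.lambdas = np.ones((2, 1))
        brain, genera = threshold_loadings(m, micro_modality="genus",
                                           genus_ids=[f"g{i}" for i in range(12)])
        assert brain[0]["DMN"]["voxels"] == [50]

    def test_all_equal_column_yields_empty_sets(self):
        S_brain = np.column_stack([np.ones(20) / np.sqrt(20)])
        S_micro = np.column_stack([np.ones(12) / np.sqrt(12)])
        m = stub_model(H=np.ones((1, 8)) / np.sqrt(8),
                       sources=[S_brain, S_micro], lambdas=np.ones((2, 1)))
        brain, genera = threshold_loadings(m, micro_modality="genus")
        assert brain[0] == {} and genera[0] == []

    def test_zero_threshold_reports_every_feature(self):
        rng = np.random.default_rng(5)
        m = stub_model()
        brain, genera = threshold_loadings(m, brain_z=0.0, micro_z=0.0,
                                           micro_modality="genus")
        for c in range(m.n_components):
            assert len(brain[c]["DMN"]["voxels"]) == m.sources[0].shape[0]
            assert len(genera[c]) == m.sources[1].shape[0]

    def test_signs_reported(self):
        rng = np.random.default_rng(6)
        col = rng.standard_normal(40)
        col[3] = 9.0
        col[4] = -9.0
        S_micro = np.column_stack([col / np.linalg.norm(col)])
        m = stub_model(H=np.ones((1, 8)) / np.sqrt(8),
                       sources=[np.random.default_rng(0).standard_normal((20, 1)),
                                S_micro],
                       lambdas=np.ones((2, 1)))
        _, genera = threshold_loadings(m, micro_modality="genus",
                                       genus_ids=[f"g{i}" for i in range(40)])
        signs = {g["genus"]: g["sign"] for g in genera[0]}
        assert signs["g3"] == "+" and signs["g4"] == "-"


class TestRendering:
    def _reports(self):
        rng = np.random.default_rng(7)
        lambdas = np.array([[1.0, 2.0, 0.5],
                            [1.0, 0.5, 3.0]])     # component 2 micro-heavy
        m = stub_model(lambdas=lambdas)
        return m, build_reports(m, micro_modality="genus",
                                genus_ids=[f"g{i}" for i in range(12)])

    def test_round_trip_through_rendered_files(self, tmp_path):
        m, reports = self._reports()
        render_report(reports, [f"g{i}" for i in range(12)], ["DMN"], tmp_path)
        back = load_reports(tmp_path)
        assert len(back) == len(reports)
        for a, b in zip(back, reports):
            assert a.component_id == b.component_id
            assert a.P_column == pytest.approx(b.P_column)
            assert a.selected == b.selected
            assert a.thresholded_genera == b.thresholded_genera

    def test_micro_heavy_component_ranked_first(self, tmp_path):
        m, reports = self._reports()
        render_report(reports, [f"g{i}" for i in range(12)], ["DMN"], tmp_path)
        digest = (tmp_path / "digest.txt").read_text()
        assert "most microbiome-weighted component: 2" in digest

    def test_no_suprathreshold_genera_stated(self):
        S_micro = np.column_stack([np.full(12, 1 / np.sqrt(12))])
        m = stub_model(H=np.ones((1, 8)) / np.sqrt(8),
                       sources=[np.random.default_rng(0).standard_normal((20, 1)),
                                S_micro],
                       lambdas=np.array([[0.5], [2.0]]))
        reports = build_reports(m, micro_modality="genus")
        assert "no genus loadings above threshold" in reports[0].digest
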