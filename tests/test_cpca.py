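"""Consensus PCA: oracle equivalence, invariants and correlation loadings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidblocks.cpca import (
    CPCAError,
    concatenated_svd_scores,
    correlation_loadings,
    fit_cpca,
    score_plot_data,
)
from lipidblocks.preprocessing import Block, BlockSet, build_blocks
from tests.conftest import make_blockset


class TestOracleEquivalence:
    def test_single_block_equals_pca(self):
        rng = np.random.default_rng(1)
        index = pd.Index([f"s{i}" for i in range(15)])
        data = rng.normal(size=(15, 6))
        data -= data.mean(axis=0)
        df = pd.DataFrame(data, index=index, columns=[f"v{j}" for j in range(6)])
        blocks = BlockSet({"X": Block(df, df.mean(), df.std(ddof=1))})
        model = fit_cpca(blocks, 3)
        U, s, Vt = np.linalg.svd(data, full_matrices=False)
        for a in range(3):
            pca_scores = U[:, a] * s[a]
            got = model.global_scores.iloc[:, a].to_numpy()
            err = min(
                np.abs(got - pca_scores).max(), np.abs(got + pca_scores).max()
            )
            assert err < 1e-8

    @given(
        n=st.integers(8, 32),
        widths=st.lists(st.integers(3, 20), min_size=5, max_size=5),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25)
    def test_five_block_scores_match_concatenated_svd(self, n, widths, seed):
        blocks = make_blockset(np.random.default_rng(seed), n, widths)
        k = min(3, n - 1)
        model = fit_cpca(blocks, k)
        svd_scores = concatenated_svd_scores(blocks, k)
        for a in range(k):
            ref = svd_scores[:, a]
            got = model.global_scores.iloc[:, a].to_numpy()
            err = min(np.abs(got - ref).max(), np.abs(got + ref).max())
            assert err / np.abs(ref).max() < 1e-6

    def test_rank1_noiseless_blocks_give_100_percent_ev(self):
        rng = np.random.default_rng(7)
        index = pd.Index([f"s{i}" for i in range(10)])
        t = rng.normal(size=10)
        t -= t.mean()
        blocks = {}
        for b in range(3):
            p = rng.normal(size=4)
            df = pd.DataFrame(np.outer(t, p), index=index,
                              columns=[f"b{b}v{j}" for j in range(4)])
            blocks[f"B{b}"] = Block(df, df.mean(), pd.Series(1.0, index=df.columns))
        model = fit_cpca(BlockSet(blocks), 1)
        assert model.ev_global.iloc[0] == pytest.approx(1.0, abs=1e-10)


class TestModelInvariants:
    @pytest.fixture(scope="class")
    def fitted(self):
        blocks = make_blockset(np.random.default_rng(11), 16, [4, 6, 3, 8, 5])
        return blocks, fit_cpca(blocks, 4)

    def test_global_scores_orthogonal(self, fitted):
        _, model = fitted
        T = model.global_scores.to_numpy()
        Tn = T / np.linalg.norm(T, axis=0)
        off = Tn.T @ Tn - np.eye(T.shape[1])
        assert np.abs(off).max() < 1e-8

    def test_super_weights_unit_norm(self, fitted):
        _, model = fitted
        norms = np.linalg.norm(model.super_weights.to_numpy(), axis=0)
        assert np.allclose(norms, 1.0, atol=1e-10)

    def test_global_ev_nonincreasing_and_bounded(self, fitted):
        _, model = fitted
        ev = model.ev_global.to_numpy()
        assert ((ev >= 0) & (ev <= 1)).all()
        assert (np.diff(ev) <= 1e-12).all()

    def test_total_ev_sums_to_one(self):
        blocks = make_blockset(np.random.default_rng(2), 8, [3, 4, 2, 5, 3])
        model = fit_cpca(blocks, 7)  # all extractable components (n - 1)
        assert model.ev_global.sum() == pytest.approx(1.0, abs=1e-8)

    def test_deflation_leaves_no_residual_along_scores(self, fitted):
        blocks, model = fitted
        T = model.global_scores.to_numpy()
        for lab, b in blocks.blocks.items():
            X = b.data.to_numpy().copy()
            for a in range(model.n_components):
                X -= np.outer(T[:, a], model.block_loadings[lab].iloc[:, a])
            proj = T.T @ X
            assert np.abs(proj).max() / np.abs(b.data.to_numpy()).max() < 1e-8

    def test_refit_is_bitwise_deterministic(self):
        blocks = make_blockset(np.random.default_rng(9), 12, [3, 5, 4, 6, 2])
        m1 = fit_cpca(blocks, 2)
        m2 = fit_cpca(blocks, 2)
        assert (m1.global_scores.to_numpy() == m2.global_scores.to_numpy()).all()

    def test_too_many_components_rejected(self):
        blocks = make_blockset(np.random.default_rng(1), 6, [2, 2, 2, 2, 2])
        with pytest.raises(CPCAError):
            fit_cpca(blocks, 6)


class TestCorrelationLoadings:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(21)
        blocks = make_blockset(rng, 20, [5, 6, 4, 7, 5])
        model = fit_cpca(blocks, 3)
        return rng, blocks, model

    def test_variable_equal_to_score_1(self, fitted):
        _, blocks, model = fitted
        t1 = model.global_scores.iloc[:, 0]
        data = pd.DataFrame({"v": t1}, index=model.global_scores.index)
        cl = correlation_loadings(model, data, components=(1, 2))
        assert cl.correlations.loc["v", "r_PC1"] == pytest.approx(1.0, abs=1e-10)
        assert cl.correlations.loc["v", "r_PC2"] == pytest.approx(0.0, abs=1e-8)
        assert cl.explained_variance["v"] == pytest.approx(1.0, abs=1e-8)

    def test_variable_orthogonal_to_plotted_scores(self, fitted):
        rng, _, model = fitted
        T = model.global_scores.to_numpy()[:, :2]
        v = rng.normal(size=T.shape[0])
        v -= v.mean()
        v -= T @ np.linalg.lstsq(T, v, rcond=None)[0]  # project out both scores
        data = pd.DataFrame({"v": v}, index=model.global_scores.index)
        cl = correlation_loadings(model, data)
        assert cl.explained_variance["v"] == pytest.approx(0.0, abs=1e-10)

    def test_variable_in_span_of_components_1_2_has_full_ev(self, fitted):
        _, _, model = fitted
        T = model.global_scores
        v = 0.6 * T.iloc[:, 0] - 1.7 * T.iloc[:, 1]
        data = pd.DataFrame({"v": v}, index=T.index)
        cl = correlation_loadings(model, data)
        assert cl.explained_variance["v"] == pytest.approx(1.0, abs=1e-12)

    def test_component_out_of_range(self, fitted):
        _, blocks, model = fitted
        with pytest.raises(IndexError):
            correlation_loadings(model, blocks.concatenated(), components=(1, 9))


class TestScorePlotData:
    def test_levels_and_errors(self, gut_normalized):
        blocks = build_blocks(gut_normalized)
        model = fit_cpca(blocks, 2)
        table = score_plot_data(model, gut_normalized.sample_meta, "global", (1, 2))
        assert len(table) == gut_normalized.n_samples
        assert {"PC1", "PC2", "diet_group", "stage"} <= set(table.columns)
        pc_table = score_plot_data(model, gut_normalized.sample_meta, "PC")
        assert np.allclose(pc_table["PC1"], model.block_scores["PC"]["PC1"])
        with pytest.raises(KeyError):
            score_plot_data(model, gut_normalized.sample_meta, "nope")
        with pytest.raises(IndexError):
            score_plot_data(model, gut_normalized.sample_meta, "global", (1, 3))
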