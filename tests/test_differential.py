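"""Two-way ANOVA, Tukey HSD, fold changes, the significance rule, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidblocks.differential import (
    DesignError,
    heatmap_groups,
    log2_fold_change,
    run_differential,
    significance_filter,
    studentized_range_sf,
    tukey_hsd,
    two_way_anova,
    two_way_anova_matrix,
)

DIETS = [f"g{i}" for i in range(8)]
STAGES_ = ["FW", "SW"]


def _design(n=4):
    diet = np.repeat(DIETS, 2 * n)
    stage = np.tile(np.repeat(STAGES_, n), 8)
    return diet, stage


class TestTwoWayAnova:
    def test_matches_statsmodels_regression_oracle(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(0)
        diet, stage = _design()
        for _ in range(5):
            y = rng.normal(size=len(diet))
            ours = two_way_anova(y, diet, stage)
            df = pd.DataFrame({"y": y, "diet": diet, "stage": stage})
            fit = smf.ols("y ~ C(diet) * C(stage)", data=df).fit()
            tab = sm.stats.anova_lm(fit, typ=2)
            assert ours.ss["diet"] == pytest.approx(tab.loc["C(diet)", "sum_sq"], abs=1e-8)
            assert ours.ss["stage"] == pytest.approx(tab.loc["C(stage)", "sum_sq"], abs=1e-8)
            assert ours.ss["interaction"] == pytest.approx(
                tab.loc["C(diet):C(stage)", "sum_sq"], abs=1e-8
            )
            assert ours.ss["error"] == pytest.approx(tab.loc["Residual", "sum_sq"], abs=1e-8)
            assert ours.p_diet == pytest.approx(tab.loc["C(diet)", "PR(>F)"], abs=1e-10)
            assert ours.p_stage == pytest.approx(tab.loc["C(stage)", "PR(>F)"], abs=1e-10)

    def test_ss_decomposition_is_exact(self):
        rng = np.random.default_rng(1)
        diet, stage = _design()
        y = rng.normal(size=len(diet))
        res = two_way_anova(y, diet, stage)
        ss_total = float(((y - y.mean()) ** 2).sum())
        assert sum(res.ss.values()) == pytest.approx(ss_total, rel=1e-12)

    def test_constant_data_flagged_degenerate(self):
        diet, stage = _design()
        res = two_way_anova(np.full(len(diet), 3.14), diet, stage)
        assert res.degenerate and np.isnan(res.p_diet) and np.isnan(res.p_stage)

    def test_empty_cell_is_design_error_naming_cell(self):
        diet, stage = _design()
        mask = ~((diet == "g3") & (stage == "SW"))
        with pytest.raises(DesignError, match="g3"):
            two_way_anova(np.zeros(mask.sum()), diet[mask], stage[mask])

    def test_unbalanced_design_rejected(self):
        diet, stage = _design()
        with pytest.raises(DesignError, match="[Uu]nbalanced"):
            two_way_anova(np.zeros(len(diet) - 1), diet[:-1], stage[:-1])

    def test_null_type_i_error_near_nominal(self):
        rng = np.random.default_rng(7)
        diet, stage = _design()
        Y = rng.normal(size=(len(diet), 1000))
        res = two_way_anova_matrix(Y, diet, stage)
        rate = float((res["p_stage"] < 0.05).mean())
        lo, hi = stats.binom.interval(0.999, 1000, 0.05)
        assert lo / 1000 <= rate <= hi / 1000

    def test_power_for_two_sd_stage_effect(self):
        rng = np.random.default_rng(8)
        diet, stage = _design()
        Y = rng.normal(size=(len(diet), 200))
        Y[np.asarray(stage) == "SW"] += 2.0  # 2 residual-sd stage offset
        res = two_way_anova_matrix(Y, diet, stage)
        assert (res["p_stage"] < 0.05).mean() > 0.90


class TestTukey:
    def test_identical_cell_means_give_p_one(self):
        means = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        p = tukey_hsd(means, mse=0.5, df_error=9, n_per_cell=4)
        assert np.allclose(p.to_numpy(), 1.0, atol=1e-10)

    def test_published_critical_value_k3_df9(self):
        # q_{0.05}(k=3, df=9) = 3.948 from standard studentized-range tables
        se = np.sqrt(0.5 / 4)
        means = pd.Series({"a": 0.0, "b": 3.948 * se, "c": 0.0})
        p = tukey_hsd(means, mse=0.5, df_error=9, n_per_cell=4, contrasts=[("b", "a")])
        assert p.iloc[0] == pytest.approx(0.05, abs=2e-3)

    def test_matches_scipy_tukey_hsd_end_to_end(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(loc=m, size=5) for m in (0.0, 0.4, 1.0, 0.2)]
        ref = stats.tukey_hsd(*groups)
        k = 4
        n = 5
        mse = np.mean([g.var(ddof=1) for g in groups])
        means = pd.Series({f"g{i}": g.mean() for i, g in enumerate(groups)})
        ours = tukey_hsd(means, mse, df_error=k * (n - 1), n_per_cell=n)
        for i in range(k):
            for j in range(i + 1, k):
                assert ours[(f"g{i}", f"g{j}")] == pytest.approx(
                    ref.pvalue[i, j], abs=1e-8
                )

    def test_monotone_in_family_size(self):
        means = pd.Series({"a": 0.0, "b": 1.0})
        ps = [
            tukey_hsd(means, 0.5, 24, 4, contrasts=[("b", "a")], k_family=k).iloc[0]
            for k in range(2, 17)
        ]
        assert all(p2 >= p1 - 1e-12 for p1, p2 in zip(ps, ps[1:]))

    def test_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = rng.normal(size=4)
            b = rng.normal(size=4)
            mse = (a.var(ddof=1) + b.var(ddof=1)) / 2
            if mse == 0:
                continue
            means = pd.Series({"a": a.mean(), "b": b.mean()})
            p_adj = tukey_hsd(means, mse, df_error=6, n_per_cell=4, k_family=16).iloc[0]
            p_raw = stats.ttest_ind(a, b).pvalue
            assert p_adj >= p_raw - 1e-10

    def test_n_below_two_rejected(self):
        with pytest.raises(DesignError):
            tukey_hsd(pd.Series({"a": 0.0, "b": 1.0}), 0.5, 9, 1)

    def test_fast_sf_matches_scipy_across_grid(self):
        qs = np.array([0.25, 1.0, 2.5, 3.948, 5.5, 8.0, 12.0])
        for k, df in [(2, 6), (3, 9), (8, 30), (16, 48)]:
            ref = stats.studentized_range.sf(qs, k, df)
            ours = studentized_range_sf(qs, k, df)
            assert np.abs(ours - ref).max() < 1e-10


class TestFoldChange:
    def test_examples(self):
        assert log2_fold_change([8.0, 8.0], [4.0, 4.0]) == pytest.approx(1.0)
        assert log2_fold_change([5.0], [5.0]) == 0.0

    def test_nonpositive_mean_is_nan(self):
        assert np.isnan(log2_fold_change([0.0, 0.0], [4.0]))

    def test_empty_group_rejected(self):
        with pytest.raises(DesignError):
            log2_fold_change([], [1.0])


class TestSignificanceFilter:
    def test_worked_triple(self):
        df = pd.DataFrame(
            {
                "log2fc": [1.02, 0.9, 1.5],
                "p": [0.04, 0.001, 0.06],
                "tissue": ["gut"] * 3,
            },
            index=["hit", "small_fc", "weak_p"],
        )
        flagged, counts = significance_filter(df)
        assert list(flagged.index) == ["hit"]
        assert counts["gut"] == 1

    def test_nan_rows_never_flagged(self):
        df = pd.DataFrame({"log2fc": [np.nan, 2.0], "p": [0.001, np.nan]})
        flagged, _ = significance_filter(df)
        assert flagged.empty

    def test_null_data_filter_rate_below_p_rate(self):
        # the fold-change gate can only remove rejections
        rng = np.random.default_rng(9)
        n = 500
        df = pd.DataFrame(
            {"log2fc": rng.normal(0, 0.5, n), "p": rng.uniform(size=n)}
        )
        flagged, _ = significance_filter(df)
        assert len(flagged) <= (df["p"] < 0.05).sum()


class TestHeatmapGroups:
    def test_identical_rows_share_a_group(self):
        row = np.linspace(0, 1, 6)
        mat = pd.DataFrame([row, row, row[::-1]], index=["a", "b", "c"])
        labels, scaled = heatmap_groups(mat, n_groups=2)
        assert labels["a"] == labels["b"] != labels["c"]
        assert np.allclose(scaled.mean(axis=1), 0, atol=1e-12)

    def test_anticorrelated_rows_split_at_k2(self):
        up = np.linspace(0, 1, 8)
        mat = pd.DataFrame([up, up * 2, -up, 1 - up], index=list("abcd"))
        labels, _ = heatmap_groups(mat, n_groups=2)
        assert labels["a"] == labels["b"] != labels["c"] == labels["d"]

    def test_single_row_gets_trivial_group(self):
        mat = pd.DataFrame([[1.0, 2.0]], index=["only"])
        labels, _ = heatmap_groups(mat)
        assert list(labels) == ["A"]

    def test_three_planted_archetypes_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(12)
        t = np.linspace(0, 1, 10)
        archetypes = [np.sin(2 * np.pi * t), t, 1 - t]
        rows, truth = [], []
        for i in range(60):
            a = i % 3
            rows.append(archetypes[a] + rng.normal(0, 0.1, len(t)))
            truth.append(a)
        mat = pd.DataFrame(rows, index=[f"s{i}" for i in range(60)])
        labels, _ = heatmap_groups(mat, n_groups=3)
        codes = labels.astype("category").cat.codes
        assert adjusted_rand_score(truth, codes) >= 0.9

    def test_labels_follow_dendrogram_order_deterministically(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(size=(12, 6)))
        l1, _ = heatmap_groups(mat, 3)
        l2, _ = heatmap_groups(mat, 3)
        assert (l1 == l2).all()
        assert set(l1) <= {"A", "B", "C"}


class TestRunDifferential:
    def test_detects_planted_stage_offsets(self, gut_normalized, small_experiment):
        _, truth = small_experiment
        res = run_differential(gut_normalized)
        offset = truth.species_params.query("is_stage_offset").index
        hit_rate = res.loc[offset, "significant"].mean()
        assert hit_rate >= 0.8  # |offset| = 1.5 log2 units, n = 4

    def test_null_species_rarely_flagged(self, gut_normalized, small_experiment):
        _, truth = small_experiment
        res = run_differential(gut_normalized)
        null = truth.species_params.query("is_null").index
        assert res.loc[null, "significant"].mean() <= 0.05

    def test_flagged_species_get_cluster_groups(self, gut_normalized):
        res = run_differential(gut_normalized)
        flagged = res[res["significant"]]
        if len(flagged) >= 2:
            assert flagged["cluster_group"].notna().all()
        assert res.loc[~res["significant"], "cluster_group"].isna().all()

    def test_requires_single_tissue(self, small_experiment):
        dataset, _ = small_experiment
        two = dataset.sample_meta.copy()
        two.loc[two.index[:10], "tissue"] = "liver"
        ds = dataset.__class__(dataset.abundance, two, dataset.species)
        with pytest.raises(DesignError):
            run_differential(ds)

    def test_anova_p_source_option(self, gut_normalized):
        res = run_differential(gut_normalized, p_source="anova")
        d0 = "p_D0_FO"
        assert np.allclose(
            res[d0].to_numpy(), res["p_stage"].to_numpy(), equal_nan=True
        )
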