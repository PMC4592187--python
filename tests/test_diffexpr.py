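"""Per-gene ANOVA, BH FDR, signed fold change and DEG calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import synerseq as ss
from synerseq.diffexpr import (
    Contrast,
    anova_gene,
    bh_fdr,
    call_degs,
    fold_change,
)

from conftest import pooled_call_degs


class TestAnovaGene:
    def test_identical_groups(self):
        res = anova_gene([(1.0, 1.0, 1.0), (1.0, 1.0, 1.0)])
        assert res.F == 0.0 and res.p == 1.0 and not res.degenerate

    def test_forced_separation_is_degenerate(self):
        res = anova_gene([(0.0, 0.0, 0.0), (10.0, 10.0, 10.0)])
        assert res.p == 0.0 and res.degenerate

    def test_textbook_sums_of_squares(self):
        # hand evaluation of the SS decomposition for a small example
        g1, g2 = np.array([1.2, 1.9, 0.8]), np.array([3.1, 2.7, 3.5])
        grand = np.concatenate([g1, g2]).mean()
        ssb = 3 * (g1.mean() - grand) ** 2 + 3 * (g2.mean() - grand) ** 2
        ssw = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
        F_expected = (ssb / 1) / (ssw / 4)
        p_expected = stats.f.sf(F_expected, 1, 4)
        res = anova_gene([g1, g2])
        assert res.F == pytest.approx(F_expected, abs=1e-10)
        assert res.p == pytest.approx(p_expected, abs=1e-10)

    @pytest.mark.parametrize("n_groups", [2, 3, 4])
    def test_matches_scipy_f_oneway(self, n_groups):
        rng = np.random.default_rng(17)
        for _ in range(200):
            groups = [rng.normal(rng.uniform(-1, 1), 1, size=rng.integers(2, 6))
                      for _ in range(n_groups)]
            res = anova_gene(groups)
            ref = stats.f_oneway(*groups)
            assert res.F == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-8, abs=1e-12)

    def test_two_groups_equal_t_squared(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b = rng.normal(size=4), rng.normal(1, 1, size=3)
            res = anova_gene([a, b])
            t = stats.ttest_ind(a, b, equal_var=True)
            assert res.F == pytest.approx(t.statistic**2, abs=1e-9)
            assert res.p == pytest.approx(t.pvalue, abs=1e-9)

    def test_missing_values_dropped_and_untestable(self):
        res = anova_gene([(1.0, np.nan, 2.0), (3.0, 4.0, 5.0)])
        ref = anova_gene([(1.0, 2.0), (3.0, 4.0, 5.0)])
        assert res == ref
        res = anova_gene([(1.0, np.nan, np.nan), (3.0, 4.0, 5.0)])
        assert np.isnan(res.F) and np.isnan(res.p)


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_nan_propagates_without_joining_family(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_fdr([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_matches_step_up_definition(self, pvals):
        p = np.array(pvals)
        n = len(p)
        order = np.argsort(p, kind="stable")
        expected = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            expected[i] = running
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30))
    def test_monotone_in_p(self, pvals):
        p = np.array(pvals)
        q = bh_fdr(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestFoldChange:
    @pytest.mark.parametrize(
        "test, ref, expected",
        [(20.0, 10.0, 2.0), (10.0, 20.0, -2.0), (10.0, 10.0, 1.0)],
    )
    def test_examples(self, test, ref, expected):
        assert fold_change(test, ref) == pytest.approx(expected)

    def test_zero_handling(self):
        assert fold_change(5.0, 0.0) == np.inf
        assert fold_change(0.0, 5.0) == -np.inf
        assert np.isnan(fold_change(0.0, 0.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=1e-6, max_value=1e6),
        st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_antisymmetry_and_magnitude(self, a, b):
        fc = fold_change(a, b)
        assert abs(fc) >= 1.0
        if a != b:
            assert fold_change(b, a) == pytest.approx(-fc, rel=1e-12)


def two_group_dataset(values_by_gene, n_rep=3):
    """Build an rpkm table + design with conditions test/ref from per-gene pairs."""
    genes = list(values_by_gene)
    test_cols = [f"t{r}" for r in range(1, n_rep + 1)]
    ref_cols = [f"r{r}" for r in range(1, n_rep + 1)]
    rows = [list(v[0]) + list(v[1]) for v in values_by_gene.values()]
    table = ss.ExpressionTable(
        pd.DataFrame(rows, index=genes, columns=test_cols + ref_cols), "rpkm"
    )
    design = ss.DesignSheet(
        pd.DataFrame(
            {
                "doseA": [1.0] * n_rep + [0.0] * n_rep,
                "flagB": True,
                "time": 8,
                "replicate": list(range(1, n_rep + 1)) * 2,
            },
            index=pd.Index(test_cols + ref_cols, name="sample_id"),
        )
    )
    contrast = Contrast(
        "test_vs_ref",
        ss.make_condition_id(1.0, True, 8),
        ss.make_condition_id(0.0, True, 8),
    )
    return table, design, contrast


class TestCallDegs:
    def test_simple_calls(self):
        data = {
            "up": ((40.0, 44.0, 38.0), (10.0, 11.0, 9.0)),
            "down": ((5.0, 5.5, 4.6), (21.0, 19.0, 20.0)),
            "flat": ((10.0, 11.0, 9.0), (10.2, 10.8, 9.4)),
            "na_ref": ((10.0, 11.0, 9.0), (np.nan, np.nan, np.nan)),
        }
        table, design, contrast = two_group_dataset(data)
        deg = call_degs(table, design, contrast)
        assert deg.loc["up", "call"] == "up"
        assert deg.loc["down", "call"] == "down"
        assert deg.loc["flat", "call"] == "not_de"
        assert deg.loc["na_ref", "call"] == "untestable"
        assert np.isnan(deg.loc["na_ref", "q_value"])
        # untestable genes are excluded from the BH family
        testable = deg.dropna(subset=["p_value"])
        np.testing.assert_allclose(
            testable["q_value"], bh_fdr(testable["p_value"]), atol=1e-12
        )

    def test_null_contrast_duplicated_columns_gives_zero_calls(self):
        rng = np.random.default_rng(8)
        reps = rng.uniform(1, 50, size=(30, 3))
        data = {f"g{i}": (reps[i], reps[i].copy()) for i in range(30)}
        table, design, contrast = two_group_dataset(data)
        deg = call_degs(table, design, contrast)
        assert (deg["call"] == "not_de").all()
        np.testing.assert_allclose(deg["fold_change"], 1.0)

    def test_default_p_equals_anova_gene(self):
        rng = np.random.default_rng(11)
        data = {
            f"g{i}": (rng.uniform(1, 40, 3), rng.uniform(1, 40, 3)) for i in range(20)
        }
        table, design, contrast = two_group_dataset(data)
        deg = call_degs(table, design, contrast)
        for g, (t, r) in data.items():
            expected = anova_gene([np.log2(t + 1), np.log2(r + 1)]).p
            assert deg.loc[g, "p_value"] == pytest.approx(expected, abs=1e-12)

    def test_pooled_error_changes_df_not_means(self, strong_sim):
        rpkm, design = strong_sim["rpkm"], strong_sim["design"]
        cid = ss.make_condition_id
        contrast = Contrast("c", cid(1.0, True, 8), cid(0.0, True, 8))
        plain = call_degs(rpkm, design, contrast)
        pooled = pooled_call_degs(rpkm, design, cid(1.0, True, 8), cid(0.0, True, 8), 8)
        pd.testing.assert_series_equal(plain["fold_change"], pooled["fold_change"])
        # pooled error has more df, hence generally smaller p for real effects
        syn = strong_sim["truth"]["class_label"] == "synergistic"
        assert pooled.loc[syn.to_numpy(), "p_value"].median() < \
            plain.loc[syn.to_numpy(), "p_value"].median()

    def test_insufficient_samples_rejected(self):
        data = {"g": ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0))}
        table, design, contrast = two_group_dataset(data)
        table = table.subset_samples(["t1", "t2", "t3", "r1"])
        with pytest.raises(ValueError, match="<2 samples"):
            call_degs(table, design, contrast)

    def test_planted_truth_recovery(self):
        # 100 strong A-main-effect genes among 1000; contrast A vs vehicle
        config = ss.SimulationConfig(
            n_genes=1000, seed=2, times=(8,), dosesA=(0.0, 1.0),
            dispersion=0.01, effect_log2fc=3.0,
            frac_null=0.9, frac_A_only=0.1, frac_B_only=0,
            frac_additive=0, frac_synergistic=0,
        )
        counts, design, lengths, truth = ss.simulate_experiment(config)
        rpkm = ss.compute_rpkm(counts, lengths, "derive")
        cid = ss.make_condition_id
        deg = call_degs(
            rpkm, design, Contrast("A_vs_ctrl", cid(1.0, False, 8), cid(0.0, False, 8))
        )
        planted = truth["class_label"] == "A_only"
        called = deg["call"].isin(["up", "down"])
        correct_sign = np.sign(deg["fold_change"]) == truth["direction"]
        assert (called & correct_sign)[planted.to_numpy()].sum() >= 90
        assert called[(~planted).to_numpy()].sum() <= 5
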