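"""Two-way factorial ANOVA, BH adjustment and contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brixomics.anova import (STATUS_DROPPED, STATUS_NO_INTERACTION, STATUS_OK,
                             bh_adjust, call_significant,
                             compute_log2_contrast, fit_two_way_anova)

from conftest import make_experiment


def textbook_anova(Y: np.ndarray):
    """Loop-based classical two-way ANOVA from group means.

    ``Y`` has shape (a, b, n).  Independent of the package's vectorized
    path; follows the sums-of-squares decomposition directly.
    """
    a, b, n = Y.shape
    grand = Y.mean()
    ss_a = sum(b * n * (Y[i].mean() - grand) ** 2 for i in range(a))
    ss_b = sum(a * n * (Y[:, j].mean() - grand) ** 2 for j in range(b))
    ss_ab = 0.0
    for i in range(a):
        for j in range(b):
            ss_ab += n * (Y[i, j].mean() - Y[i].mean() - Y[:, j].mean()
                          + grand) ** 2
    ss_e = sum((Y[i, j, r] - Y[i, j].mean()) ** 2
               for i in range(a) for j in range(b) for r in range(n))
    out = {}
    df_e = a * b * (n - 1)
    for name, ss, df in (("brix", ss_a, a - 1), ("tissue", ss_b, b - 1),
                         ("interaction", ss_ab, (a - 1) * (b - 1))):
        F = (ss / df) / (ss_e / df_e)
        out[f"F_{name}"] = F
        out[f"p_{name}"] = stats.f.sf(F, df, df_e)
    out["ss_parts"] = (ss_a, ss_b, ss_ab, ss_e)
    out["ss_total"] = ((Y - grand) ** 2).sum()
    return out


class TestFitTwoWayAnova:
    def test_matches_textbook_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        a, b, n = 4, 2, 6
        Y = rng.normal(8, 1, size=(20, a, b, n))
        exp = make_experiment(Y.reshape(20, -1),
                              brix_levels=(22.6, 23.2, 25.0, 36.7), n_reps=n)
        table = fit_two_way_anova(exp)
        for g in range(20):
            ref = textbook_anova(Y[g])
            for eff in ("brix", "tissue", "interaction"):
                assert table.iloc[g][f"F_{eff}"] == \
                    pytest.approx(ref[f"F_{eff}"], abs=1e-8)
                assert table.iloc[g][f"p_{eff}"] == \
                    pytest.approx(ref[f"p_{eff}"], abs=1e-8)

    def test_pure_tissue_shift_with_zero_noise(self):
        # tissue effect only: F_brix and F_interaction are exactly zero and
        # the tissue p-value collapses to the representable floor
        base = np.zeros((2, 2, 3)) + 8.0
        base[:, 0, :] += 2.0
        exp = make_experiment(base.reshape(1, -1))
        table = fit_two_way_anova(exp)
        row = table.iloc[0]
        assert row["status"] == STATUS_OK
        assert row["F_brix"] == pytest.approx(0.0, abs=1e-10)
        assert row["F_interaction"] == pytest.approx(0.0, abs=1e-10)
        assert 0 < row["p_tissue"] < 1e-12 or np.isinf(row["F_tissue"])

    def test_constant_gene_dropped_degenerate(self):
        exp = make_experiment(np.full((1, 12), 8.0))
        table = fit_two_way_anova(exp)
        assert table.iloc[0]["status"] == STATUS_DROPPED
        assert np.isnan(table.iloc[0]["p_brix"])

    def test_sample_order_permutation_leaves_statistics_unchanged(self):
        from brixomics.preprocess import ExpressionExperiment

        rng = np.random.default_rng(3)
        values = rng.normal(8, 1, size=(10, 12))
        exp = make_experiment(values)
        perm = rng.permutation(12)
        exp2 = ExpressionExperiment(exp.values.iloc[:, perm], exp.design)
        t1 = fit_two_way_anova(exp)
        t2 = fit_two_way_anova(exp2)
        for eff in ("brix", "tissue", "interaction"):
            np.testing.assert_allclose(t1[f"F_{eff}"], t2[f"F_{eff}"])

    def test_unbalanced_gene_matches_statsmodels_type2(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(4)
        values = rng.normal(8, 1, size=(3, 24))
        values[1, 0] = np.nan          # one missing replicate -> unbalanced
        exp = make_experiment(values, n_reps=6)
        table = fit_two_way_anova(exp)
        y = values[1][~np.isnan(values[1])]
        df = pd.DataFrame({
            "y": y,
            "b": exp.design["brix"].to_numpy()[~np.isnan(values[1])],
            "t": exp.design["tissue"].to_numpy()[~np.isnan(values[1])],
        })
        fit = smf.ols("y ~ C(b) * C(t)", data=df).fit()
        ref = anova_lm(fit, typ=2)
        assert table.iloc[1]["F_brix"] == pytest.approx(ref.loc["C(b)", "F"],
                                                        rel=1e-6)
        assert table.iloc[1]["F_tissue"] == pytest.approx(
            ref.loc["C(t)", "F"], rel=1e-6)
        assert table.iloc[1]["F_interaction"] == pytest.approx(
            ref.loc["C(b):C(t)", "F"], rel=1e-6)
        assert table.iloc[1]["status"] == STATUS_OK

    def test_fully_excluded_cell_keeps_marginal_tests(self):
        rng = np.random.default_rng(5)
        values = rng.normal(8, 1, size=(2, 24))
        values[0, :6] = np.nan         # whole (brix0, skin) cell missing
        exp = make_experiment(values, n_reps=6)
        table = fit_two_way_anova(exp)
        row = table.iloc[0]
        assert row["status"] == STATUS_NO_INTERACTION
        assert np.isnan(row["p_interaction"])
        assert np.isfinite(row["p_brix"]) and np.isfinite(row["p_tissue"])


class TestBhAdjust:
    def test_hand_worked_example(self):
        # step-up: all four adjusted to 0.04
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_step_up_formula_on_random_lists(self):
        rng = np.random.default_rng(1)
        for size in (5, 50, 1000):
            p = rng.uniform(size=size)
            adj = bh_adjust(p)
            order = np.argsort(p)
            m = size
            expected = np.empty(m)
            running = np.inf
            for rank in range(m, 0, -1):
                running = min(running, p[order[rank - 1]] * m / rank)
                expected[order[rank - 1]] = min(running, 1.0)
            np.testing.assert_allclose(adj, expected, atol=1e-12)

    def test_nan_passthrough_and_order_isotonic(self):
        p = np.array([0.2, np.nan, 0.01, 0.8])
        adj = bh_adjust(p)
        assert np.isnan(adj[1])
        finite = ~np.isnan(p)
        order = np.argsort(p[finite])
        assert (np.diff(adj[finite][order]) >= -1e-15).all()
        assert (adj[finite] >= p[finite]).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallSignificant:
    def test_null_table_yields_empty_sets(self):
        table = pd.DataFrame({"adjBrix": [1.0], "adjTissue": [1.0],
                              "adjInteraction": [1.0]}, index=["g0"])
        sig = call_significant(table)
        assert all(len(v) == 0 for v in sig.values())

    def test_boundary_is_strict(self):
        table = pd.DataFrame({"adjBrix": [0.05, 0.049],
                              "adjTissue": [1.0, 1.0],
                              "adjInteraction": [1.0, 1.0]},
                             index=["g0", "g1"])
        sig = call_significant(table, alpha=0.05)
        assert sig["brix"] == ["g1"]

    def test_alpha_domain_checked(self):
        table = pd.DataFrame({"adjBrix": [0.5], "adjTissue": [0.5],
                              "adjInteraction": [0.5]}, index=["g0"])
        with pytest.raises(ValueError):
            call_significant(table, alpha=1.5)


class TestLog2Contrast:
    def test_identical_cells_give_zero(self, small_experiment):
        exp, _ = small_experiment
        c = compute_log2_contrast(exp, (22.6, "skin"), (22.6, "skin"))
        np.testing.assert_allclose(c.to_numpy(), 0.0)

    def test_two_log2_units_is_a_fourfold_ratio(self):
        values = np.zeros((1, 12))
        exp = make_experiment(values)
        exp.values.loc[:, exp.condition_samples(22.6, "skin")] = 8.0
        exp.values.loc[:, exp.condition_samples(23.2, "skin")] = 6.0
        c = compute_log2_contrast(exp, (22.6, "skin"), (23.2, "skin"))
        assert c.iloc[0] == pytest.approx(2.0)
        assert 2 ** c.iloc[0] == pytest.approx(4.0)

    def test_unknown_cell_rejected(self, small_experiment):
        exp, _ = small_experiment
        with pytest.raises(KeyError):
            compute_log2_contrast(exp, (99.0, "skin"), (22.6, "skin"))
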