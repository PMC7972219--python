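"""Descriptives, t tests, ANOVA + post hoc, normality, percent change."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spineglia.group_stats import (
    anova_oneway_tukey,
    anova_twoway,
    ks_normality,
    mean_sem,
    percent_change,
    significance_stars,
    t_test_unpaired,
)


def tidy(groups: dict) -> pd.DataFrame:
    rows = [
        {"unit_id": f"{g}{i}", "group": g, "metric": "m", "value": v}
        for g, vals in groups.items()
        for i, v in enumerate(vals)
    ]
    return pd.DataFrame(rows)


class TestMeanSem:
    def test_hand_computed_example(self):
        m, s = mean_sem([1, 2, 3])
        assert m == pytest.approx(2.0)
        assert s == pytest.approx(1.0 / np.sqrt(3), abs=1e-4)  # 0.5774

    def test_constant_values_zero_sem(self):
        assert mean_sem([4.2, 4.2, 4.2])[1] == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            mean_sem([5])


class TestTTest:
    def test_identical_groups(self):
        r = t_test_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        r = t_test_unpaired([1, 2, 3], [4, 5, 6])
        assert abs(r.statistic) == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), abs=1e-3)

    def test_degenerate_equal_groups_convention(self):
        r = t_test_unpaired([2.0, 2.0], [2.0, 2.0])
        assert (r.statistic, r.p_value) == (0.0, 1.0)

    def test_matches_pooled_formula_on_random_pairs(self, rng):
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(3, 20))
            b = rng.normal(0.5, 2, rng.integers(3, 20))
            r = t_test_unpaired(a, b)
            na, nb = len(a), len(b)
            sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p_hand = 2 * stats.t.sf(abs(t_hand), na + nb - 2)
            assert r.statistic == pytest.approx(t_hand, abs=1e-9)
            assert r.p_value == pytest.approx(p_hand, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            t_test_unpaired([1], [2, 3])


class TestOneWayAnova:
    def test_two_group_f_equals_t_squared(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, 8)
            b = rng.normal(1, 1, 11)
            t = t_test_unpaired(a, b).statistic
            f, _ = stats.f_oneway(a, b)
            assert f == pytest.approx(t**2, abs=1e-9)

    def test_identical_groups_f_zero(self):
        table = tidy({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        r = anova_oneway_tukey(table, "m")
        assert r.p_value > 0.9

    def test_shifted_group_flagged_by_tukey(self, rng):
        table = tidy({
            "a": rng.normal(0, 0.1, 10),
            "b": rng.normal(0, 0.1, 10),
            "c": rng.normal(5, 0.1, 10),
        })
        r = anova_oneway_tukey(table, "m")
        assert r.p_value < 1e-6
        for pair in r.post_hoc:
            involved_c = "c" in pair["pair"]
            assert pair["significant"] == involved_c

    def test_matches_statsmodels_reference(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.api import stats as sm_stats

        table = tidy({g: rng.normal(i, 1, 9) for i, g in enumerate("abcd")})
        r = anova_oneway_tukey(table, "m")
        model = smf.ols("value ~ C(group)", data=table).fit()
        tab = sm_stats.anova_lm(model, typ=1)
        assert r.statistic == pytest.approx(float(tab.loc["C(group)", "F"]), abs=1e-6)
        assert r.p_value == pytest.approx(float(tab.loc["C(group)", "PR(>F)"]), abs=1e-9)

    def test_tukey_matches_scipy_cross_check(self, rng):
        groups = {g: rng.normal(i * 0.5, 1, 10) for i, g in enumerate("abc")}
        r = anova_oneway_tukey(tidy(groups), "m")
        ref = stats.tukey_hsd(*groups.values())
        names = list(groups)
        for pair in r.post_hoc:
            i, j = names.index(pair["pair"][0]), names.index(pair["pair"][1])
            assert pair["p_adj"] == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_tukey_adjusted_p_not_below_raw_p(self, rng):
        groups = {g: rng.normal(i * 0.3, 1, 8) for i, g in enumerate("abcd")}
        r = anova_oneway_tukey(tidy(groups), "m")
        for pair in r.post_hoc:
            raw = t_test_unpaired(groups[pair["pair"][0]], groups[pair["pair"][1]]).p_value
            assert pair["p_adj"] >= raw - 1e-12

    def test_two_groups_redirected_to_t_test(self):
        with pytest.raises(ValueError, match="t"):
            anova_oneway_tukey(tidy({"a": [1, 2], "b": [3, 4]}), "m")


def factorial(values_by_cell: dict) -> pd.DataFrame:
    rows = []
    for (g, t), vals in values_by_cell.items():
        for i, v in enumerate(vals):
            rows.append({"unit_id": f"{g}{t}{i}", "genotype": g, "treatment": t,
                         "metric": "m", "value": v})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_all_identical_cells(self):
        cells = {(g, t): [3.0, 3.0, 3.0] for g in "AB" for t in "XY"}
        r = anova_twoway(factorial(cells), "m")
        assert all(term["F"] == 0.0 for term in r.terms.values())

    def test_additive_effects_zero_interaction_ss(self, rng):
        noise = rng.normal(0, 1, 5)  # identical within-cell residuals per cell
        cells = {
            (g, t): 10.0 + {"A": 0, "B": 2}[g] + {"X": 0, "Y": 5}[t] + noise
            for g in "AB" for t in "XY"
        }
        r = anova_twoway(factorial(cells), "m")
        assert r.terms["genotype:treatment"]["ss"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_hand_balanced_decomposition(self, rng):
        cells = {(g, t): rng.normal(i, 1, 6)
                 for i, (g, t) in enumerate(itertools.product("AB", "XY"))}
        r = anova_twoway(factorial(cells), "m")
        # hand type-II == classic decomposition on a balanced design
        y = np.array([v for vals in cells.values() for v in vals])
        n = 6
        grand = y.mean()
        ga = {g: np.concatenate([cells[(g, t)] for t in "XY"]).mean() for g in "AB"}
        gb = {t: np.concatenate([cells[(g, t)] for g in "AB"]).mean() for t in "XY"}
        ss_a = 2 * n * sum((ga[g] - grand) ** 2 for g in "AB")
        ss_b = 2 * n * sum((gb[t] - grand) ** 2 for t in "XY")
        ss_ab = n * sum(
            (cells[(g, t)].mean() - ga[g] - gb[t] + grand) ** 2
            for g in "AB" for t in "XY"
        )
        ss_e = sum(((cells[c] - cells[c].mean()) ** 2).sum() for c in cells)
        df_e = 4 * (n - 1)
        assert r.terms["genotype"]["F"] == pytest.approx(ss_a / 1 / (ss_e / df_e), rel=1e-6)
        assert r.terms["treatment"]["F"] == pytest.approx(ss_b / 1 / (ss_e / df_e), rel=1e-6)
        assert r.statistic == pytest.approx(ss_ab / 1 / (ss_e / df_e), rel=1e-6)

    def test_holm_sidak_option(self, rng):
        cells = {(g, t): rng.normal(i, 1, 6)
                 for i, (g, t) in enumerate(itertools.product("AB", "XY"))}
        r = anova_twoway(factorial(cells), "m", post_hoc="holm-sidak")
        assert len(r.post_hoc) == 6
        for pair in r.post_hoc:
            assert 0 <= pair["p_adj"] <= 1

    def test_empty_cell_rejected(self):
        cells = {(g, t): [1.0, 2.0] for g in "AB" for t in "XY"}
        df = factorial(cells)
        df = df[~((df.genotype == "A") & (df.treatment == "X"))]
        with pytest.raises(ValueError, match="cell"):
            anova_twoway(df, "m")


class TestKsNormality:
    def test_nominal_level_on_normal_data(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            ks_normality(rng.normal(3, 2, 100))[1] < 0.05 for _ in range(400)
        )
        assert rejections / 400 <= 0.08  # close to the nominal 5% level

    def test_power_against_exponential(self):
        rng = np.random.default_rng(8)
        rejections = sum(
            ks_normality(rng.exponential(1.0, 100))[1] < 0.05 for _ in range(200)
        )
        assert rejections / 200 > 0.9

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0] * 10)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref,comp,expected",
        [(10.0, 6.7, -33.0), (5.0, 5.0, 0.0), (1.0, 1.65, 65.0)],
    )
    def test_examples(self, ref, comp, expected):
        assert percent_change(ref, comp) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


def test_significance_stars_bands():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.0005) == "***"
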