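"""Normality/homoscedasticity checks, ANOVA and Duncan's multiple range test."""

import numpy as np
import pytest
from scipy import stats as spstats

from mwtselect.stats_tests import (
    ZeroVarianceError,
    anova_oneway,
    anova_twoway,
    duncan_mrt,
    ks_normality,
    levene,
    _duncan_q,
)

# Duncan 5% significant studentized ranges, q(1-(1-a)^(p-1); p, df), frozen
# from R's qtukey (agrees with the published Duncan tables to 3 decimals).
DUNCAN_TABLE_5PCT = {
    10: [3.1511, 3.2928, 3.3763, 3.4297, 3.4652, 3.4891, 3.5052, 3.5156, 3.5218],
    20: [2.9500, 3.0965, 3.1896, 3.2546, 3.3026, 3.3392, 3.3678, 3.3905, 3.4086],
    10_000_000: [2.7718, 2.9184, 3.0167, 3.0893, 3.1463, 3.1928, 3.2317, 3.2651, 3.2941],
}


class TestKsNormality:
    def test_gaussian_sample_not_rejected(self):
        x = np.random.default_rng(1).standard_normal(5000)
        stat, p = ks_normality(x)
        assert 0.0 <= stat <= 1.0
        assert p > 0.05

    def test_exponential_sample_rejected(self):
        x = np.random.default_rng(1).exponential(size=5000)
        _, p = ks_normality(x)
        assert p < 0.001

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])


class TestLevene:
    def test_equal_variances_usually_not_rejected(self):
        rng = np.random.default_rng(2)
        hits = sum(
            levene([rng.standard_normal(50), rng.standard_normal(50)])[1] > 0.05
            for _ in range(100)
        )
        assert hits >= 90

    def test_unequal_variances_rejected(self):
        rng = np.random.default_rng(3)
        g1 = rng.standard_normal(100)
        g2 = rng.standard_normal(100) * 5.0
        _, p = levene([g1, g2])
        assert p < 0.01

    def test_identical_groups_give_zero_statistic(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        stat, _ = levene([g, g])
        assert stat == pytest.approx(0.0)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            levene([[1.0], [1.0, 2.0]])


class TestAnovaOneway:
    def test_identical_groups_give_zero_f(self):
        res = anova_oneway({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_within_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            anova_oneway({"a": [0.0, 0.0], "b": [2.0, 2.0]})

    def test_agrees_with_scipy(self, rng):
        groups = [rng.standard_normal(20) + i * 0.2 for i in range(4)]
        res = anova_oneway(groups)
        ref = spstats.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_f_equals_squared_t_for_two_groups(self, rng):
        for _ in range(100):
            g1 = rng.standard_normal(int(rng.integers(5, 30)))
            g2 = rng.standard_normal(int(rng.integers(5, 30))) + rng.normal()
            res = anova_oneway([g1, g2])
            t = spstats.ttest_ind(g1, g2).statistic
            assert res.f_statistic == pytest.approx(t**2, rel=1e-8)

    def test_null_pvalues_are_uniform(self):
        # 45 equal groups: the p-value should be U[0,1] across seeds
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            groups = [rng.standard_normal(12) for _ in range(45)]
            pvals.append(anova_oneway(groups).p_value)
        assert spstats.kstest(pvals, "uniform").pvalue > 0.01


class TestAnovaTwoway:
    def test_additive_layout_has_no_interaction(self):
        a_eff = {"a1": 0.0, "a2": 1.5}
        b_eff = {"b1": 0.0, "b2": -2.0, "b3": 4.0}
        values, fa, fb = [], [], []
        for a, av in a_eff.items():
            for b, bv in b_eff.items():
                for _ in range(3):
                    values.append(av + bv)
                    fa.append(a)
                    fb.append(b)
        res = anova_twoway(values, fa, fb)
        # noiseless layout: interaction sum of squares vanishes (F is a 0/0
        # ratio of rounding residue, so compare the SS itself)
        ss_ab = res["A:B"].f_statistic * res["A:B"].df_num * res["A:B"].mse
        ss_total = float(np.sum((np.array(values) - np.mean(values)) ** 2))
        assert ss_ab < 1e-10 * ss_total
        assert res["A"].f_statistic > 1e6  # no noise: effects are exact

    def test_constant_factor_requires_noise_and_shows_zero_effect(self, rng):
        values = rng.standard_normal(24)
        fa = ["a1"] * 24
        fb = (["b1", "b2"] * 12)[:24]
        # factor A has one level; drop it to B-only comparison via two-way
        with pytest.raises(Exception):
            anova_twoway(values, fa, fb)  # singular design for A

    def test_sum_of_squares_decomposition(self, rng):
        # balanced 3 x 4 with 5 replicates: SS_A + SS_B + SS_AB + SS_within
        # equals total SS
        levels_a, levels_b, reps = 3, 4, 5
        values, fa, fb = [], [], []
        for i in range(levels_a):
            for j in range(levels_b):
                for _ in range(reps):
                    values.append(rng.standard_normal() + 0.5 * i - 0.3 * j)
                    fa.append(f"a{i}")
                    fb.append(f"b{j}")
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        import pandas as pd

        df = pd.DataFrame({"y": values, "A": fa, "B": fb})
        table = sm.stats.anova_lm(smf.ols("y ~ C(A) * C(B)", df).fit(), typ=2)
        total = np.sum((df["y"] - df["y"].mean()) ** 2)
        assert table["sum_sq"].sum() == pytest.approx(total, rel=1e-8)
        res = anova_twoway(values, fa, fb)
        assert set(res) == {"A", "B", "A:B"}
        assert res["A"].p_value <= 1.0


class TestDuncan:
    @pytest.mark.parametrize("df", sorted(DUNCAN_TABLE_5PCT))
    def test_quantiles_match_published_tables(self, df):
        for p, expected in zip(range(2, 11), DUNCAN_TABLE_5PCT[df]):
            assert _duncan_q(0.05, p, df) == pytest.approx(expected, abs=2e-3)

    def test_four_group_fixture_matches_table_oracle(self):
        # classic 4-treatment layout, n = 5 each, MSE = 11.79, df = 16.
        # Oracle computed by hand from the frozen table quantiles at df 16
        # (2.998, 3.1438, 3.2349): sqrt(11.79/5) = 1.5356 gives
        # R2 = 4.604, R3 = 4.828, R4 = 4.968; means D 21.6, C 17.6,
        # B 15.4, A 9.8 yield subsets {D,C}, {C,B}, {A}.
        groups = {
            "A": [9.8] * 5, "B": [15.4] * 5, "C": [17.6] * 5, "D": [21.6] * 5,
        }
        res = duncan_mrt(groups, alpha=0.05, mse=11.79, df_within=16)
        assert list(res.means) == ["D", "C", "B", "A"]
        assert res.subsets == [("D", "C"), ("C", "B"), ("A",)]
        assert res.letters == {"D": "a", "C": "ab", "B": "b", "A": "c"}
        assert res.critical_ranges[2] == pytest.approx(4.604, abs=5e-3)
        assert res.critical_ranges[4] == pytest.approx(4.968, abs=5e-3)

    def test_critical_ranges_nondecreasing_in_span(self, rng):
        groups = {f"g{i}": rng.standard_normal(8) for i in range(6)}
        res = duncan_mrt(groups, alpha=0.05)
        rp = [res.critical_ranges[p] for p in range(2, 7)]
        assert all(a <= b + 1e-12 for a, b in zip(rp, rp[1:]))

    def test_equal_means_share_one_letter(self):
        groups = {"a": [1.0, 1.1, 0.9], "b": [1.0, 0.9, 1.1], "c": [1.1, 1.0, 0.9]}
        res = duncan_mrt(groups, alpha=0.05)
        assert len(res.subsets) == 1
        assert set(res.letters.values()) == {"a"}

    def test_widely_separated_groups_get_distinct_letters(self, rng):
        g1 = rng.standard_normal(10)
        g2 = rng.standard_normal(10) + 100.0
        res = duncan_mrt({"low": g1, "high": g2}, alpha=0.05)
        assert not (set(res.letters["low"]) & set(res.letters["high"]))

    def test_letters_consistent_with_mean_ordering(self, rng):
        # groups sharing a letter must be contiguous in the mean ordering
        groups = {f"g{i}": rng.standard_normal(6) + 0.4 * i for i in range(7)}
        res = duncan_mrt(groups, alpha=0.05)
        names = list(res.means)
        for members in res.subsets:
            idx = sorted(names.index(m) for m in members)
            assert idx == list(range(idx[0], idx[-1] + 1))

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            duncan_mrt({"a": [1.0, 2.0], "b": [2.0, 3.0]}, mse=1.0, df_within=0)
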