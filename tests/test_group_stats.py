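"""Comparison battery: t tests, homogeneity rule, two-way ANOVA, protected LSD."""

import math

import numpy as np
import pytest

from enzystoich import (
    StatsError,
    auto_transform,
    homogeneity_check,
    independent_t,
    lsd_posthoc,
    two_way_anova,
)


class TestIndependentT:
    def test_identical_groups(self):
        res = independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_is_significant(self):
        res = independent_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.p_value < 0.01

    def test_degenerate_equal_constant_groups(self):
        res = independent_t([5.0, 5.0], [5.0, 5.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_degenerate_unequal_constant_groups_flagged(self):
        res = independent_t([5.0, 5.0], [7.0, 7.0])
        assert math.isinf(res.statistic)
        assert "zero-variance" in res.flags

    def test_welch_vs_pooled_df(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [1.0, 5.0, 9.0, 13.0, 17.0]
        welch = independent_t(a, b, welch=True)
        pooled = independent_t(a, b, welch=False)
        assert pooled.df == pytest.approx(7.0)
        assert welch.df < pooled.df  # Satterthwaite shrinks df under unequal variance

    def test_permutation_oracle_agreement(self):
        """Parametric two-sided p agrees with a permutation p within 0.05
        on seeded datasets of n ≥ 15 per group."""
        rng = np.random.default_rng(7)
        n, n_perm = 15, 5000
        for _ in range(20):
            a = rng.normal(0.0, 1.0, n)
            b = rng.normal(rng.uniform(0, 1.2), 1.0, n)
            res = independent_t(a, b, welch=False)
            pooled = np.concatenate([a, b])
            idx = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
            perm = pooled[idx]
            diffs = perm[:, :n].mean(axis=1) - perm[:, n:].mean(axis=1)
            obs = abs(a.mean() - b.mean())
            p_perm = float((np.abs(diffs) >= obs - 1e-12).mean())
            assert abs(res.p_value - p_perm) < 0.05

    def test_small_group_rejected(self):
        with pytest.raises(StatsError):
            independent_t([1.0], [1.0, 2.0])


class TestHomogeneityAndTransform:
    def test_equal_variances_homogeneous(self):
        rng = np.random.default_rng(0)
        verdict, _, p = homogeneity_check([rng.normal(0, 1, 20), rng.normal(5, 1, 20)])
        assert verdict == "homogeneous"

    def test_gross_variance_ratio_detected(self):
        rng = np.random.default_rng(1)
        verdict, _, p = homogeneity_check(
            [rng.normal(0, 1, 20), rng.normal(0, 10, 20)])
        assert verdict == "heterogeneous" and p < 0.05

    def test_constant_data_homogeneous_by_convention(self):
        verdict, stat, p = homogeneity_check([[3.0, 3.0, 3.0], [3.0, 3.0, 3.0]])
        assert verdict == "homogeneous" and p == 1.0

    def test_auto_transform_applies_log_to_lognormal_heteroscedasticity(self):
        rng = np.random.default_rng(11)
        # same log-scale SD, very different medians → raw variances differ
        a = np.exp(rng.normal(0.0, 0.6, 40))
        b = np.exp(rng.normal(3.0, 0.6, 40))
        groups, transform, flags = auto_transform([a, b])
        assert transform == "log"
        assert np.allclose(groups[0], np.log(a))

    def test_auto_transform_keeps_homogeneous_data(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        groups, transform, flags = auto_transform([a, b])
        assert transform == "none" and flags == []
        assert np.allclose(groups[0], a)

    def test_auto_transform_blocks_on_nonpositive(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 20)          # contains negatives
        b = rng.normal(0, 12, 20)
        _, transform, flags = auto_transform([a, b])
        assert transform == "none"
        assert "heterogeneous-nonpositive-not-transformed" in flags


def balanced_design(n=4, effect_a=0.0, effect_b=0.0, interaction=0.0, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for ai, a in enumerate(["spring", "autumn"]):
        for bi, b in enumerate(["HY", "TS", "XY"]):
            mu = effect_a * ai + effect_b * bi + interaction * ai * bi
            for v in rng.normal(mu, sd, n):
                rows.append((v, a, b))
    vals, fa, fb = zip(*rows)
    return np.array(vals), np.array(fa), np.array(fb)


class TestTwoWayAnova:
    def test_constant_response(self):
        vals, fa, fb = balanced_design(sd=0.0)
        vals[:] = 7.0
        table = two_way_anova(vals, fa, fb)
        assert table.f[:3] == pytest.approx([0.0, 0.0, 0.0])
        assert table.p[:3] == pytest.approx([1.0, 1.0, 1.0])

    def test_pure_main_effect_partition(self):
        # factor A adds 10, factor B adds nothing, no noise:
        # hand partition: SS_A = n_cell·n_B·Σ(mean_a − grand)² = 4·3·(5²+5²) = 600
        vals, fa, fb = balanced_design(n=4, effect_a=10.0, sd=0.0)
        table = two_way_anova(vals, fa, fb)
        row = {s: ss for s, ss in zip(table.source, table.ss)}
        assert row["season"] == pytest.approx(600.0)
        assert row["management"] == pytest.approx(0.0, abs=1e-9)
        assert table.p[0] < 0.05

    def test_partition_conservation_on_balanced_noise(self):
        vals, fa, fb = balanced_design(n=6, effect_a=1.0, effect_b=0.5,
                                       interaction=0.3, seed=5)
        table = two_way_anova(vals, fa, fb)
        assert table.balanced
        assert sum(table.ss) == pytest.approx(table.ss_total, rel=1e-9)

    def test_unbalanced_falls_back_to_type_ii(self):
        vals, fa, fb = balanced_design(n=4, effect_a=2.0, seed=6)
        vals, fa, fb = vals[:-1], fa[:-1], fb[:-1]  # drop one observation
        table = two_way_anova(vals, fa, fb)
        assert not table.balanced
        assert table.p[0] < 0.05

    def test_balanced_matches_statsmodels_type_ii(self):
        # on a balanced design the classical partition equals Type II
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        import pandas as pd
        vals, fa, fb = balanced_design(n=5, effect_a=1.0, effect_b=0.7,
                                       interaction=0.4, seed=9)
        ours = two_way_anova(vals, fa, fb)
        fit = smf.ols("y ~ C(A) * C(B)",
                      data=pd.DataFrame({"y": vals, "A": fa, "B": fb})).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        assert ours.ss[0] == pytest.approx(float(ref.loc["C(A)", "sum_sq"]), rel=1e-9)
        assert ours.ss[1] == pytest.approx(float(ref.loc["C(B)", "sum_sq"]), rel=1e-9)
        assert ours.ss[2] == pytest.approx(float(ref.loc["C(A):C(B)", "sum_sq"]), rel=1e-9)
        assert ours.p[0] == pytest.approx(float(ref.loc["C(A)", "PR(>F)"]), rel=1e-9)

    def test_empty_cell_named_in_error(self):
        vals, fa, fb = balanced_design(n=2)
        keep = ~((fa == "spring") & (fb == "XY"))
        with pytest.raises(StatsError, match="spring.*XY"):
            two_way_anova(vals[keep], fa[keep], fb[keep])


class TestLSD:
    def test_identical_groups_share_a_letter(self):
        vals = np.array([1.0, 1.1, 0.9] * 3)
        labels = np.repeat(["g1", "g2", "g3"], 3)
        _, letters, _ = lsd_posthoc(vals, labels)
        assert set(letters.values()) == {"a"}

    def test_outlying_group_gets_distinct_letter(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                               rng.normal(10, 1, 10)])
        labels = np.repeat(["g1", "g2", "g3"], 10)
        pmat, letters, omnibus_p = lsd_posthoc(vals, labels)
        assert omnibus_p < 0.05
        assert letters["g3"] == "a"  # highest mean gets first letter
        assert set(letters["g3"]) != set(letters["g1"])
        assert set(letters["g1"]) & set(letters["g2"])  # g1, g2 share

    def test_two_groups_match_pooled_t(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 12), rng.normal(1.5, 1, 12)
        pmat, letters, _ = lsd_posthoc(np.concatenate([a, b]),
                                       np.repeat(["a", "b"], 12))
        t_res = independent_t(a, b, welch=False)
        assert pmat.loc["a", "b"] == pytest.approx(t_res.p_value, rel=1e-9)
        distinct = (letters["a"] != letters["b"])
        assert distinct == (t_res.p_value < 0.05)

    def test_single_group_rejected(self):
        with pytest.raises(StatsError):
            lsd_posthoc([1.0, 2.0], ["g", "g"])


class TestTypeICalibration:
    """Under null lognormal populations the rejection rate at α=0.05 stays
    within 0.05 ± 0.02 over 2,000 seeded simulations."""

    def test_t_test_calibration(self):
        rng = np.random.default_rng(123)
        n_sim, n = 2000, 12
        draws = np.exp(rng.normal(0.0, 0.15, (n_sim, 2 * n)))
        a, b = draws[:, :n], draws[:, n:]
        from scipy import stats as ss
        p = ss.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        rate = float((p < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_anova_calibration(self):
        rng = np.random.default_rng(321)
        n_sim, n_cell = 2000, 4
        rejections = np.zeros(3)
        fa = np.repeat(["s", "a"], 3 * n_cell)
        fb = np.tile(np.repeat(["HY", "TS", "XY"], n_cell), 2)
        for _ in range(n_sim):
            vals = np.exp(rng.normal(0.0, 0.15, 6 * n_cell))
            table = two_way_anova(vals, fa, fb)
            rejections += np.array(table.p[:3]) < 0.05
        rates = rejections / n_sim
        assert np.all(rates >= 0.03) and np.all(rates <= 0.07)
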