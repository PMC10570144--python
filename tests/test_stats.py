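"""Shared statistics against hand computations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from apicodyn.stats import anova_bonferroni, bonferroni, pearson, t_test


def brute_pooled_t(x, y):
    """Textbook pooled-variance t from first principles."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * sps.t.sf(abs(t), nx + ny - 2)
    return t, p


class TestTTest:
    def test_hand_computed_example(self):
        # pooled sd = 1, SE = sqrt(2/3): t = -3/sqrt(2/3)
        res = t_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3 / np.sqrt(2 / 3), abs=1e-12)
        assert res.df == 4
        assert res.p == pytest.approx(0.0214, abs=5e-4)

    def test_paired_zero_differences(self):
        res = t_test([1, 2, 3], [1, 2, 3], paired=True)
        assert res.statistic == 0 and res.p == 1 and res.degenerate

    def test_identical_groups_p_one(self):
        res = t_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        res = t_test([1.1, 1.0, 1.2], [0.7, 0.6, 0.8], paired=True)
        assert res.degenerate and res.p == 0.0 and np.isinf(res.statistic)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(0, 1, 12), r.normal(0.5, 2, 9)
        res = t_test(x, y)
        t, p = brute_pooled_t(x, y)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_welch_matches_scipy(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(1, 3, 8)
        res = t_test(x, y, welch=True)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_paired_matches_scipy(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0.3, 1, 10)
        res = t_test(x, y, paired=True)
        ref = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            t_test([1.0], [2.0, 3.0])


class TestBonferroni:
    def test_multiplication_rule(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)

    def test_capped_at_one(self):
        assert bonferroni(0.5, 5) == 1.0

    def test_monotone(self):
        ps = np.linspace(0, 1, 11)
        adj = [bonferroni(p, 4) for p in ps]
        assert all(a2 >= a1 for a1, a2 in zip(adj, adj[1:]))
        assert all(a >= p for p, a in zip(ps, adj))


def brute_oneway_F(groups):
    """One-way ANOVA F from sum-of-squares decomposition."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    return F, sps.f.sf(F, dfb, dfw)


class TestAnova:
    def _frame(self, groups):
        return pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat([f"g{i}" for i in range(len(groups))],
                           [len(g) for g in groups])})

    def test_oneway_matches_brute_force(self, rng):
        groups = [rng.normal(m, 1, 8) for m in (0, 0.5, 2)]
        res = anova_bonferroni(self._frame(groups), "y", ["g"])
        F, p = brute_oneway_F(groups)
        om = res["omnibus"]["g"]
        assert om.statistic == pytest.approx(F, abs=1e-10)
        assert om.p == pytest.approx(p, abs=1e-10)

    def test_oneway_matches_scipy(self, rng):
        groups = [rng.normal(m, 1, 6) for m in (0, 1, 2, 3)]
        res = anova_bonferroni(self._frame(groups), "y", ["g"])
        ref = sps.f_oneway(*groups)
        assert res["omnibus"]["g"].statistic == pytest.approx(ref.statistic,
                                                              abs=1e-10)

    def test_posthoc_bonferroni_adjustment(self, rng):
        groups = [rng.normal(m, 1, 10) for m in (0, 0, 5)]
        res = anova_bonferroni(self._frame(groups), "y", ["g"])
        ph = res["posthoc"]["g"]
        assert len(ph) == 3
        for r in ph:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p * 3))

    def test_twoway_balanced_matches_brute_force(self, rng):
        # balanced 2x2, n=6 per cell: classic SS decomposition oracle
        n = 6
        ya = np.repeat([0, 0, 1, 1], n)
        yb = np.tile(np.repeat([0, 1], n), 2)
        y = 0.5 * ya + 1.5 * yb + 0.8 * ya * yb + rng.normal(0, 1, 4 * n)
        df = pd.DataFrame({"y": y, "A": ya.astype(str), "B": yb.astype(str)})
        res = anova_bonferroni(df, "y", ["A", "B"])
        grand = y.mean()
        ss_a = sum(2 * n * (y[ya == v].mean() - grand) ** 2 for v in (0, 1))
        ss_b = sum(2 * n * (y[yb == v].mean() - grand) ** 2 for v in (0, 1))
        cell_means = {(a, b): y[(ya == a) & (yb == b)].mean()
                      for a in (0, 1) for b in (0, 1)}
        ss_cells = sum(n * (m - grand) ** 2 for m in cell_means.values())
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = sum(((y[(ya == a) & (yb == b)] - cell_means[a, b]) ** 2).sum()
                     for a in (0, 1) for b in (0, 1))
        ms_err = ss_err / (4 * n - 4)
        assert res["omnibus"]["A"].statistic == pytest.approx(ss_a / ms_err,
                                                              rel=1e-8)
        assert res["omnibus"]["B"].statistic == pytest.approx(ss_b / ms_err,
                                                              rel=1e-8)
        assert res["omnibus"]["A:B"].statistic == pytest.approx(
            ss_ab / ms_err, rel=1e-8)

    def test_unbalanced_degrades_to_main_effects(self, rng):
        df = pd.DataFrame({
            "y": rng.normal(0, 1, 11),
            "A": ["a"] * 5 + ["b"] * 6,
            "B": ["x", "y"] * 5 + ["x"]})
        res = anova_bonferroni(df, "y", ["A", "B"])
        assert "A:B" not in res["omnibus"]
        assert {"A", "B"} <= set(res["omnibus"])

    def test_power_separated_means(self):
        hits = 0
        for s in range(100):
            r = np.random.default_rng(s)
            groups = [r.normal(m, 1, 20) for m in (0, 0, 5)]
            res = anova_bonferroni(self._frame(groups), "y", ["g"])
            hits += res["omnibus"]["g"].p < 0.001
        assert hits >= 95

    def test_type_I_error_rate(self):
        rej = 0
        n_runs = 1000
        for s in range(n_runs):
            r = np.random.default_rng(10_000 + s)
            groups = [r.normal(0, 1, 10) for _ in range(3)]
            res = anova_bonferroni(self._frame(groups), "y", ["g"])
            rej += res["omnibus"]["g"].p < 0.05
        assert 0.03 <= rej / n_runs <= 0.07


class TestPearson:
    def test_perfect_negative(self):
        x = np.arange(10.0)
        res = pearson(x, -x)
        assert res.r == pytest.approx(-1.0, abs=1e-12)
        assert res.slope == pytest.approx(-1.0, abs=1e-12)

    def test_exact_line_recovery(self, rng):
        x = rng.normal(0, 2, 20)
        res = pearson(x, 3.5 * x - 1.25)
        assert res.slope == pytest.approx(3.5, abs=1e-9)
        assert res.intercept == pytest.approx(-1.25, abs=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_covariance_formula(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        res = pearson(x, y)
        r = (((x - x.mean()) * (y - y.mean())).sum()
             / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        t = r * np.sqrt(28 / (1 - r * r))
        p = 2 * sps.t.sf(abs(t), 28)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_null_rejection_rate(self):
        rej = 0
        n_runs = 2000
        for s in range(n_runs):
            r = np.random.default_rng(50_000 + s)
            res = pearson(r.normal(0, 1, 10), r.normal(0, 1, 10))
            rej += res.p < 0.05
        assert 0.03 <= rej / n_runs <= 0.07

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])
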