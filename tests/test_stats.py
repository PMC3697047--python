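"""The 11 statistical criteria: correlation tests and regression
applicability diagnostics."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import comb

from tetractivity.stats import (
    CRITERIA,
    all_criteria,
    applicability_criteria,
    dichotomous_tests,
    kendall,
    median_split_table,
    pearson,
    regression_diagnostics,
    runs_test,
    spearman,
)


class TestCorrelationTests:
    def test_printed_table_correlations(self, table1, table2):
        assert round(pearson(table1.annotations["wrhw_f1"], table1.activity).statistic, 2) == 0.67
        assert round(pearson(table1.annotations["dryd_f2"], table1.activity).statistic, 2) == 0.58
        assert round(
            pearson(table2.annotations["rhhk_f3"], table2.annotations["delta"]).statistic, 2
        ) == 0.75
        assert round(
            pearson(table2.annotations["yrhb_f4"], table2.annotations["sigma"]).statistic, 2
        ) == 0.86

    def test_exact_linear(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)
        assert res.direction == "favourable"

    def test_monotone_rank_correlations(self):
        x = np.arange(12.0)
        y = np.exp(x)  # strictly monotone, nonlinear
        assert spearman(x, y).statistic == pytest.approx(1.0)
        assert kendall(x, y).statistic == pytest.approx(1.0)
        assert spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_constant_input_convention(self):
        x = np.ones(8)
        y = np.arange(8.0)
        for fn in (pearson, spearman, kendall):
            res = fn(x, y)
            assert res.statistic == 0.0 and res.alpha == 1.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])

    def test_definitional_agreement(self, rng):
        """Pearson/Spearman against definitional formulas on random data."""
        for _ in range(100):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            r_def = np.corrcoef(x, y)[0, 1]
            assert pearson(x, y).statistic == pytest.approx(r_def, abs=1e-10)
            rho_def = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
            assert spearman(x, y).statistic == pytest.approx(rho_def, abs=1e-10)

    def test_null_alphas_near_uniform(self, rng):
        """Fractions of alpha < 0.05 under permuted labels stay near (or
        below) the nominal rate for every favourable test."""
        n, reps = 20, 2000
        x = rng.normal(size=n)
        hits = {cid: 0 for cid in ("pearson", "spearman", "kendall", "chi2", "fisher")}
        for _ in range(reps):
            y = rng.permutation(x)
            hits["pearson"] += pearson(x, y).alpha < 0.05
            hits["spearman"] += spearman(x, y).alpha < 0.05
            hits["kendall"] += kendall(x, y).alpha < 0.05
            chi2_r, fisher_r = dichotomous_tests(x, y)
            hits["chi2"] += chi2_r.alpha < 0.05
            hits["fisher"] += fisher_r.alpha < 0.05
        for cid, h in hits.items():
            assert h / reps <= 0.07, f"{cid}: {h / reps:.3f}"


class TestDichotomous:
    def test_median_split_ties_go_low(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        t = median_split_table(x, x)
        # median is 2; values equal to it are "low": 3 low, 1 high
        assert t.sum() == 4 and t[0, 0] == 3 and t[1, 1] == 1

    def test_fisher_perfect_split(self):
        x = np.arange(10.0)
        res_chi2, res_fisher = dichotomous_tests(x, x)
        # the 2x2 table is [[5,0],[0,5]]; two-sided exact p = 2/252
        assert res_fisher.alpha == pytest.approx(2 / comb(10, 5), rel=1e-9)
        assert res_chi2.alpha < 0.01

    def test_fisher_matches_hypergeometric_enumeration(self, rng):
        """Two-sided Fisher p equals summing all hypergeometric tables at
        most as probable as the observed one (fixed margins)."""
        for _ in range(30):
            x = rng.normal(size=int(rng.integers(8, 21)))
            y = rng.normal(size=x.size)
            table = median_split_table(x, y)
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            _, fisher_res = dichotomous_tests(x, y)
            r1, r2 = table.sum(axis=1)
            c1 = table[:, 0].sum()
            n = table.sum()
            probs = [
                sps.hypergeom.pmf(a, n, r1, c1)
                for a in range(max(0, c1 - r2), min(r1, c1) + 1)
            ]
            p_obs = sps.hypergeom.pmf(table[0, 0], n, r1, c1)
            p_exact = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
            assert fisher_res.alpha == pytest.approx(p_exact, rel=1e-6)

    def test_balanced_independent_table(self):
        # alternate low/high so the table is [[3,3],[3,3]]
        x = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1], dtype=float)
        res_chi2, res_fisher = dichotomous_tests(x, y)
        assert res_chi2.statistic == pytest.approx(0.0)
        assert res_chi2.alpha == pytest.approx(1.0)

    def test_degenerate_margin(self):
        x = np.ones(8)
        y = np.arange(8.0)
        res_chi2, res_fisher = dichotomous_tests(x, y)
        assert res_chi2.alpha == 1.0 and res_fisher.alpha == 1.0


class TestRunsTest:
    def test_alternating_signs_too_many_runs(self):
        signs = np.array([True, False] * 10)
        z, p = runs_test(signs)
        assert z > 3 and p < 0.001

    def test_closed_form_oracle(self):
        """z matches the Wald-Wolfowitz closed form computed by hand."""
        signs = np.array([1, 1, 0, 1, 0, 0, 1, 1, 1, 0], dtype=bool)
        n1, n2 = 6, 4
        runs = 6
        mean = 1 + 2 * n1 * n2 / 10
        var = 2 * n1 * n2 * (2 * n1 * n2 - 10) / (100 * 9)
        z_expected = (runs - mean) / np.sqrt(var)
        z, p = runs_test(signs)
        assert z == pytest.approx(z_expected, abs=1e-12)

    def test_statsmodels_agreement(self, rng):
        from statsmodels.sandbox.stats.runs import runstest_1samp

        for _ in range(20):
            values = rng.normal(size=30)
            z_sm, p_sm = runstest_1samp(values, cutoff=0, correction=False)
            z, p = runs_test(values >= 0)
            assert z == pytest.approx(z_sm, abs=1e-9)
            assert p == pytest.approx(p_sm, abs=1e-9)

    def test_single_symbol_uninformative(self):
        assert runs_test(np.ones(10, dtype=bool)) == (0.0, 1.0)


class TestApplicability:
    def test_uniform_grid_passes(self):
        x = np.linspace(0, 1, 20)
        f = np.linspace(2, 5, 20) + np.sin(np.arange(20)) * 0.2
        results = applicability_criteria(x, f)
        unif_x = results[0]
        assert unif_x.criterion_id == "unif_x"
        assert unif_x.alpha > 0.5
        assert all(r.direction == "unfavourable" for r in results)

    def test_perfectly_linear_passes_residual_checks(self):
        x = np.linspace(0, 1, 12)
        f = 3 * x + 1
        results = {r.criterion_id: r for r in applicability_criteria(x, f)}
        for cid in ("norm_fx", "indep_fx", "norm_xf", "indep_xf"):
            assert results[cid].alpha == 1.0

    def test_alternating_residuals_fail_independence(self):
        x = np.arange(20.0)
        f = x + np.tile([0.5, -0.5], 10)  # residuals strictly alternate
        results = {r.criterion_id: r for r in applicability_criteria(x, f)}
        assert results["indep_fx"].alpha < 0.01

    def test_regression_diagnostics_are_least_squares(self, rng):
        x = rng.normal(size=15)
        f = 2 * x + rng.normal(size=15)
        d = regression_diagnostics(x, f)
        lam, mu = np.polyfit(x, f, 1)
        assert d.slope_fx == pytest.approx(lam) and d.intercept_fx == pytest.approx(mu)
        assert d.residuals_fx.sum() == pytest.approx(0.0, abs=1e-9)


def test_all_criteria_complete_grid(rng):
    x = rng.normal(size=12)
    f = rng.normal(size=12)
    results = all_criteria(x, f)
    assert [r.criterion_id for r in results] == list(CRITERIA)
    assert len(results) == 11
    # tests whose minimum n exceeds the subset size degrade to alpha=1
    small = {r.criterion_id: r for r in all_criteria(x[:3], f[:3])}
    assert len(small) == 11
    for cid in ("chi2", "fisher", "unif_x", "unif_f", "norm_fx", "indep_fx",
                "norm_xf", "indep_xf"):
        assert small[cid].alpha == 1.0
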