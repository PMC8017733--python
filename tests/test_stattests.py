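"""First-principles statistics engine vs closed forms, enumeration oracles
and the reference implementations in scipy/statsmodels."""

import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from bsirisk.stattests import (Table2x2, chi_square, fisher_exact,
                               gram_crosstab, logistic_fit, mann_whitney,
                               mcnemar, t_test, t_test_from_stats)
from bsirisk.scores import score_cohort
from bsirisk.synth import GeneratorConfig, simulate_cohort


def fisher_oracle(a, b, c, d):
    """Full hypergeometric enumeration, point-probability two-sided rule."""
    r1, c1, n = a + b, a + c, a + b + c + d
    ks = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    def pk(k):
        return comb(c1, k) * comb(n - c1, r1 - k) / comb(n, r1)
    p_obs = pk(a)
    return sum(pk(k) for k in ks if pk(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_gram_table_is_significant(self):
        """13/4 vs 7/12 Gram-negative/positive isolates differ at p < 0.05."""
        assert fisher_exact(Table2x2(13, 4, 7, 12)) < 0.05

    def test_two_by_two_of_singletons(self):
        assert fisher_exact(Table2x2(1, 0, 0, 1)) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_for_small_margins(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(v) for v in rng.integers(0, 7, size=4))
        if a + b + c + d == 0:
            a = 1
        assert fisher_exact(Table2x2(a, b, c, d)) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-10)

    @pytest.mark.parametrize("table", [(13, 4, 7, 12), (5, 9, 14, 2), (1, 7, 6, 3)])
    def test_matches_scipy(self, table):
        ours = fisher_exact(Table2x2(*table))
        ref = sps.fisher_exact([[table[0], table[1]], [table[2], table[3]]])[1]
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_invariant_under_transpose_and_row_column_swap(self, rng):
        for _ in range(20):
            a, b, c, d = (int(v) for v in rng.integers(0, 15, size=4))
            if a + b + c + d == 0:
                continue
            p = fisher_exact(Table2x2(a, b, c, d))
            assert 0 < p <= 1
            assert fisher_exact(Table2x2(a, c, b, d)) == pytest.approx(p, abs=1e-12)
            assert fisher_exact(Table2x2(d, c, b, a)) == pytest.approx(p, abs=1e-12)

    def test_doubled_one_tail_variant(self):
        p_pp = fisher_exact(Table2x2(13, 4, 7, 12), method="point_probability")
        p_dt = fisher_exact(Table2x2(13, 4, 7, 12), method="doubled_one_tail")
        assert p_dt >= p_pp - 1e-12


class TestChiSquare:
    def test_shapiro_ge2_table_highly_significant(self):
        """72/84 vs 248/400 rule-positive split: p < 0.001."""
        _, p = chi_square(Table2x2(72, 12, 248, 152))
        assert p < 0.001

    def test_identical_row_proportions_give_zero(self):
        stat, p = chi_square(Table2x2(10, 30, 20, 60))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_statistic_matches_definitional_sum(self, rng):
        for _ in range(20):
            t = rng.integers(1, 40, size=4).astype(float)
            obs = t.reshape(2, 2)
            row, col = obs.sum(1), obs.sum(0)
            exp = np.outer(row, col) / obs.sum()
            direct = ((obs - exp) ** 2 / exp).sum()
            stat, _ = chi_square(Table2x2(*(int(v) for v in t)))
            assert stat == pytest.approx(direct, rel=1e-12)

    def test_equals_squared_two_proportion_z(self, rng):
        """Algebraic identity: chi2 = z^2 of the two-proportion test."""
        a, b, c, d = 30, 20, 25, 45
        stat, _ = chi_square(Table2x2(a, b, c, d))
        p1, p2 = a / (a + b), c / (c + d)
        pool = (a + c) / (a + b + c + d)
        z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / (a + b) + 1 / (c + d)))
        assert stat == pytest.approx(z * z, rel=1e-12)

    def test_matches_scipy_with_and_without_yates(self):
        table = [[72, 12], [248, 152]]
        for corr in (False, True):
            stat, p = chi_square(Table2x2(72, 12, 248, 152), correction=corr)
            ref = sps.chi2_contingency(table, correction=corr)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestMcNemar:
    def test_balanced_discordance_is_null(self):
        assert mcnemar(10, 10).p == pytest.approx(1.0)
        assert mcnemar(30, 30).p == pytest.approx(1.0)   # asymptotic branch

    def test_one_sided_discordance_closed_form(self):
        res = mcnemar(5, 0)
        assert res.method == "exact"
        assert res.p == pytest.approx(2 * 0.5 ** 5)

    def test_exact_matches_binomial_enumeration(self):
        """b=17, c=18 (forced exact): doubled tail of Binomial(35, 1/2)."""
        res = mcnemar(17, 18, exact_threshold=100)
        expected = 2 * sum(comb(35, k) * 0.5 ** 35 for k in range(18))
        assert res.method == "exact"
        assert res.p == pytest.approx(min(1.0, expected), abs=1e-12)

    def test_symmetry_in_discordant_counts(self, rng):
        for _ in range(20):
            b, c = (int(v) for v in rng.integers(0, 20, size=2))
            assert mcnemar(b, c).p == pytest.approx(mcnemar(c, b).p, abs=1e-12)

    def test_threshold_switches_method(self):
        assert mcnemar(12, 12, exact_threshold=25).method == "exact"
        assert mcnemar(13, 12, exact_threshold=25).method == "chi2"

    def test_asymptotic_matches_statsmodels(self):
        sm_contingency = pytest.importorskip("statsmodels.stats.contingency_tables")
        res = mcnemar(40, 25)
        ref = sm_contingency.mcnemar([[0, 40], [25, 0]], exact=False, correction=False)
        assert res.p == pytest.approx(float(ref.pvalue), rel=1e-9)


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        u, p, method = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert method == "exact"
        assert p == pytest.approx(2 / comb(6, 3))   # only the two extreme splits

    def test_identical_samples_give_p_one(self):
        _, p, _ = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_normal_approx_close_to_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 12, size=6).astype(float)
        y = rng.integers(0, 12, size=6).astype(float)
        _, p_exact, m1 = mann_whitney(x, y)
        _, p_norm, m2 = mann_whitney(x, y, exact_limit=0)
        assert (m1, m2) == ("exact", "normal")
        if p_exact < 0.9:
            assert abs(p_exact - p_norm) <= 0.03
        else:
            # near the null the continuity-corrected normal p saturates at 1
            # while the discrete exact p stays just below it
            assert p_norm >= 0.9

    def test_large_sample_matches_scipy(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 50)
        u, p, _ = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestTTest:
    def test_equal_samples(self):
        t, p = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_published_age_summaries_are_significant(self):
        """Age 69.6 (SD 17.0, n=84) vs 63.6 (SD 19.6, n=400): p < 0.05."""
        _, p = t_test_from_stats(69.6, 17.0, 84, 63.6, 19.6, 400)
        assert p < 0.05
        _, p_w = t_test_from_stats(69.6, 17.0, 84, 63.6, 19.6, 400, welch=True)
        assert p_w < 0.05

    def test_closed_form_worked_example(self):
        """Pooled t for means 10 vs 8, common SD 2, n = 16 each: t = 2.83."""
        t, p = t_test_from_stats(10.0, 2.0, 16, 8.0, 2.0, 16)
        se = 2.0 * np.sqrt(2 / 16)
        assert t == pytest.approx(2.0 / se, rel=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(t, 30), rel=1e-12)

    def test_matches_scipy_on_raw_data(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0.7, 1.5, 25)
        for welch in (False, True):
            t, p = t_test(x, y, welch=welch)
            ref = sps.ttest_ind(x, y, equal_var=not welch)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)


class TestLogistic:
    def test_single_binary_predictor_equals_log_odds_ratio(self):
        # 2x2: exposed 30/20 events, unexposed 15/35
        y = np.r_[np.ones(30), np.zeros(20), np.ones(15), np.zeros(35)]
        x = np.r_[np.ones(50), np.zeros(50)]
        fit = logistic_fit(y, x)
        assert fit.converged
        log_or = np.log((30 * 35) / (20 * 15))
        assert fit.coef[0] == pytest.approx(log_or, abs=1e-8)

    def test_loglik_nondecreasing_over_irls_iterations(self, rng):
        x = rng.normal(0, 1, 200)
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.5 + x)))).astype(float)
        fit = logistic_fit(y, x)
        diffs = np.diff(fit.loglik_path)
        assert (diffs >= -1e-8).all()

    def test_matches_statsmodels(self, rng):
        sm_api = pytest.importorskip("statsmodels.api")
        x = rng.normal(0, 1, (150, 2))
        y = (rng.random(150) < 1 / (1 + np.exp(-(0.3 + x @ [1.0, -0.5])))).astype(float)
        fit = logistic_fit(y, x)
        ref = sm_api.Logit(y, sm_api.add_constant(x)).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.coef == pytest.approx(ref.params[1:], abs=1e-6)

    def test_null_predictors_give_near_zero_coefficients(self, rng):
        x = rng.normal(0, 1, 400)
        y = rng.integers(0, 2, 400).astype(float)   # independent of x
        fit = logistic_fit(y, x)
        assert abs(fit.coef[0]) < 0.3

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        fit = logistic_fit(x.copy(), x)
        assert not fit.converged
        assert "separation" in fit.message

    def test_combined_score_not_worse_than_components(self):
        """On a calibrated cohort, MSS+NLCR AUC >= max individual - 0.01."""
        from bsirisk.roc import roc_curve

        cohort = simulate_cohort(GeneratorConfig(n_events=4000), seed=5)
        panels = score_cohort(cohort)
        rows = [(r, p) for r, p in zip(cohort, panels) if p.nlcr is not None]
        y = np.array([r.culture_positive for r, _ in rows])
        mss = np.array([p.mss_points for _, p in rows], dtype=float)
        nlcr = np.array([p.nlcr for _, p in rows], dtype=float)
        fit = logistic_fit(y.astype(float), np.column_stack([mss, np.log(nlcr)]))
        combo = fit.linear_predictor
        auc = {name: roc_curve(s[y], s[~y]).auc
               for name, s in (("mss", mss), ("nlcr", nlcr), ("combo", combo))}
        assert auc["combo"] >= max(auc["mss"], auc["nlcr"]) - 0.01


class TestGramCrosstab:
    def test_partition_conserves_evaluable_positives(self, default_cohort,
                                                     default_panels):
        res = gram_crosstab(default_cohort, default_panels)
        n_direct = sum(1 for r, p in zip(default_cohort, default_panels)
                       if r.culture_positive and p.nlcr is not None)
        assert sum(res.venn.values()) == res.n_evaluable == n_direct

    def test_identical_rule_sets_skip_gram_test(self, default_cohort,
                                                default_panels):
        # an extreme MSS cut makes the MSS-only cell empty
        res = gram_crosstab(default_cohort, default_panels, mss_cut=15)
        assert res.gram_table is None
        assert "skipped" in res.message

    def test_gram_table_counts_isolates_not_patients(self, default_cohort,
                                                     default_panels):
        res = gram_crosstab(default_cohort, default_panels)
        if res.gram_table is not None:
            n_isolates = (res.gram_table.a + res.gram_table.b
                          + res.gram_table.c + res.gram_table.d)
            assert n_isolates >= res.venn["only_nlcr"] + res.venn["only_mss"]
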