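"""Synthetic cohort generator: quantile calibration, reproducibility,
marginal fidelity and the rule-level component calibration search."""

import io

import numpy as np
import pytest
from scipy import stats

from bsirisk.cohort import write_cohort_csv
from bsirisk.roc import roc_curve
from bsirisk.scores import score_cohort
from bsirisk.synth import (GeneratorConfig, calibrate_mss_components,
                           lognormal_from_quantiles, mss_point_distribution,
                           simulate_cohort)


class TestLognormalFromQuantiles:
    @pytest.mark.parametrize("median, q1, q3, mu, sigma", [
        (16.2, 10.0, 25.1, 2.785, 0.682),   # culture-positive NLCR summary
        (8.2, 4.7, 14.6, 2.104, 0.840),     # culture-negative NLCR summary
    ])
    def test_closed_form(self, median, q1, q3, mu, sigma):
        got_mu, got_sigma = lognormal_from_quantiles(median, q1, q3)
        assert got_mu == pytest.approx(mu, abs=2e-3)
        assert got_sigma == pytest.approx(sigma, abs=2e-3)

    def test_sampling_recovers_median_and_log_iqr(self, rng):
        """1e6 draws reproduce the target median and log-scale IQR within 1%.

        The printed quartiles are mildly asymmetric on the log scale, so a
        log-normal reproduces the median and the IQR width exactly but can
        shift each individual quartile by the asymmetry (~2% here).
        """
        mu, sigma = lognormal_from_quantiles(16.2, 10.0, 25.1)
        draws = rng.lognormal(mu, sigma, size=10 ** 6)
        q1, med, q3 = np.percentile(draws, [25, 50, 75])
        assert med == pytest.approx(16.2, rel=0.01)
        assert np.log(q3) - np.log(q1) == pytest.approx(
            np.log(25.1) - np.log(10.0), rel=0.01)
        assert q1 == pytest.approx(10.0, rel=0.05)
        assert q3 == pytest.approx(25.1, rel=0.05)

    def test_degenerate_quantiles_rejected(self):
        with pytest.raises(ValueError):
            lognormal_from_quantiles(5.0, 5.0, 5.0)
        with pytest.raises(ValueError):
            lognormal_from_quantiles(3.0, 4.0, 5.0)

    def test_asymmetric_quantiles_warn(self):
        with pytest.warns(UserWarning, match="asymmetric"):
            lognormal_from_quantiles(10.0, 9.5, 30.0)

    def test_parameter_recovery_from_generated_sample(self, rng):
        """Fitting the sample median/IQR of 1e5 draws recovers (mu, sigma)
        within 2%."""
        mu, sigma = lognormal_from_quantiles(16.2, 10.0, 25.1)
        draws = rng.lognormal(mu, sigma, size=10 ** 5)
        q1, med, q3 = np.percentile(draws, [25, 50, 75])
        mu_hat, sigma_hat = lognormal_from_quantiles(med, q1, q3)
        assert mu_hat == pytest.approx(mu, rel=0.02)
        assert sigma_hat == pytest.approx(sigma, rel=0.02)


class TestSimulateCohort:
    def test_default_prevalence_near_17_percent(self):
        cohort = simulate_cohort(seed=1)
        prev = cohort.n_positive / len(cohort)
        assert prev == pytest.approx(0.17, abs=0.03)

    def test_zero_prevalence_yields_all_negative(self):
        cohort = simulate_cohort(GeneratorConfig(n_events=100, prevalence=0.0), seed=0)
        assert cohort.n_positive == 0
        assert all(not r.pathogens for r in cohort)

    def test_same_seed_gives_byte_identical_csv(self):
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            write_cohort_csv(simulate_cohort(seed=7), buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_different_seeds_differ(self):
        a = simulate_cohort(seed=1)
        b = simulate_cohort(seed=2)
        assert a.to_dataframe().equals(b.to_dataframe()) is False

    def test_records_pass_domain_validation(self, default_cohort):
        default_cohort.validate()   # raises on violation

    def test_sepsis3_flag_consistent_with_sofa_totals(self, default_cohort,
                                                      default_panels):
        for r, p in zip(default_cohort, default_panels):
            assert p.sepsis3 == (r.sofa_admission - r.sofa_baseline >= 2)

    def test_missingness_rates_within_binomial_tolerance(self):
        config = GeneratorConfig(n_events=20_000)
        cohort = simulate_cohort(config, seed=3)
        n = len(cohort)
        for field_, rate in config.missingness.items():
            if field_ == "lymphocytes":
                continue   # joint with neutrophils, checked below
            observed = sum(getattr(r, field_) is None for r in cohort) / n
            tol = 4 * np.sqrt(rate * (1 - rate) / n)
            assert observed == pytest.approx(rate, abs=max(tol, 1e-3)), field_
        lymph = sum(r.lymphocytes is None for r in cohort) / n
        assert lymph == pytest.approx(16 / 484, abs=4e-3)

    def test_nlcr_marginals_match_published_summaries(self):
        cohort = simulate_cohort(GeneratorConfig(n_events=40_000), seed=9)
        panels = score_cohort(cohort)
        pos = [p.nlcr for r, p in zip(cohort, panels)
               if r.culture_positive and p.nlcr is not None]
        neg = [p.nlcr for r, p in zip(cohort, panels)
               if not r.culture_positive and p.nlcr is not None]
        assert np.median(pos) == pytest.approx(16.2, rel=0.05)
        assert np.median(neg) == pytest.approx(8.2, rel=0.05)

    def test_gram_fraction_among_isolates(self):
        cohort = simulate_cohort(GeneratorConfig(n_events=20_000), seed=4)
        isolates = [p.gram for r in cohort for p in r.pathogens]
        frac_neg = isolates.count("negative") / len(isolates)
        assert frac_neg == pytest.approx(51 / 90, abs=0.03)

    def test_binormal_limit_auc(self, rng):
        """Empirical NLCR AUC matches Phi(dmu / sqrt(s1^2+s2^2)) at 1e5/group."""
        config = GeneratorConfig()
        mu1, s1 = config.positive.nlcr.params
        mu2, s2 = config.negative.nlcr.params
        closed = stats.norm.cdf((mu1 - mu2) / np.hypot(s1, s2))
        pos = rng.lognormal(mu1, s1, 10 ** 5)
        neg = rng.lognormal(mu2, s2, 10 ** 5)
        assert roc_curve(pos, neg).auc == pytest.approx(closed, abs=0.01)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_events=0)
        with pytest.raises(ValueError):
            GeneratorConfig(prevalence=1.5)


class TestCalibration:
    TARGETS = [(2, 0.857, 0.382), (3, 0.69, 0.64)]

    def test_targets_achieved_within_tolerance(self):
        res = calibrate_mss_components(self.TARGETS)
        assert not res.warnings
        for cut, sens, spec in self.TARGETS:
            assert res.achieved[f"sens_ge{cut}"] == pytest.approx(sens, abs=0.05)
            assert res.achieved[f"spec_ge{cut}"] == pytest.approx(spec, abs=0.05)

    def test_simulated_operating_points_match_calibration(self):
        """50,000 simulated events reproduce the calibrated rule-level
        sensitivity and specificity within 5 points."""
        cohort = simulate_cohort(GeneratorConfig(n_events=50_000), seed=13)
        panels = score_cohort(cohort)
        truth = np.array([r.culture_positive for r in cohort])
        mss = np.array([p.mss_points for p in panels])
        for cut, sens, spec in self.TARGETS:
            got_sens = (mss[truth] >= cut).mean()
            got_spec = (mss[~truth] < cut).mean()
            assert got_sens == pytest.approx(sens, abs=0.05)
            assert got_spec == pytest.approx(spec, abs=0.05)

    def test_fixed_point_returns_near_identical_rates(self):
        """Targets equal to the defaults' own implied operating points leave
        the free rates essentially unchanged."""
        config = GeneratorConfig()
        dist_pos = mss_point_distribution(config.positive.component_rates())
        dist_neg = mss_point_distribution(config.negative.component_rates())
        implied = [(c, float(dist_pos[c:].sum()), float(1 - dist_neg[c:].sum()))
                   for c in (2, 3)]
        res = calibrate_mss_components(implied, config=config)
        for key, rates in (("chills", res.rates_positive),
                           ("chills", res.rates_negative)):
            assert 0 < rates[key] < 1
        assert res.rates_positive["chills"] == pytest.approx(
            config.positive.chills_rate, abs=0.02)
        assert res.rates_negative["chills"] == pytest.approx(
            config.negative.chills_rate, abs=0.02)

    def test_boundary_targets_warn_infeasible(self):
        with pytest.warns(UserWarning):
            res = calibrate_mss_components([(3, 1.0, 1.0)])
        assert res.warnings   # achieved values cannot reach the boundary

    def test_applying_calibration_returns_updated_config(self):
        res = calibrate_mss_components(self.TARGETS)
        new = res.apply(GeneratorConfig())
        assert new.positive.chills_rate == pytest.approx(
            res.rates_positive["chills"])


def test_mss_point_distribution_is_a_distribution():
    rates = GeneratorConfig().positive.component_rates()
    dist = mss_point_distribution(rates)
    assert dist.sum() == pytest.approx(1.0, abs=1e-12)
    assert (dist >= 0).all()
    # matches Monte-Carlo of independent components
    rng = np.random.default_rng(0)
    n = 200_000
    pts = np.zeros(n, dtype=int)
    pts += 2 * (rng.random(n) < rates["suspected_endocarditis"])
    pts += 3 * (rng.random(n) < rates["indwelling_vascular_catheter"])
    u = rng.random(n)
    pts += 3 * (u < rates["temperature_major"])
    pts += 1 * ((u >= rates["temperature_major"])
                & (u < rates["temperature_major"] + rates["temperature_minor"]))
    for name in ("age_over_65", "chills", "hypotension", "wbc_high",
                 "platelets_low", "creatinine_high"):
        pts += rng.random(n) < rates[name]
    for cut in (2, 3, 4):
        assert (pts >= cut).mean() == pytest.approx(dist[cut:].sum(), abs=0.006)
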