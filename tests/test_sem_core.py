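"""Latent-genotype SEM: implied moments, FIML likelihood, fitting, tests."""

import math

import numpy as np
import pytest
from scipy import stats

from matfet import simgen
from matfet.sem_core import (
    PatternedDataset,
    SEMParameters,
    closed_form_mf,
    fiml_loglik,
    fit_sem,
    implied_moments,
    lrt_2df,
)
from matfet.simgen import Pattern, SimConfig


def params(**kw):
    base = dict(m=0.1, f=0.2, phi=0.5, sigma2=1.0, sigma2_o=1.0, rho=0.2)
    base.update(kw)
    return SEMParameters(**base)


class TestImpliedMoments:
    def test_no_genetic_paths(self):
        _, sigma = implied_moments(params(m=0.0, f=0.0))
        assert sigma[0, 1] == 0.0 and sigma[0, 2] == 0.0
        assert sigma[1, 2] == pytest.approx(0.2)

    def test_path_tracing_example(self):
        _, sigma = implied_moments(params())
        assert sigma[0, 1] == pytest.approx(0.125)
        assert sigma[0, 2] == pytest.approx(0.100)
        assert sigma[1, 2] == pytest.approx(0.225)
        assert sigma[1, 1] == pytest.approx(1.035)

    def test_symmetric_paths(self):
        _, sigma = implied_moments(params(m=0.07, f=0.07))
        assert sigma[0, 1] == pytest.approx(1.5 * 0.07 * 0.5)
        assert sigma[0, 1] == pytest.approx(sigma[0, 2])

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SEMParameters(m=0, f=0, phi=-1, sigma2=1, sigma2_o=1, rho=0)
        with pytest.raises(ValueError):
            SEMParameters(m=0, f=0, phi=0.5, sigma2=1, sigma2_o=1, rho=1.5)


class TestFimlLoglik:
    def test_single_record_at_the_mean(self):
        p = params()
        mu, sigma = implied_moments(p)
        data = PatternedDataset({Pattern.BOTH: mu[None, :]})
        expected = -0.5 * math.log((2 * math.pi) ** 3 * np.linalg.det(sigma))
        assert fiml_loglik(p, data) == pytest.approx(expected)

    def test_duplication_doubles(self, small_cohort):
        p = params(m=0.05, f=0.03, phi=0.42, rho=0.1)
        data = PatternedDataset.from_dataframe(small_cohort)
        doubled = PatternedDataset(
            {pat: np.vstack([x, x]) for pat, x in data.blocks.items()}
        )
        assert fiml_loglik(p, doubled) == pytest.approx(2 * fiml_loglik(p, data))

    def test_matches_per_record_density_oracle(self, small_cohort):
        p = params(m=0.02, f=0.06, phi=0.45, sigma2=1.1, sigma2_o=0.9, rho=0.12,
                   mu_snp=0.6, mu_bw=0.1, mu_bwo=-0.05)
        data = PatternedDataset.from_dataframe(small_cohort)
        mu, sigma = implied_moments(p)
        idx = {Pattern.OWN_ONLY: [0, 1], Pattern.OFFSPRING_ONLY: [0, 2], Pattern.BOTH: [0, 1, 2]}
        brute = sum(
            stats.multivariate_normal(mu[i], sigma[np.ix_(i, i)]).logpdf(x).sum()
            for pat, x in data.blocks.items()
            for i in [idx[pat]]
        )
        assert fiml_loglik(p, data) == pytest.approx(brute, abs=1e-8)

    def test_singular_implied_covariance_returns_minus_inf(self, small_cohort):
        # rho at the Cauchy-Schwarz boundary makes the residual pair perfectly
        # correlated and the implied covariance singular
        data = PatternedDataset.from_dataframe(small_cohort)
        boundary = SEMParameters(m=0.0, f=0.0, phi=0.5, sigma2=1.0, sigma2_o=1.0, rho=1.0)
        assert fiml_loglik(boundary, data) == -np.inf


class TestClosedFormMF:
    def test_symmetric_covariances(self):
        s = np.array([[1.0, 0.3, 0.3], [0.3, 2.0, 0.5], [0.3, 0.5, 2.0]])
        m, f = closed_form_mf(s)
        assert m == pytest.approx(2 * 0.3 / 3)
        assert f == pytest.approx(2 * 0.3 / 3)

    def test_round_trip_through_implied_moments(self):
        _, sigma = implied_moments(params(m=0.1, f=0.2))
        m, f = closed_form_mf(sigma)
        assert (m, f) == (pytest.approx(0.1), pytest.approx(0.2))

    def test_zero_covariances(self):
        s = np.diag([0.5, 1.0, 1.0])
        assert closed_form_mf(s) == (0.0, 0.0)

    def test_nonpositive_phi_rejected(self):
        with pytest.raises(ValueError):
            closed_form_mf(np.zeros((3, 3)))


class TestFitSem:
    def test_complete_data_matches_saturation_oracle(self, complete_cohort):
        data = PatternedDataset.from_dataframe(complete_cohort)
        fit = fit_sem(data, compute_lrt=False)
        X = complete_cohort[["g_self", "bw_own", "bw_offspring"]].to_numpy()
        xbar = X.mean(axis=0)
        S = (X - xbar).T @ (X - xbar) / len(X)
        m_cf, f_cf = closed_form_mf(S)
        assert fit.converged
        assert fit.estimates.m == pytest.approx(m_cf, abs=1e-4)
        assert fit.estimates.f == pytest.approx(f_cf, abs=1e-4)
        mu, sigma = implied_moments(fit.estimates)
        assert np.abs(sigma - S).max() < 1e-6
        assert np.abs(mu - xbar).max() < 1e-6

    def test_identification_errors(self, small_cohort):
        df = small_cohort.copy()
        with pytest.raises(ValueError, match="offspring birth weight"):
            no_bwo = df.copy()
            no_bwo["bw_offspring"] = np.nan
            fit_sem(PatternedDataset.from_dataframe(no_bwo))
        with pytest.raises(ValueError, match="own birth weight"):
            no_bw = df.copy()
            no_bw["bw_own"] = np.nan
            fit_sem(PatternedDataset.from_dataframe(no_bw))

    def test_scale_equivariance(self, small_cohort):
        data = PatternedDataset.from_dataframe(small_cohort)
        fit1 = fit_sem(data, compute_lrt=False)
        scaled = small_cohort.copy()
        scaled["bw_own"] *= 3.0
        scaled["bw_offspring"] *= 3.0
        fit2 = fit_sem(PatternedDataset.from_dataframe(scaled), compute_lrt=False)
        assert fit2.estimates.m == pytest.approx(3 * fit1.estimates.m, rel=1e-4)
        assert fit2.estimates.f == pytest.approx(3 * fit1.estimates.f, rel=1e-4)
        assert fit2.wald_m[0] == pytest.approx(fit1.wald_m[0], rel=1e-3)

    def test_information_monotone_in_complete_records(self):
        # moving records from single-phenotype patterns into BOTH at fixed n
        # can only sharpen the estimates
        ses = []
        for fractions in [(0.45, 0.45, 0.1), (0.25, 0.25, 0.5), (0.0, 0.0, 1.0)]:
            cfg = SimConfig(
                n_individuals=30_000, eaf=0.3, m=0.05, f=0.03, rho=0.1,
                pattern_fractions=fractions, seed=55,
            )
            fit = fit_sem(
                PatternedDataset.from_dataframe(simgen.simulate_cohort(cfg)),
                compute_lrt=False,
            )
            ses.append((fit.se["m"], fit.se["f"]))
        assert ses[0][0] > ses[1][0] > ses[2][0]
        assert ses[0][1] > ses[1][1] > ses[2][1]

    def test_agrees_with_pair_regression_on_complete_trios(self, complete_cohort):
        # asymptotic equivalence of FIML and the joint mother-child regression
        from matfet.pair_conditional import conditional_regression
        import pandas as pd

        cfg = SimConfig(
            n_individuals=50_000, eaf=0.3, m=0.05, f=0.03, rho=0.1,
            pattern_fractions=(0, 0, 1), seed=31,
        )
        cohort = simgen.simulate_cohort(cfg)
        fit = fit_sem(PatternedDataset.from_dataframe(cohort), compute_lrt=False)
        pairs = pd.DataFrame(
            {
                "g_mother": cohort["g_self"],
                "g_child": cohort["g_offspring"],
                "bw_z": cohort["bw_offspring"],
            }
        )
        maternal, fetal = conditional_regression(pairs)
        tol_m = 3 * math.hypot(fit.se["m"], maternal.se)
        tol_f = 3 * math.hypot(fit.se["f"], fetal.se)
        assert abs(fit.estimates.m - maternal.beta) < tol_m
        assert abs(fit.estimates.f - fetal.beta) < tol_f

    def test_fix_phi_option(self, complete_cohort):
        data = PatternedDataset.from_dataframe(complete_cohort)
        phi0 = 2 * 0.3 * 0.7
        fit = fit_sem(data, fix_phi=phi0, compute_lrt=False)
        assert fit.estimates.phi == phi0
        assert "phi" not in fit.se


class TestLRT:
    def test_strong_effects_give_tiny_p(self):
        cfg = SimConfig(
            n_individuals=50_000, eaf=0.3, m=0.2, f=0.2, rho=0.1, seed=13
        )
        fit = fit_sem(PatternedDataset.from_dataframe(simgen.simulate_cohort(cfg)))
        stat, p = fit.lrt_2df
        assert stat > 0
        assert p < 1e-8

    def test_null_data_small_statistic(self):
        cfg = SimConfig(n_individuals=20_000, eaf=0.3, m=0.0, f=0.0, rho=0.1, seed=14)
        data = PatternedDataset.from_dataframe(simgen.simulate_cohort(cfg))
        fit = fit_sem(data)
        stat, p = fit.lrt_2df
        assert 0 <= stat < stats.chi2(df=2).ppf(0.999)
        assert lrt_2df(fit, data) == pytest.approx(fit.lrt_2df)
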