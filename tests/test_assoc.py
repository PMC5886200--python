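"""Association stage: additive regression, HWE exact test, QC filters, GC."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from matfet import assoc


class TestAdditiveAssoc:
    def test_recovers_generative_slope(self, rng):
        n = 50_000
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.05 * g + rng.normal(0, 1, n)
        res = assoc.additive_assoc(g, y)
        assert abs(res.beta - 0.05) < 2 * res.se
        assert res.n == n
        assert res.eaf == pytest.approx(g.mean() / 2)

    def test_monomorphic_skipped(self):
        res = assoc.additive_assoc(np.zeros(100), np.random.default_rng(0).normal(size=100))
        assert res is None

    def test_perfect_fit(self, rng):
        g = rng.binomial(2, 0.5, 200).astype(float)
        res = assoc.additive_assoc(g, 0.1 * g)
        assert res.beta == pytest.approx(0.1, abs=1e-10)
        assert res.se == pytest.approx(0.0, abs=1e-10)

    def test_equivariance(self, rng):
        g = rng.binomial(2, 0.4, 2000).astype(float)
        y = 0.03 * g + rng.normal(0, 1, 2000)
        base = assoc.additive_assoc(g, y)
        doubled = assoc.additive_assoc(g, 2 * y)
        assert doubled.beta == pytest.approx(2 * base.beta)
        assert doubled.se == pytest.approx(2 * base.se)
        shifted = assoc.additive_assoc(g - 1.0, y)  # 0/1/2 -> -1/0/1 coding
        assert shifted.beta == pytest.approx(base.beta)
        assert shifted.p == pytest.approx(base.p)

    def test_covariate_adjustment_and_rank_deficiency(self, rng):
        n = 3000
        g = rng.binomial(2, 0.3, n).astype(float)
        sex = rng.integers(0, 2, n).astype(float)
        y = 0.05 * g + 0.4 * sex + rng.normal(0, 1, n)
        res = assoc.additive_assoc(g, y, covariates=pd.DataFrame({"sex": sex}))
        assert abs(res.beta - 0.05) < 3 * res.se
        with pytest.raises(ValueError, match="rank-deficient"):
            assoc.additive_assoc(
                g, y, covariates=np.column_stack([sex, sex])
            )

    def test_null_pvalues_uniform_and_lambda_near_one(self):
        # under m = f = 0 the per-SNP p-values are uniform and genomic
        # control finds nothing to correct
        rng = np.random.default_rng(77)
        n, reps = 500, 5000
        pvals = np.empty(reps)
        chisq = np.empty(reps)
        for i in range(reps):
            g = rng.binomial(2, 0.3, n).astype(float)
            y = rng.normal(0, 1, n)
            res = assoc.additive_assoc(g, y)
            pvals[i] = res.p
            chisq[i] = (res.beta / res.se) ** 2
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        lam, _ = assoc.genomic_control(chisq)
        assert 0.95 < lam < 1.05


def _hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration of the conditional heterozygote distribution."""
    n = n_AA + n_Aa + n_aa
    na = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    if na == 0:
        return 1.0
    weights = {}
    for h in range(na % 2, na + 1, 2):
        hom_minor = (na - h) // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            continue
        weights[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(hom_minor) * math.factorial(h) * math.factorial(hom_major),
        )
    total = sum(weights.values())
    p_obs = weights[n_Aa]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)


class TestHWEExact:
    def test_monomorphic_is_one(self):
        assert assoc.hwe_exact(57, 0, 0) == 1.0

    def test_two_sample_enumeration(self):
        # support {0, 2} hets with probabilities {1/3, 2/3}; observed 0 -> 1/3
        assert assoc.hwe_exact(1, 0, 1) == pytest.approx(1 / 3)

    def test_sample_at_hwe_proportions_not_rejected(self):
        # counts exactly at p^2 : 2pq : q^2 sit at the conditional mode
        assert assoc.hwe_exact(360, 480, 160) > 0.5

    def test_matches_exact_rational_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(1, 51))
            n_aa = int(rng.integers(0, n + 1))
            n_Aa = int(rng.integers(0, n - n_aa + 1))
            n_AA = n - n_aa - n_Aa
            assert assoc.hwe_exact(n_AA, n_Aa, n_aa) == pytest.approx(
                _hwe_oracle(n_AA, n_Aa, n_aa), rel=1e-9
            )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            assoc.hwe_exact(-1, 2, 3)
        with pytest.raises(ValueError):
            assoc.hwe_exact(0, 0, 0)


class TestFilterVariants:
    def _qc(self, rows):
        return pd.DataFrame(rows)

    def test_maf_and_dialect_thresholds(self):
        qc = self._qc(
            [
                {"snp_id": "low_maf", "eaf": 0.005, "quality": 0.99, "dialect": "PLINK_INFO"},
                {"snp_id": "plink_bad", "eaf": 0.3, "quality": 0.79, "dialect": "PLINK_INFO"},
                {"snp_id": "plink_edge", "eaf": 0.3, "quality": 0.80, "dialect": "PLINK_INFO"},
                {"snp_id": "mach_bad", "eaf": 0.3, "quality": 0.29, "dialect": "MACH_R2HAT"},
                {"snp_id": "snptest_ok", "eaf": 0.3, "quality": 0.45, "dialect": "SNPTEST_PROPER_INFO"},
                {"snp_id": "high_eaf", "eaf": 0.995, "quality": 0.9, "dialect": "PLINK_INFO"},
            ]
        )
        kept, log = assoc.filter_variants(qc, "autosomal-meta")
        assert sorted(kept["snp_id"]) == ["plink_edge", "snptest_ok"]
        reasons = dict(zip(log["snp_id"], log["reason"]))
        assert reasons["low_maf"] == "LOW_MAF"
        assert reasons["high_eaf"] == "LOW_MAF"  # maf = min(eaf, 1-eaf)
        assert reasons["plink_bad"] == "LOW_QUALITY"
        assert reasons["mach_bad"] == "LOW_QUALITY"

    def test_x_chromosome_profile(self):
        qc = self._qc(
            [
                {"snp_id": "a", "eaf": 0.3, "hwe_p": 1e-7, "missing_rate": 0.001},
                {"snp_id": "b", "eaf": 0.3, "hwe_p": 0.5, "missing_rate": 0.02},
                {"snp_id": "c", "eaf": 0.3, "hwe_p": 0.5, "missing_rate": 0.015},
            ]
        )
        kept, log = assoc.filter_variants(qc, "x-chromosome")
        assert list(kept["snp_id"]) == ["c"]
        reasons = dict(zip(log["snp_id"], log["reason"]))
        assert reasons == {"a": "HWE_FAIL", "b": "HIGH_MISSING"}

    def test_followup_profile_strict_quality_and_bonferroni_hwe(self):
        qc = self._qc(
            [
                {"snp_id": "hwe_bad", "eaf": 0.3, "quality": np.nan, "dialect": None, "hwe_p": 0.002},
                {"snp_id": "hwe_edge", "eaf": 0.3, "quality": np.nan, "dialect": None, "hwe_p": 0.0028},
                {"snp_id": "q_edge", "eaf": 0.3, "quality": 0.8, "dialect": "MACH_R2HAT", "hwe_p": 0.9},
                {"snp_id": "q_ok", "eaf": 0.3, "quality": 0.81, "dialect": "SNPTEST_PROPER_INFO", "hwe_p": 0.9},
            ]
        )
        kept, log = assoc.filter_variants(qc, "followup")
        assert sorted(kept["snp_id"]) == ["hwe_edge", "q_ok"]
        reasons = dict(zip(log["snp_id"], log["reason"]))
        assert reasons == {"hwe_bad": "HWE_FAIL", "q_edge": "LOW_QUALITY"}

    def test_conservation_and_unknown_dialect(self, rng):
        qc = pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(100)],
                "eaf": rng.uniform(0, 0.5, 100),
                "quality": rng.uniform(0.5, 1.1, 100),
                "dialect": "PLINK_INFO",
            }
        )
        kept, log = assoc.filter_variants(qc, "autosomal-meta")
        assert len(kept) + len(log) == len(qc)
        qc2 = qc.copy()
        qc2.loc[0, "dialect"] = "IMPUTE_SCORE"
        with pytest.raises(ValueError, match="dialect"):
            assoc.filter_variants(qc2, "autosomal-meta")


class TestGenomicControl:
    def test_lambda_one_at_chi2_median(self):
        stats_in = np.full(11, assoc.CHI2_1_MEDIAN)
        lam, adjusted = assoc.genomic_control(stats_in)
        assert lam == pytest.approx(1.0)
        assert adjusted == pytest.approx(stats_in)

    def test_scaling_recovered(self, rng):
        draws = 2.0 * rng.chisquare(1, 200_000)
        lam, adjusted = assoc.genomic_control(draws)
        assert lam == pytest.approx(2.0, rel=0.02)
        assert np.median(adjusted) == pytest.approx(assoc.CHI2_1_MEDIAN, rel=0.02)

    def test_no_deflation(self, rng):
        draws = 0.8 * rng.chisquare(1, 10_000)
        lam, adjusted = assoc.genomic_control(draws)
        assert lam < 1.0
        assert adjusted == pytest.approx(draws)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assoc.genomic_control([])
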