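"""Per-study association machinery.

Additive linear regression of a birth-weight z-score on genotype dosage with
covariates, variant-level quality control (minor allele frequency,
imputation-quality by software dialect, exact Hardy-Weinberg test, missing
rate) and per-study genomic control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "AssocResult",
    "FilterConfig",
    "FILTER_PROFILES",
    "additive_assoc",
    "hwe_exact",
    "filter_variants",
    "genomic_control",
]

# median of a 1-df chi-square; the genomic-control denominator
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))

QUALITY_DIALECTS = ("PLINK_INFO", "MACH_R2HAT", "SNPTEST_PROPER_INFO")

MONOMORPHIC = "MONOMORPHIC"
LOW_MAF = "LOW_MAF"
LOW_QUALITY = "LOW_QUALITY"
HWE_FAIL = "HWE_FAIL"
HIGH_MISSING = "HIGH_MISSING"


@dataclass(frozen=True)
class AssocResult:
    """A per-study additive association result (one SNP)."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: int

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("se must be nonnegative")


def additive_assoc(
    dosages,
    bw_z,
    covariates=None,
    *,
    snp_id: str = "snp",
    effect_allele: str = "A",
    other_allele: str = "G",
) -> AssocResult | None:
    """OLS of birth-weight z-score on dosage (additive model) with covariates.

    Dosages may be hard calls or fractional imputed values in [0, 2]; the
    effect allele frequency is mean(dosage)/2.  Rows with any missing value
    are dropped.  Two-sided p-values use the t reference.  Monomorphic
    dosages are skipped (returns None, logged) rather than raising.
    """
    g = np.asarray(dosages, dtype=float)
    y = np.asarray(bw_z, dtype=float)
    if covariates is None:
        x = np.empty((len(g), 0))
        cov_names: list[str] = []
    elif isinstance(covariates, pd.DataFrame):
        cov_names = list(covariates.columns)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        cov_names = [f"cov{i}" for i in range(x.shape[1])]

    ok = np.isfinite(g) & np.isfinite(y)
    if x.shape[1]:
        ok &= np.isfinite(x).all(axis=1)
    g, y, x = g[ok], y[ok], x[ok]
    n = len(g)
    if n <= x.shape[1] + 2:
        raise ValueError("too few complete observations for the design")
    if np.var(g) == 0:
        logger.warning("SNP %s skipped: %s", snp_id, MONOMORPHIC)
        return None

    design = np.column_stack([np.ones(n), g, x])
    k = design.shape[1]
    if np.linalg.matrix_rank(design) < k:
        raise ValueError(f"rank-deficient design (covariates: {cov_names})")

    fit = sm.OLS(y, design).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    if se == 0.0 or not math.isfinite(se):
        se = max(se, 0.0) if math.isfinite(se) else 0.0
        p = 0.0 if slope != 0 else 1.0
    else:
        p = float(2 * stats.t.sf(abs(slope / se), df=fit.df_resid))
    return AssocResult(
        snp_id=snp_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=float(g.mean() / 2.0),
        beta=slope,
        se=se,
        p=max(p, np.nextafter(0, 1)),
        n=n,
    )


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test for Hardy-Weinberg equilibrium.

    Given the allele counts, the heterozygote count follows a known
    conditional distribution under HWE; the p-value is the summed probability
    of all heterozygote counts at most as probable as the observed one
    (Wigginton-style mid-free exact test).
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts) or any(c != int(c) for c in counts):
        raise ValueError("genotype counts must be nonnegative integers")
    n_AA, n_Aa, n_aa = (int(c) for c in counts)
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    # work with the rarer allele
    n_alt = 2 * n_aa + n_Aa
    n_ref = 2 * n_AA + n_Aa
    n_minor = min(n_alt, n_ref)
    if n_minor == 0:
        return 1.0

    # support: heterozygote counts with the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    valid = hom_major >= 0
    hets, hom_minor, hom_major = hets[valid], hom_minor[valid], hom_major[valid]

    logp = (
        special.gammaln(n + 1)
        - special.gammaln(hom_minor + 1)
        - special.gammaln(hets + 1)
        - special.gammaln(hom_major + 1)
        + hets * math.log(2.0)
    )
    logp -= special.logsumexp(logp)
    probs = np.exp(logp)
    p_obs = probs[hets == n_Aa]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    p = probs[probs <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


@dataclass(frozen=True)
class FilterConfig:
    """Variant-QC thresholds.

    ``quality_min`` maps an imputation-quality dialect to its minimum;
    ``quality_strict`` distinguishes the two boundary conventions in use:
    False keeps a value equal to the threshold (discovery filters remove
    strictly-below values), True requires strictly greater (follow-up rule
    "quality > 0.8").  None thresholds disable the corresponding filter.
    """

    maf_min: float | None = 0.01
    quality_min: dict[str, float] | None = None
    quality_strict: bool = False
    hwe_p_min: float | None = None
    missing_max: float | None = None


FILTER_PROFILES: dict[str, FilterConfig] = {
    # genome-wide discovery meta-analysis: MAF and per-dialect imputation quality
    "autosomal-meta": FilterConfig(
        maf_min=0.01,
        quality_min={
            "PLINK_INFO": 0.8,
            "MACH_R2HAT": 0.3,
            "SNPTEST_PROPER_INFO": 0.4,
        },
        quality_strict=False,
    ),
    # directly genotyped X-chromosome set
    "x-chromosome": FilterConfig(
        maf_min=0.01, quality_min=None, hwe_p_min=1e-6, missing_max=0.015
    ),
    # custom-genotyped follow-up SNPs: Bonferroni HWE (0.05/18) and strict
    # quality > 0.8 for the imputed ones
    "followup": FilterConfig(
        maf_min=None,
        quality_min={"MACH_R2HAT": 0.8, "SNPTEST_PROPER_INFO": 0.8},
        quality_strict=True,
        hwe_p_min=0.0028,
    ),
}


def filter_variants(
    qc: pd.DataFrame, config: FilterConfig | str = "autosomal-meta"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply variant-level QC, conserving rows between kept table and log.

    Expected columns: ``snp_id``, ``eaf``; optional ``quality`` +
    ``dialect``, ``hwe_p``, ``missing_rate``.  Quality metrics slightly
    above 1 are clamped to 1.  Returns (kept, log of removed rows with
    reason codes).
    """
    if isinstance(config, str):
        try:
            config = FILTER_PROFILES[config]
        except KeyError:
            raise ValueError(
                f"unknown filter profile {config!r}; expected one of "
                f"{sorted(FILTER_PROFILES)}"
            ) from None

    df = qc.copy()
    maf = np.minimum(df["eaf"].to_numpy(float), 1.0 - df["eaf"].to_numpy(float))
    reason = pd.Series(pd.NA, index=df.index, dtype=object)

    if config.maf_min is not None:
        reason[maf < config.maf_min] = LOW_MAF

    if config.quality_min is not None and "quality" in df.columns:
        if "dialect" not in df.columns:
            raise ValueError("quality filtering requires a 'dialect' column")
        unknown = set(df["dialect"].dropna()) - set(QUALITY_DIALECTS)
        if unknown:
            raise ValueError(f"unknown quality dialect(s): {sorted(unknown)}")
        q = np.minimum(df["quality"].to_numpy(float), 1.0)  # clamp at read
        for dialect, threshold in config.quality_min.items():
            sel = (df["dialect"] == dialect).to_numpy() & np.isfinite(q)
            fail = (q <= threshold) if config.quality_strict else (q < threshold)
            reason[sel & fail & reason.isna()] = LOW_QUALITY

    if config.hwe_p_min is not None and "hwe_p" in df.columns:
        hp = df["hwe_p"].to_numpy(float)
        reason[np.isfinite(hp) & (hp < config.hwe_p_min) & reason.isna()] = HWE_FAIL

    if config.missing_max is not None and "missing_rate" in df.columns:
        mr = df["missing_rate"].to_numpy(float)
        reason[np.isfinite(mr) & (mr > config.missing_max) & reason.isna()] = HIGH_MISSING

    excluded = reason.notna()
    log = pd.DataFrame(
        {
            "snp_id": df.loc[excluded, "snp_id"].to_numpy(),
            "reason": reason[excluded].to_numpy(),
        }
    )
    return df.loc[~excluded].copy(), log


def genomic_control(chisq_stats) -> tuple[float, np.ndarray]:
    """Per-study genomic control.

    lambda = median(chi-square) / 0.4549 (the 1-df chi-square median);
    statistics are divided by lambda only when lambda > 1 (no deflation).
    Returns (lambda, adjusted statistics).
    """
    arr = np.asarray(chisq_stats, dtype=float)
    if arr.size == 0:
        raise ValueError("genomic control needs at least one statistic")
    if (arr < 0).any():
        raise ValueError("chi-square statistics must be nonnegative")
    lam = float(np.median(arr) / CHI2_1_MEDIAN)
    adjusted = arr / lam if lam > 1.0 else arr.copy()
    return lam, adjusted
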