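"""Synthetic three-generation cohorts for maternal/fetal effect partitioning.

Simulates the generative process the latent-genotype SEM assumes: a
grandmother's genotype drawn from Hardy-Weinberg equilibrium, Mendelian
transmission to the genotyped woman and again to her first child (random-mating
partners), birth weights built from a maternal path ``m`` (the mother's
genotype acting on her offspring's weight through the intrauterine
environment) and a fetal path ``f`` (the individual's own genotype acting on
their own weight):

    BW   = m * G_G + f * SNP + eps
    BW_O = m * SNP + f * G_O + eps_O

with bivariate-normal residuals ``(eps, eps_O)`` of variances ``sigma2``,
``sigma2_o`` and covariance ``rho``.  UK-Biobank-style planned missingness
(own birth weight only / offspring birth weight only / both) and raw-report
artifacts (pound-denominated reports, discrepant repeats, out-of-range values)
are layered on top so every downstream cleaning and fitting stage can be
exercised with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Pattern",
    "SimConfig",
    "mendelian_transmit",
    "simulate_genotypes",
    "simulate_phenotypes",
    "apply_missingness",
    "add_reporting_artifacts",
    "simulate_cohort",
]

# 1 SD of birth weight in the source cohorts is about 484 g.
BW_MEAN_KG = 3.5
BW_SD_KG = 0.484
KG_PER_POUND = 0.45


class Pattern(str, Enum):
    """Which birth-weight fields a participant reported."""

    OWN_ONLY = "OWN_ONLY"
    OFFSPRING_ONLY = "OFFSPRING_ONLY"
    BOTH = "BOTH"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one single-SNP cohort simulation.

    Defaults reflect the study conditions of the motivating analysis: a
    UK-Biobank-scale sample (n = 78 674) with reporting-pattern mix
    0.42 / 0.27 / 0.31 (own only / offspring only / both), an allele
    frequency of 0.3, and maternal/fetal effects on the order of the
    identified loci (a few hundredths of an SD of birth weight per allele).
    """

    n_individuals: int = 78_674
    eaf: float = 0.3
    m: float = 0.05
    f: float = 0.03
    sigma2: float = 1.0
    sigma2_o: float = 1.0
    rho: float = 0.1
    pattern_fractions: tuple[float, float, float] = (0.42, 0.27, 0.31)
    seed: int = 0
    dosage_noise_sd: float = 0.0  # optional imputation-style noise, off by default

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"eaf must be in [0, 1], got {self.eaf}")
        if self.sigma2 <= 0 or self.sigma2_o <= 0:
            raise ValueError("residual variances must be positive")
        if self.rho**2 > self.sigma2 * self.sigma2_o:
            raise ValueError(
                "residual covariance violates Cauchy-Schwarz: "
                f"rho^2 = {self.rho**2:.6g} > {self.sigma2 * self.sigma2_o:.6g}"
            )
        if len(self.pattern_fractions) != 3 or any(
            p < 0 for p in self.pattern_fractions
        ):
            raise ValueError("pattern_fractions must be three nonnegative values")
        if abs(sum(self.pattern_fractions) - 1.0) > 1e-12:
            raise ValueError("pattern_fractions must sum to 1 within 1e-12")
        if self.dosage_noise_sd < 0:
            raise ValueError("dosage_noise_sd must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _transmit_one(g_parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # One allele drawn uniformly from the parent's two: alt with prob g/2.
    return (rng.random(g_parent.shape) < g_parent / 2.0).astype(np.int64)


def mendelian_transmit(g_mother, g_father, rng: np.random.Generator):
    """Draw a child genotype from two parental genotypes.

    One allele is sampled uniformly from each parent's pair and summed, which
    realizes the fixed 0.5 parent-offspring transmission paths of the model.
    Accepts scalars or equal-length arrays of hard calls in {0, 1, 2}.
    """
    gm = np.asarray(g_mother)
    gf = np.asarray(g_father)
    for name, g in (("g_mother", gm), ("g_father", gf)):
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError(f"{name} contains genotypes outside {{0, 1, 2}}")
    child = _transmit_one(gm, rng) + _transmit_one(gf, rng)
    if np.ndim(g_mother) == 0 and np.ndim(g_father) == 0:
        return int(child)
    return child


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Three-generation genotypes: grandmother -> mother -> child.

    The grandmother and every partner (grandfather, the woman's own partner)
    are independent Hardy-Weinberg draws at ``config.eaf`` (random mating);
    each child is a Mendelian transmission from its two parents.
    """
    if rng is None:
        rng = config.rng()
    n = config.n_individuals
    g_grandmother = rng.binomial(2, config.eaf, n)
    g_grandfather = rng.binomial(2, config.eaf, n)
    g_self = mendelian_transmit(g_grandmother, g_grandfather, rng)
    g_partner = rng.binomial(2, config.eaf, n)
    g_offspring = mendelian_transmit(g_self, g_partner, rng)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "g_grandmother": g_grandmother,
            "g_self": g_self,
            "g_offspring": g_offspring,
        }
    )


def simulate_phenotypes(
    genotypes: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Attach own and offspring birth weights with correlated residuals."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(genotypes)
    cov = np.array(
        [[config.sigma2, config.rho], [config.rho, config.sigma2_o]], dtype=float
    )
    # Cholesky fails iff the residual covariance is not PD (config guards PSD).
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("residual covariance matrix is not positive definite") from exc
    eps = rng.standard_normal((n, 2)) @ chol.T
    out = genotypes.copy()
    out["bw_own"] = (
        config.m * out["g_grandmother"] + config.f * out["g_self"] + eps[:, 0]
    )
    out["bw_offspring"] = (
        config.m * out["g_self"] + config.f * out["g_offspring"] + eps[:, 1]
    )
    if config.dosage_noise_sd > 0:
        noisy = out["g_self"] + rng.normal(0, config.dosage_noise_sd, n)
        out["dosage_self"] = np.clip(noisy, 0.0, 2.0)
    return out


def apply_missingness(
    records: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Assign each record one reporting pattern and mask the unreported field.

    Patterns are drawn multinomially with ``config.pattern_fractions``,
    independently of phenotype (missing completely at random — the condition
    under which full-information maximum likelihood is valid).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    out = records.copy()
    codes = rng.choice(3, size=len(out), p=list(config.pattern_fractions))
    labels = np.array(
        [Pattern.OWN_ONLY.value, Pattern.OFFSPRING_ONLY.value, Pattern.BOTH.value]
    )
    out["pattern"] = labels[codes]
    out.loc[codes == 0, "bw_offspring"] = np.nan
    out.loc[codes == 1, "bw_own"] = np.nan
    return out


def add_reporting_artifacts(
    records: pd.DataFrame,
    rng: np.random.Generator,
    *,
    second_report_fraction: float = 0.0,
    second_report_error_lb: float = 1.5,
    out_of_range_fraction: float = 0.0,
    mean_kg: float = BW_MEAN_KG,
    sd_kg: float = BW_SD_KG,
) -> pd.DataFrame:
    """Turn offspring birth-weight z-scores into raw pound-denominated reports.

    Emulates questionnaire data: weights reported in pounds, a fraction of
    women answering twice with a discrepant second report (offset by
    ``second_report_error_lb`` pounds, >= 1 lb so the repeat filter fires),
    and a fraction of implausible out-of-range values.  The z-to-kg mapping
    uses mean 3.5 kg and SD 0.484 kg, with tails compressed into
    [2.55, 4.45] kg so that only injected artifacts violate the downstream
    range filter; the ground-truth record id is retained throughout.
    """
    base = records.loc[records["bw_offspring"].notna()].copy()
    kg = np.clip(mean_kg + sd_kg * base["bw_offspring"].to_numpy(), 2.55, 4.45)

    n = len(base)
    out = pd.DataFrame({"id": base["id"].to_numpy()})
    report_1 = kg / KG_PER_POUND
    report_2 = np.full(n, np.nan)

    if second_report_fraction > 0 and n > 0:
        k = int(round(second_report_fraction * n))
        idx = rng.choice(n, size=k, replace=False)
        signs = rng.choice([-1.0, 1.0], size=k)
        report_2[idx] = report_1[idx] + signs * second_report_error_lb

    if out_of_range_fraction > 0 and n > 0:
        k = int(round(out_of_range_fraction * n))
        # choose from records without an injected second report so each
        # record carries at most one artifact class
        candidates = np.flatnonzero(np.isnan(report_2))
        idx = rng.choice(candidates, size=min(k, len(candidates)), replace=False)
        low = rng.random(len(idx)) < 0.5
        injected_kg = np.where(
            low, rng.uniform(0.8, 2.3, len(idx)), rng.uniform(4.7, 6.5, len(idx))
        )
        report_1 = np.asarray(report_1, dtype=float)
        report_1[idx] = injected_kg / KG_PER_POUND

    out["report_1"] = report_1
    out["report_2"] = report_2
    return out


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Full generative chain: genotypes -> phenotypes -> missingness patterns."""
    rng = config.rng()
    geno = simulate_genotypes(config, rng)
    pheno = simulate_phenotypes(geno, config, rng)
    return apply_missingness(pheno, config, rng)
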