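"""Fixed-effects inverse-variance meta-analysis of GWAS summary statistics.

Allele harmonization across studies, the inverse-variance-weighted pooled
estimate, Cochran's Q heterogeneity test, the final combination of
SEM-derived and mother-child-pair conditional estimates, and an additive
variance-explained summary.  A ``verify`` mode recomputes the pooled estimate
through an independent accumulation code path and asserts agreement,
mirroring the practice of running two meta-analysts in parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "StudyEffect",
    "MetaResult",
    "harmonize_alleles",
    "ivw_meta",
    "cochran_q",
    "combine_sem_pairs",
    "variance_explained",
]

PALINDROMIC = "PALINDROMIC"
ALLELE_MISMATCH = "ALLELE_MISMATCH"

_PALINDROME_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class StudyEffect:
    """One study's effect estimate for one SNP."""

    study_id: str
    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    n: int

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("se must be positive")


@dataclass(frozen=True)
class MetaResult:
    """Pooled fixed-effects result with heterogeneity diagnostics."""

    snp_id: str
    beta: float
    se: float
    p: float
    n_total: int
    k_studies: int
    q: float | None = None
    q_df: int | None = None
    p_het: float | None = None
    direction: str = ""
    label: str = ""


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1.upper(), a2.upper()} in _PALINDROME_PAIRS


def harmonize_alleles(
    records: list[StudyEffect],
) -> tuple[list[StudyEffect], list[tuple[StudyEffect, str]]]:
    """Express all studies on a common effect allele (the first study's).

    Records whose alleles are swapped relative to the reference get
    beta -> -beta and eaf -> 1 - eaf.  Palindromic SNPs (A/T, C/G) are
    rejected outright — strand orientation cannot be inferred — as are
    allele pairs matching neither orientation.  Returns (aligned records,
    rejects with reason).
    """
    aligned: list[StudyEffect] = []
    rejected: list[tuple[StudyEffect, str]] = []
    reference: tuple[str, str] | None = None
    for rec in records:
        ea, oa = rec.effect_allele.upper(), rec.other_allele.upper()
        if _is_palindromic(ea, oa):
            rejected.append((rec, PALINDROMIC))
            continue
        if reference is None:
            reference = (ea, oa)
            aligned.append(rec)
            continue
        if (ea, oa) == reference:
            aligned.append(rec)
        elif (oa, ea) == reference:
            aligned.append(
                replace(
                    rec,
                    effect_allele=reference[0],
                    other_allele=reference[1],
                    beta=-rec.beta,
                    eaf=1.0 - rec.eaf,
                )
            )
        else:
            rejected.append((rec, ALLELE_MISMATCH))
    return aligned, rejected


def _ivw_matrix(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    w = 1.0 / ses**2
    beta = float(w @ betas / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    return beta, se


def _ivw_accumulate(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    # independent code path: sequential scalar accumulation
    sw = 0.0
    swb = 0.0
    for b, s in zip(betas.tolist(), ses.tolist()):
        w = 1.0 / (s * s)
        sw += w
        swb += w * b
    return swb / sw, 1.0 / sw**0.5


def ivw_meta(effects: list[StudyEffect], *, verify: bool = False, label: str = "") -> MetaResult:
    """Fixed-effects inverse-variance pooled estimate.

    Weights are 1/se^2; the two-sided p-value uses a normal reference.  With
    ``verify=True`` the estimate is recomputed via an independent
    accumulation path and the two must agree to 1e-10.  Inputs are assumed
    allele-harmonized.
    """
    if not effects:
        raise ValueError("meta-analysis needs at least one study")
    betas = np.array([e.beta for e in effects])
    ses = np.array([e.se for e in effects])
    if (ses <= 0).any():
        raise ValueError("all standard errors must be positive")
    beta, se = _ivw_matrix(betas, ses)
    if verify:
        beta2, se2 = _ivw_accumulate(betas, ses)
        if abs(beta - beta2) > 1e-10 or abs(se - se2) > 1e-10:
            raise AssertionError(
                "parallel meta-analysis code paths disagree: "
                f"({beta}, {se}) vs ({beta2}, {se2})"
            )
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    direction = "".join("+" if b > 0 else "-" if b < 0 else "0" for b in betas)
    q = q_df = p_het = None
    if len(effects) >= 2:
        q, q_df, p_het = cochran_q(effects)
    return MetaResult(
        snp_id=effects[0].snp_id,
        beta=beta,
        se=se,
        p=max(p, np.nextafter(0, 1)),
        n_total=int(sum(e.n for e in effects)),
        k_studies=len(effects),
        q=q,
        q_df=q_df,
        p_het=p_het,
        direction=direction,
        label=label,
    )


def cochran_q(effects: list[StudyEffect]) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic: sum of w_i (beta_i - pooled)^2.

    Referred to a chi-square with k-1 degrees of freedom under homogeneity.
    """
    if len(effects) < 2:
        raise ValueError("heterogeneity test needs at least 2 studies")
    betas = np.array([e.beta for e in effects])
    ses = np.array([e.se for e in effects])
    w = 1.0 / ses**2
    pooled = w @ betas / w.sum()
    q = float(w @ (betas - pooled) ** 2)
    df = len(effects) - 1
    return q, df, float(stats.chi2.sf(q, df=df))


def combine_sem_pairs(
    sem_estimate: StudyEffect,
    pair_estimate: StudyEffect | None = None,
    *,
    label: str = "",
    verify: bool = False,
) -> MetaResult:
    """Combine an SEM-derived conditional estimate with the pair-based one.

    A plain inverse-variance meta-analysis of the two inputs (which must be
    on the same allele and scale); when the pair estimate is absent, the SEM
    estimate is returned as a single-study result.
    """
    inputs = [sem_estimate] if pair_estimate is None else [sem_estimate, pair_estimate]
    return ivw_meta(inputs, verify=verify, label=label)


def variance_explained(betas, eafs) -> float:
    """Additive variance explained on the z-score scale: sum 2 p (1-p) beta^2.

    Assumes independent loci; an approximation, no standard error reported.
    """
    b = np.asarray(betas, dtype=float)
    p = np.asarray(eafs, dtype=float)
    if b.shape != p.shape:
        raise ValueError("betas and eafs must have matching shapes")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("eaf values must lie strictly inside (0, 1)")
    if not np.isfinite(b).all():
        raise ValueError("betas must be finite")
    return float((2.0 * p * (1.0 - p) * b**2).sum())
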