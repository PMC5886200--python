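"""Conditional regression in mother-child pairs.

When both maternal and fetal genotypes are observed, a single joint
regression of the offspring birth-weight z-score on both genotypes (plus sex
and gestational duration where available) separates the maternal effect,
adjusted for the fetal genotype, from the fetal effect adjusted for the
maternal genotype.  Because mother and child share half their alleles
(genotype correlation about 0.5), the unconditional maternal estimate
absorbs half the fetal effect and vice versa; the joint fit removes that
contamination directly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .assoc import AssocResult
from .meta import MetaResult, StudyEffect, ivw_meta

logger = logging.getLogger(__name__)

__all__ = ["conditional_regression", "pair_meta"]

_OPTIONAL_COVARIATES = ("sex", "gestational_duration")


def conditional_regression(
    pairs: pd.DataFrame,
    *,
    snp_id: str = "snp",
    effect_allele: str = "A",
    other_allele: str = "G",
) -> tuple[AssocResult, AssocResult]:
    """Joint OLS of bw_z on g_mother + g_child (+ sex, gestational duration).

    Returns (maternal_conditional, fetal_conditional) association results.
    Optional covariate columns absent from the table are simply omitted
    (logged), matching cohorts where gestational duration was not collected.
    Near-perfect correlation between the two genotypes raises a collinearity
    error.
    """
    needed = ["g_mother", "g_child", "bw_z"]
    for col in needed:
        if col not in pairs.columns:
            raise ValueError(f"pairs table missing required column {col!r}")
    cov_cols = [c for c in _OPTIONAL_COVARIATES if c in pairs.columns]
    for c in set(_OPTIONAL_COVARIATES) - set(cov_cols):
        logger.info("covariate %r unavailable; fitting without it", c)

    cols = needed + cov_cols
    data = pairs[cols].dropna()
    gm = data["g_mother"].to_numpy(float)
    gc = data["g_child"].to_numpy(float)
    y = data["bw_z"].to_numpy(float)
    n = len(data)
    if n <= len(cov_cols) + 3:
        raise ValueError("too few complete mother-child pairs for the design")
    if np.std(gm) == 0 or np.std(gc) == 0:
        raise ValueError("monomorphic genotype in mother-child pairs")
    r = np.corrcoef(gm, gc)[0, 1]
    if abs(r) > 0.99:
        raise ValueError(
            f"maternal and fetal genotypes nearly collinear (|r| = {abs(r):.4f})"
        )

    design = np.column_stack(
        [np.ones(n), gm, gc] + [data[c].to_numpy(float) for c in cov_cols]
    )
    fit = sm.OLS(y, design).fit()

    def result(idx: int, eaf: float) -> AssocResult:
        slope, se = float(fit.params[idx]), float(fit.bse[idx])
        p = float(2 * stats.t.sf(abs(slope / se), df=fit.df_resid)) if se > 0 else 0.0
        return AssocResult(
            snp_id=snp_id,
            effect_allele=effect_allele,
            other_allele=other_allele,
            eaf=eaf,
            beta=slope,
            se=se,
            p=max(p, np.nextafter(0, 1)),
            n=n,
        )

    maternal = result(1, float(gm.mean() / 2))
    fetal = result(2, float(gc.mean() / 2))
    return maternal, fetal


def pair_meta(
    per_study: dict[str, tuple[AssocResult, AssocResult]], *, verify: bool = False
) -> dict[str, MetaResult]:
    """Pool per-study conditional estimates with fixed-effects IVW.

    ``per_study`` maps study id to its (maternal_conditional,
    fetal_conditional) results; returns pooled results keyed
    ``"maternal_conditional"`` / ``"fetal_conditional"``.
    """
    if not per_study:
        raise ValueError("no per-study results supplied")

    def to_effects(which: int) -> list[StudyEffect]:
        return [
            StudyEffect(
                study_id=sid,
                snp_id=res[which].snp_id,
                effect_allele=res[which].effect_allele,
                other_allele=res[which].other_allele,
                eaf=res[which].eaf,
                beta=res[which].beta,
                se=res[which].se,
                n=res[which].n,
            )
            for sid, res in per_study.items()
        ]

    return {
        "maternal_conditional": ivw_meta(
            to_effects(0), verify=verify, label="maternal_conditional"
        ),
        "fetal_conditional": ivw_meta(
            to_effects(1), verify=verify, label="fetal_conditional"
        ),
    }
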