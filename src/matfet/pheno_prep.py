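"""Phenotype cleaning and transformation.

Implements the questionnaire-report cleaning used for self-reported offspring
birth weight (pound-to-kg conversion, plausible-range and repeat-report
filters), covariate residualization, z-scoring, rank-based inverse-normal
transformation, and the blood-pressure preparation used for look-up analyses
(reading averaging, discrepancy and outlier screens, antihypertensive
medication offsets).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pounds_to_kg",
    "filter_offspring_bw",
    "zscore",
    "adjust_covariates",
    "inverse_normal",
    "prep_blood_pressure",
    "BP_TRAITS",
]

KG_PER_POUND = 0.45

# exclusion reason codes
RANGE = "RANGE"
REPEAT_DISCREPANCY = "REPEAT_DISCREPANCY"
MULTIPLE_BIRTH = "MULTIPLE_BIRTH"
READING_DISCREPANCY = "READING_DISCREPANCY"
OUTLIER = "OUTLIER"
NO_READINGS = "NO_READINGS"

# birth weight plausibility window (kg); values strictly outside are removed
BW_KG_MIN = 2.5
BW_KG_MAX = 4.5
# repeat reports differing by at least 1 lb (0.45 kg) are treated as unreliable
REPEAT_DIFF_KG = 0.45

# trait SD (mmHg) and medication offsets for systolic/diastolic blood pressure
BP_TRAITS = {
    "sbp": {"sd": 19.7, "medication_offset": 15.0},
    "dbp": {"sd": 13.1, "medication_offset": 10.0},
}
BP_SD_MULTIPLE = 4.56


def pounds_to_kg(x):
    """Convert pounds to kilograms (factor 0.45, as used for the raw reports)."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("birth weight in pounds cannot be negative")
    out = KG_PER_POUND * arr
    return float(out) if np.ndim(x) == 0 else out


def filter_offspring_bw(reports: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the offspring birth-weight report filters.

    Input columns: ``id``, ``report_1`` (pounds), optional ``report_2``
    (repeat report, pounds), optional boolean ``multiple_birth``.  Removes
    flagged multiple births, records whose two reports differ by >= 0.45 kg
    (1 lb, boundary inclusive), and derived weights outside [2.5, 4.5] kg
    (boundaries kept).  Returns (kept table with a ``bw_kg`` column,
    exclusion log with one row per removed record).
    """
    df = reports.copy()
    df["bw_kg"] = pounds_to_kg(df["report_1"].to_numpy())

    reason = pd.Series(pd.NA, index=df.index, dtype=object)

    if "multiple_birth" in df.columns:
        flag = df["multiple_birth"].fillna(False).astype(bool)
        reason[flag] = MULTIPLE_BIRTH

    if "report_2" in df.columns:
        r2 = df["report_2"]
        diff_kg = pounds_to_kg((df["report_1"] - r2).abs().to_numpy())
        discrepant = r2.notna().to_numpy() & (diff_kg >= REPEAT_DIFF_KG - 1e-12)
        reason[discrepant & reason.isna()] = REPEAT_DISCREPANCY

    out_of_range = (df["bw_kg"] < BW_KG_MIN) | (df["bw_kg"] > BW_KG_MAX)
    reason[out_of_range & reason.isna()] = RANGE

    excluded = reason.notna()
    log = pd.DataFrame(
        {
            "id": df.loc[excluded, "id"].to_numpy(),
            "reason": reason[excluded].to_numpy(),
            "value": df.loc[excluded, "bw_kg"].to_numpy(),
        }
    )
    kept = df.loc[~excluded].copy()
    return kept, log


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (n-1 denominator); NaN propagated."""
    arr = np.asarray(values, dtype=float)
    obs = arr[np.isfinite(arr)]
    if obs.size < 2:
        raise ValueError("zscore requires at least 2 non-missing values")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValueError("zscore undefined for zero-variance input")
    out = np.where(np.isfinite(arr), (arr - obs.mean()) / sd, np.nan)
    return out


def adjust_covariates(pheno, covariates) -> np.ndarray:
    """Residualize a phenotype on covariates (plus intercept), then z-score.

    ``covariates`` may be None/empty (intercept only), a DataFrame or a 2-D
    array.  Rank-deficient covariate matrices raise an error naming the
    collinear columns.
    """
    y = np.asarray(pheno, dtype=float)
    if covariates is None:
        return zscore(y)
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{i}" for i in range(x.shape[1])]
    if x.shape[1] == 0:
        return zscore(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("phenotype and covariates have different lengths")

    design = np.column_stack([np.ones(len(y)), x])
    # identify collinear columns via the diagonal of R in a pivoted-free QR
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps * 10
    bad = np.flatnonzero(diag < tol)
    if bad.size:
        offenders = [("intercept" if j == 0 else names[j - 1]) for j in bad]
        raise ValueError(f"collinear covariate columns: {', '.join(offenders)}")

    ok = np.isfinite(y) & np.isfinite(x).all(axis=1)
    beta, *_ = np.linalg.lstsq(design[ok], y[ok], rcond=None)
    resid = np.where(ok, y - design @ beta, np.nan)
    # a phenotype exactly linear in the covariates leaves only rounding noise
    if np.nanstd(resid) <= 1e-10 * (np.nanstd(y) + np.finfo(float).tiny):
        raise ValueError("zero-variance residuals: phenotype is collinear with covariates")
    return zscore(resid)


def inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets by default.

    Maps average ranks r to ``norminv((r - c) / (n - 2c + 1))`` with
    c = 3/8, preserving order; ties share the average rank; NaN propagated.
    """
    arr = np.asarray(values, dtype=float)
    mask = np.isfinite(arr)
    obs = arr[mask]
    n = obs.size
    if n < 2 or np.unique(obs).size < 2:
        raise ValueError("inverse_normal requires at least 2 distinct values")
    ranks = stats.rankdata(obs, method="average")
    transformed = stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1))
    out = np.full(arr.shape, np.nan)
    out[mask] = transformed
    return out


def prep_blood_pressure(
    records: pd.DataFrame, trait: str = "sbp", trait_sd: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Prepare blood-pressure readings for analysis.

    Input columns: ``id``, ``reading_1``, ``reading_2`` (mmHg; either may be
    missing), boolean ``on_medication``.  Records whose two readings differ
    by more than 4.56 trait SDs are excluded; the remaining readings are
    averaged (a single valid reading is used as-is and logged); +15 mmHg
    (SBP) or +10 mmHg (DBP) is added for antihypertensive users; finally,
    adjusted values more than 4.56 trait SDs from the sample mean are
    excluded.  Returns (kept table with ``adjusted`` column, exclusion log).
    """
    if trait not in BP_TRAITS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {sorted(BP_TRAITS)}")
    sd = BP_TRAITS[trait]["sd"] if trait_sd is None else float(trait_sd)
    offset = BP_TRAITS[trait]["medication_offset"]
    threshold = BP_SD_MULTIPLE * sd

    df = records.copy()
    r1 = df["reading_1"].to_numpy(dtype=float)
    r2 = df["reading_2"].to_numpy(dtype=float)
    med = df["on_medication"].fillna(False).astype(bool).to_numpy()

    reason = np.full(len(df), None, dtype=object)
    note = np.full(len(df), None, dtype=object)

    both = np.isfinite(r1) & np.isfinite(r2)
    none = ~np.isfinite(r1) & ~np.isfinite(r2)
    reason[none] = NO_READINGS
    discrepant = both & (np.abs(r1 - r2) > threshold)
    reason[discrepant & (reason == None)] = READING_DISCREPANCY  # noqa: E711

    single = np.isfinite(r1) ^ np.isfinite(r2)
    note[single] = "SINGLE_READING"

    adjusted = np.where(
        both, (r1 + r2) / 2.0, np.where(np.isfinite(r1), r1, r2)
    )
    adjusted = adjusted + np.where(med, offset, 0.0)

    ok = reason == None  # noqa: E711
    sample_mean = np.nanmean(adjusted[ok])
    outlier = ok & (np.abs(adjusted - sample_mean) > threshold)
    reason[outlier] = OUTLIER

    excluded = reason != None  # noqa: E711
    log = pd.DataFrame(
        {
            "id": df.loc[excluded, "id"].to_numpy(),
            "reason": reason[excluded],
            "value": adjusted[excluded],
        }
    )
    kept = df.loc[~excluded].copy()
    kept["adjusted"] = adjusted[~excluded]
    kept["note"] = note[~excluded]
    return kept, log
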