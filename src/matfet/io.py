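"""File formats, provenance headers and deterministic seeding.

Interchange is tab-delimited text with ``#``-prefixed provenance comment
lines (tool version, config hash, seed, timestamp, input checksums) — the
METAL-era GWAS summary-statistics convention: diff-able and free of binary
dependencies.  Summary-statistics ingestion resolves column names through
per-dialect synonym maps because formats drift.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .meta import StudyEffect

__all__ = [
    "substream",
    "write_table",
    "read_table",
    "write_cohort",
    "read_cohort",
    "read_summary_stats",
    "write_summary_stats",
    "SUMMARY_COLUMN_SYNONYMS",
]

NA_TOKEN = "NA"

COHORT_COLUMNS = [
    "id",
    "g_grandmother",
    "g_self",
    "g_offspring",
    "bw_own",
    "bw_offspring",
    "pattern",
]

# canonical name -> accepted synonyms (case-insensitive), METAL names included
SUMMARY_COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "SNP": ("SNP", "MARKERNAME", "RSID", "SNP_ID"),
    "CHR": ("CHR", "CHROMOSOME"),
    "POS": ("POS", "POSITION", "BP"),
    "EFFECT_ALLELE": ("EFFECT_ALLELE", "ALLELE1", "EA", "A1"),
    "OTHER_ALLELE": ("OTHER_ALLELE", "ALLELE2", "OA", "A2", "NEA"),
    "EAF": ("EAF", "FREQ1", "FREQ", "AF"),
    "BETA": ("BETA", "EFFECT", "B"),
    "SE": ("SE", "STDERR", "STDERR_BETA"),
    "P": ("P", "P-VALUE", "PVALUE", "P_VALUE"),
    "N": ("N", "WEIGHT", "SAMPLESIZE"),
    "INFO": ("INFO", "QUALITY", "R2HAT", "PROPER_INFO"),
    "INFO_TYPE": ("INFO_TYPE", "DIALECT"),
}

_REQUIRED_SUMMARY = ("SNP", "EFFECT_ALLELE", "OTHER_ALLELE", "EAF", "BETA", "SE", "N")


def substream(seed: int, stage: str) -> np.random.Generator:
    """Named RNG substream: every stage draws from the one root seed."""
    key = zlib.crc32(stage.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _config_hash(config) -> str:
    payload = json.dumps(config, sort_keys=True, default=str) if config else ""
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def provenance_lines(
    seed: int | None = None, config=None, inputs: list[str | Path] | None = None
) -> list[str]:
    lines = [
        f"# matfet v{__version__}",
        f"# config_hash={_config_hash(config)}",
        f"# seed={seed if seed is not None else 'NA'}",
        f"# timestamp={datetime.now(timezone.utc).isoformat()}",
    ]
    for p in inputs or []:
        lines.append(f"# input={Path(p).name} sha256={_file_checksum(Path(p))}")
    return lines


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    seed: int | None = None,
    config=None,
    inputs: list[str | Path] | None = None,
    float_format: str = "%.10g",
) -> Path:
    """Write a tab-delimited table with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(seed=seed, config=config, inputs=inputs):
            fh.write(line + "\n")
        df.to_csv(
            fh, sep="\t", index=False, na_rep=NA_TOKEN, float_format=float_format
        )
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited table, skipping provenance comment lines."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NA_TOKEN])


def write_cohort(df: pd.DataFrame, path: str | Path, *, seed: int | None = None, config=None) -> Path:
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    return write_table(df[cols + extra], path, seed=seed, config=config)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    missing = [c for c in ("id", "g_self") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required column(s): {missing}")
    return df


def _resolve_columns(columns: list[str]) -> dict[str, str]:
    upper = {c.upper(): c for c in columns}
    mapping: dict[str, str] = {}
    for canonical, synonyms in SUMMARY_COLUMN_SYNONYMS.items():
        for syn in synonyms:
            if syn in upper:
                mapping[canonical] = upper[syn]
                break
    return mapping


def read_summary_stats(
    path: str | Path, *, study_id: str | None = None
) -> tuple[list[StudyEffect], pd.DataFrame]:
    """Read METAL-style summary statistics into typed study effects.

    Column names are resolved through the synonym map; a missing required
    column raises an error naming the canonical column.  Malformed rows
    (EAF outside [0, 1], nonpositive SE, non-finite beta) are collected into
    a reject report rather than silently dropped.  Returns
    (effects, reject report).
    """
    path = Path(path)
    df = read_table(path)
    mapping = _resolve_columns(list(df.columns))
    missing = [c for c in _REQUIRED_SUMMARY if c not in mapping]
    if missing:
        raise ValueError(f"summary-statistics file missing column(s): {missing}")
    sid = study_id or path.stem

    effects: list[StudyEffect] = []
    rejects: list[dict] = []
    for _, row in df.iterrows():
        snp = str(row[mapping["SNP"]])
        try:
            eaf = float(row[mapping["EAF"]])
            beta = float(row[mapping["BETA"]])
            se = float(row[mapping["SE"]])
            n = int(row[mapping["N"]])
            ea = str(row[mapping["EFFECT_ALLELE"]]).upper()
            oa = str(row[mapping["OTHER_ALLELE"]]).upper()
        except (TypeError, ValueError):
            rejects.append({"snp_id": snp, "reason": "UNPARSEABLE"})
            continue
        if not 0.0 <= eaf <= 1.0:
            rejects.append({"snp_id": snp, "reason": "EAF_OUT_OF_RANGE"})
            continue
        if not np.isfinite(beta):
            rejects.append({"snp_id": snp, "reason": "NONFINITE_BETA"})
            continue
        if not (np.isfinite(se) and se > 0):
            rejects.append({"snp_id": snp, "reason": "BAD_SE"})
            continue
        if not (ea.isalpha() and oa.isalpha()):
            rejects.append({"snp_id": snp, "reason": "BAD_ALLELES"})
            continue
        effects.append(
            StudyEffect(
                study_id=sid,
                snp_id=snp,
                effect_allele=ea,
                other_allele=oa,
                eaf=eaf,
                beta=beta,
                se=se,
                n=n,
            )
        )
    return effects, pd.DataFrame(rejects, columns=["snp_id", "reason"])


def write_summary_stats(
    effects: list[StudyEffect], path: str | Path, *, seed: int | None = None, config=None
) -> Path:
    """Write study effects in the METAL-compatible tab-delimited layout."""
    df = pd.DataFrame(
        {
            "SNP": [e.snp_id for e in effects],
            "EFFECT_ALLELE": [e.effect_allele for e in effects],
            "OTHER_ALLELE": [e.other_allele for e in effects],
            "EAF": [e.eaf for e in effects],
            "BETA": [e.beta for e in effects],
            "SE": [e.se for e in effects],
            "N": [e.n for e in effects],
        }
    )
    return write_table(df, path, seed=seed, config=config)
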