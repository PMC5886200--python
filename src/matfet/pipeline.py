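"""End-to-end pipeline driver over synthetic cohorts.

Runs the full chain on simulated data with known ground truth:
simulate -> prep (report cleaning + z-scoring) -> per-study association with
genomic control -> fixed-effects meta-analysis -> SEM fit -> mother-child
pair conditional regression -> combination of SEM and pair estimates.  Every
stage logs record counts, all randomness flows from one root seed through
named substreams, and every artifact carries a provenance header.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import meta as meta_mod
from . import pheno_prep, sem_core, simgen
from .io import read_table, substream, write_cohort, write_summary_stats, write_table
from .meta import StudyEffect
from .pair_conditional import conditional_regression

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

STAGES = ("simulate", "prep", "assoc", "meta", "sem", "pairs", "combine")


class PipelineError(RuntimeError):
    """A stage failed; the message names the failing stage."""


@dataclass
class PipelineConfig:
    """Configuration of one synthetic end-to-end run."""

    seed: int = 0
    out_dir: str | Path = "matfet_out"
    stages: tuple[str, ...] = STAGES
    n_studies: int = 3
    sim: dict = field(default_factory=dict)  # SimConfig field overrides
    artifact_second_report_fraction: float = 0.02
    artifact_out_of_range_fraction: float = 0.02
    verify_meta: bool = False

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown pipeline stage(s): {unknown}; valid: {STAGES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        d["stages"] = list(d["stages"])
        return d


def _sim_config(config: PipelineConfig, study: int) -> simgen.SimConfig:
    overrides = dict(config.sim)
    overrides.setdefault("n_individuals", 5000)
    overrides["seed"] = int(
        substream(config.seed, f"simulate/{study}").integers(0, 2**31 - 1)
    )
    return simgen.SimConfig(**overrides)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the configured stages in order; returns the artifact paths.

    A stage failure halts the run with the failing stage named; files the
    failing stage had begun writing are retained with a ``.partial`` suffix.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    state: dict = {"config": config}

    for stage in config.stages:
        runner = _STAGE_RUNNERS[stage]
        written: list[Path] = []
        try:
            runner(config, state, artifacts, out_dir, written)
            logger.info("stage %s complete", stage)
        except Exception as exc:
            for path in written:
                if path.exists():
                    path.rename(path.with_suffix(path.suffix + ".partial"))
            raise PipelineError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return artifacts


def _stage_simulate(config, state, artifacts, out_dir, written):
    cohorts = []
    for study in range(config.n_studies):
        sim = _sim_config(config, study)
        cohort = simgen.simulate_cohort(sim)
        path = out_dir / f"cohort_{study}.tsv"
        written.append(path)
        write_cohort(cohort, path, seed=config.seed, config=config.as_dict())
        cohorts.append(cohort)
        logger.info("study %d: simulated %d trios", study, len(cohort))
    state["cohorts"] = cohorts
    state["sim_truth"] = _sim_config(config, 0)
    artifacts.update(
        {f"cohort_{i}": out_dir / f"cohort_{i}.tsv" for i in range(config.n_studies)}
    )
    # raw report table with injected artifacts, for the cleaning stage
    rng = substream(config.seed, "artifacts")
    reports = simgen.add_reporting_artifacts(
        cohorts[0],
        rng,
        second_report_fraction=config.artifact_second_report_fraction,
        out_of_range_fraction=config.artifact_out_of_range_fraction,
    )
    path = out_dir / "raw_reports.tsv"
    written.append(path)
    write_table(reports, path, seed=config.seed, config=config.as_dict())
    state["reports"] = reports
    artifacts["raw_reports"] = path


def _stage_prep(config, state, artifacts, out_dir, written):
    reports = state.get("reports")
    if reports is None:
        reports = read_table(artifacts["raw_reports"])
    kept, log = pheno_prep.filter_offspring_bw(reports)
    kept["bw_z"] = pheno_prep.zscore(kept["bw_kg"].to_numpy())
    kept_path = out_dir / "reports_clean.tsv"
    log_path = out_dir / "reports_exclusions.csv"
    written.extend([kept_path, log_path])
    write_table(kept, kept_path, seed=config.seed, config=config.as_dict())
    log.to_csv(log_path, index=False)
    logger.info("prep: kept %d reports, excluded %d", len(kept), len(log))
    state["reports_clean"] = kept
    artifacts["reports_clean"] = kept_path
    artifacts["reports_exclusions"] = log_path


def _stage_assoc(config, state, artifacts, out_dir, written):
    effects: list[StudyEffect] = []
    for study, cohort in enumerate(state["cohorts"]):
        sel = cohort["bw_offspring"].notna()
        res = assoc_mod.additive_assoc(
            cohort.loc[sel, "g_self"],
            cohort.loc[sel, "bw_offspring"],
            snp_id="snp1",
        )
        if res is None:
            continue
        lam, _ = assoc_mod.genomic_control(np.array([(res.beta / res.se) ** 2]))
        logger.info("study %d: beta=%.4f se=%.4f lambda=%.3f", study, res.beta, res.se, lam)
        effects.append(
            StudyEffect(
                study_id=f"study_{study}",
                snp_id=res.snp_id,
                effect_allele=res.effect_allele,
                other_allele=res.other_allele,
                eaf=res.eaf,
                beta=res.beta,
                se=res.se,
                n=res.n,
            )
        )
    path = out_dir / "assoc.tsv"
    written.append(path)
    write_summary_stats(effects, path, seed=config.seed, config=config.as_dict())
    state["study_effects"] = effects
    artifacts["assoc"] = path


def _stage_meta(config, state, artifacts, out_dir, written):
    aligned, rejected = meta_mod.harmonize_alleles(state["study_effects"])
    result = meta_mod.ivw_meta(aligned, verify=config.verify_meta)
    path = out_dir / "meta.tsv"
    written.append(path)
    df = pd.DataFrame([dataclasses.asdict(result)])
    write_table(df, path, seed=config.seed, config=config.as_dict())
    logger.info(
        "meta: beta=%.4f se=%.4f p=%.3g (%d studies, %d rejected)",
        result.beta,
        result.se,
        result.p,
        result.k_studies,
        len(rejected),
    )
    state["meta_result"] = result
    artifacts["meta"] = path


def _stage_sem(config, state, artifacts, out_dir, written):
    cohort = state["cohorts"][0]
    data = sem_core.PatternedDataset.from_dataframe(cohort)
    fit = sem_core.fit_sem(data)
    path = out_dir / "sem_fit.json"
    written.append(path)
    payload = {
        "estimates": dataclasses.asdict(fit.estimates),
        "se": fit.se,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_by_pattern": fit.n_by_pattern,
        "wald_m": fit.wald_m,
        "wald_f": fit.wald_f,
        "lrt_2df": fit.lrt_2df,
    }
    path.write_text(json.dumps(payload, indent=2))
    # one StudyEffect row per conditional estimate, on the meta schema
    state["sem_effects"] = {
        "maternal_conditional": StudyEffect(
            study_id="sem",
            snp_id="snp1",
            effect_allele="A",
            other_allele="G",
            eaf=float(cohort["g_self"].mean() / 2),
            beta=fit.estimates.m,
            se=fit.se["m"],
            n=data.n_total,
        ),
        "fetal_conditional": StudyEffect(
            study_id="sem",
            snp_id="snp1",
            effect_allele="A",
            other_allele="G",
            eaf=float(cohort["g_self"].mean() / 2),
            beta=fit.estimates.f,
            se=fit.se["f"],
            n=data.n_total,
        ),
    }
    state["sem_fit"] = fit
    logger.info(
        "sem: m=%.4f (SE %.4f), f=%.4f (SE %.4f), converged=%s",
        fit.estimates.m,
        fit.se["m"],
        fit.estimates.f,
        fit.se["f"],
        fit.converged,
    )
    artifacts["sem_fit"] = path


def _stage_pairs(config, state, artifacts, out_dir, written):
    # complete trios double as mother-child pairs: the woman is the mother,
    # her child's genotype is observed in the simulation
    cohort = state["cohorts"][0]
    sel = cohort["bw_offspring"].notna()
    pairs = pd.DataFrame(
        {
            "g_mother": cohort.loc[sel, "g_self"].to_numpy(float),
            "g_child": cohort.loc[sel, "g_offspring"].to_numpy(float),
            "bw_z": cohort.loc[sel, "bw_offspring"].to_numpy(float),
        }
    )
    maternal, fetal = conditional_regression(pairs, snp_id="snp1")
    path = out_dir / "pairs.tsv"
    written.append(path)
    df = pd.DataFrame(
        [
            {"label": "maternal_conditional", **dataclasses.asdict(maternal)},
            {"label": "fetal_conditional", **dataclasses.asdict(fetal)},
        ]
    )
    write_table(df, path, seed=config.seed, config=config.as_dict())
    state["pair_results"] = (maternal, fetal)
    artifacts["pairs"] = path


def _stage_combine(config, state, artifacts, out_dir, written):
    maternal, fetal = state["pair_results"]
    sem_effects = state["sem_effects"]
    rows = []
    for label, pair_res in (
        ("maternal_conditional", maternal),
        ("fetal_conditional", fetal),
    ):
        pair_eff = StudyEffect(
            study_id="pairs",
            snp_id=pair_res.snp_id,
            effect_allele=pair_res.effect_allele,
            other_allele=pair_res.other_allele,
            eaf=pair_res.eaf,
            beta=pair_res.beta,
            se=pair_res.se,
            n=pair_res.n,
        )
        combined = meta_mod.combine_sem_pairs(
            sem_effects[label], pair_eff, label=label, verify=config.verify_meta
        )
        rows.append({"label": label, **dataclasses.asdict(combined)})
    path = out_dir / "combined.tsv"
    written.append(path)
    write_table(pd.DataFrame(rows), path, seed=config.seed, config=config.as_dict())
    artifacts["combined"] = path


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "prep": _stage_prep,
    "assoc": _stage_assoc,
    "meta": _stage_meta,
    "sem": _stage_sem,
    "pairs": _stage_pairs,
    "combine": _stage_combine,
}
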