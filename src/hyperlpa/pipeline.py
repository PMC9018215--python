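"""Umbrella pipeline: simulate -> score -> percentile -> segregate -> models.

Stage outputs land in a run directory together with a manifest recording
the seed, version and configuration, so a run can be reproduced
byte-identically from its manifest.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import __version__
from .core import ConfigurationError, GenomicInterval, LPA_LOCUS, norm_chrom
from .core import KIV2_4925, RS140570886, RS186696265
from . import io as hio
from . import percentiles as pct
from . import phenomodels as pm
from . import scoring
from . import segregation as seg
from . import sim

logger = logging.getLogger(__name__)

_ALL_STAGES = ("simulate", "score", "percentile", "segregate", "models")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class ScoringOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    vcf: Optional[str] = None
    reference_vcf: Optional[str] = None
    lpa_weights: Optional[str] = None
    cad_weights: Optional[str] = None
    exclude: List[str] = [f"chr6:{LPA_LOCUS.start}-{LPA_LOCUS.end}"]
    missing: Literal["skip", "impute"] = "skip"


class SegregationOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_depth: int = 4
    pad: int = 50
    max_phenocopies: int = 0
    max_hom: int = 0


class RunConfig(BaseModel):
    """Validated pipeline configuration (unknown keys are rejected)."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str
    seed: int = 0
    stages: List[str] = list(_ALL_STAGES)
    sim: Dict = {}
    scoring: ScoringOptions = ScoringOptions()
    segregation: SegregationOptions = SegregationOptions()
    log_level: str = "INFO"

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v):
        unknown = [s for s in v if s not in _ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}")
        return v


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**data)


def _sim_dir(cfg: RunConfig) -> Path:
    return Path(cfg.out_dir) / "sim"


def _resolve(cfg: RunConfig, explicit: Optional[str], default_name: str) -> Path:
    p = Path(explicit) if explicit else _sim_dir(cfg) / default_name
    if not p.exists():
        raise ConfigurationError(f"required input {p} does not exist")
    return p


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order.

    Any stage error aborts the run with :class:`PipelineError` naming the
    failing stage.  Returns the run manifest (also written to
    ``run_manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("hyperlpa")
    root.addHandler(handler)
    root.setLevel(config.log_level.upper())

    outputs: Dict[str, list] = {}
    try:
        for stage in _ALL_STAGES:
            if stage not in config.stages:
                continue
            logger.info("running stage %s", stage)
            try:
                outputs[stage] = _STAGES[stage](config)
            except Exception as exc:
                logger.error("stage %s failed: %s", stage, exc)
                raise PipelineError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest = {
        "tool": "hyperlpa",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "outputs": outputs,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _stage_simulate(cfg: RunConfig) -> list:
    sim_cfg = sim.SimConfig(**{**cfg.sim, "seed": cfg.seed})
    manifest = sim.write_fixtures(_sim_dir(cfg), sim_cfg)
    return manifest["files"]


def _load_cohorts(cfg: RunConfig):
    fam_vcf = _resolve(cfg, cfg.scoring.vcf, "family.vcf")
    ref_vcf = _resolve(cfg, cfg.scoring.reference_vcf, "reference.vcf")
    fam, fam_samples = hio.read_vcf(fam_vcf)
    ref, ref_samples = hio.read_vcf(ref_vcf)
    return fam, fam_samples, ref, ref_samples


def _stage_score(cfg: RunConfig) -> list:
    out = Path(cfg.out_dir)
    fam, fam_samples, ref, ref_samples = _load_cohorts(cfg)
    lpa_w = scoring.read_score_file(_resolve(cfg, cfg.scoring.lpa_weights,
                                             "lpa_weights.tsv"))
    cad_w = scoring.read_score_file(_resolve(cfg, cfg.scoring.cad_weights,
                                             "cad_weights.tsv"))
    written = []
    for label, variants, samples in (("family", fam, fam_samples),
                                     ("reference", ref, ref_samples)):
        res = scoring.compute_grs(variants, lpa_w, samples=samples,
                                  missing_policy=cfg.scoring.missing)
        name = f"scores_lpa_{label}.tsv"
        scoring.results_table(res).to_csv(out / name, sep="\t")
        written.append(name)

    intervals = [GenomicInterval.from_string(s) for s in cfg.scoring.exclude]
    interval = intervals[0]
    for label, variants, samples in (("family", fam, fam_samples),
                                     ("reference", ref, ref_samples)):
        delta = scoring.ablation_delta(variants, cad_w, interval,
                                       samples=samples,
                                       missing_policy=cfg.scoring.missing)
        name = f"scores_cad_{label}.tsv"
        delta.to_csv(out / name, sep="\t")
        written.append(name)
    return written


def _stage_percentile(cfg: RunConfig) -> list:
    out = Path(cfg.out_dir)
    fam, fam_samples, ref, ref_samples = _load_cohorts(cfg)
    lpa_w = scoring.read_score_file(_resolve(cfg, cfg.scoring.lpa_weights,
                                             "lpa_weights.tsv"))
    cad_w = scoring.read_score_file(_resolve(cfg, cfg.scoring.cad_weights,
                                             "cad_weights.tsv"))
    written = []

    ref_res = scoring.compute_grs(ref, lpa_w, samples=ref_samples,
                                  missing_policy=cfg.scoring.missing)
    fam_res = scoring.compute_grs(fam, lpa_w, samples=fam_samples,
                                  missing_policy=cfg.scoring.missing)
    reports = pct.build_reports(fam_res, [r.score for r in ref_res])
    pct.reports_table(reports).to_csv(out / "percentiles_lpa.tsv", sep="\t")
    written.append("percentiles_lpa.tsv")

    interval = GenomicInterval.from_string(cfg.scoring.exclude[0])
    paired = pct.ablation_percentile_report(
        fam, cad_w, ref, interval, samples=fam_samples,
        reference_samples=ref_samples, missing_policy=cfg.scoring.missing)
    for label, reports in paired.items():
        name = f"percentiles_cad_{label}.tsv"
        pct.reports_table(reports).to_csv(out / name, sep="\t")
        written.append(name)
    return written


def _stage_segregate(cfg: RunConfig) -> list:
    out = Path(cfg.out_dir)
    vcf = _resolve(cfg, cfg.scoring.vcf, "family.vcf")
    ped = _resolve(cfg, None, "family.ped")
    exons = _resolve(cfg, None, "exons.bed")
    seg_cfg = seg.SegregationConfig(
        min_depth=cfg.segregation.min_depth,
        exon_pad=cfg.segregation.pad,
        max_phenocopies=cfg.segregation.max_phenocopies,
        max_hom_carriers=cfg.segregation.max_hom,
    )
    manifest_path = _sim_dir(cfg) / "manifest.json"
    samples = None
    if manifest_path.exists():
        samples = json.loads(manifest_path.read_text()).get("exome_samples")
    table, counts = seg.run_scan(vcf, ped, exons, seg_cfg, samples=samples)
    table.to_csv(out / "candidates.tsv", sep="\t", index=False)
    (out / "segregation_counts.json").write_text(
        json.dumps(counts, indent=2) + "\n")
    return ["candidates.tsv", "segregation_counts.json"]


def _stage_models(cfg: RunConfig) -> list:
    out = Path(cfg.out_dir)
    pheno = pd.read_csv(_resolve(cfg, None, "phenotypes.tsv"), sep="\t")
    scores = pd.read_csv(out / "scores_lpa_family.tsv", sep="\t",
                         index_col="sample_id")
    fam, fam_samples = hio.read_vcf(_resolve(cfg, cfg.scoring.vcf, "family.vcf"))

    def site_dosage(vid: str) -> dict:
        for v in fam:
            if v.vid == vid:
                return v.dosages
        raise ConfigurationError(f"site {vid} absent from family VCF")

    d186 = site_dosage(RS186696265)
    d140 = site_dosage(RS140570886)

    obs = pheno[pheno.lpa_phenotype != "unassigned"].copy()
    obs["grs"] = [scores.loc[m, "score"] for m in obs.member_id]
    obs["rs186696265"] = [d186[m] for m in obs.member_id]
    obs["rs140570886"] = [d140[m] for m in obs.member_id]
    obs["sex_male"] = (obs.sex == "male").astype(int)

    y = pm.inverse_normal(obs.lpa_nmol_l.to_numpy())
    models = [
        ("grs", obs[["grs"]]),
        ("rs186696265", obs[["rs186696265"]]),
        ("rs140570886", obs[["rs140570886"]]),
        ("isoform_age_sex_4925_grs",
         obs[["isoform_short_kiv", "age", "sex_male", "carries_4925", "grs"]]),
    ]
    fits = pm.variance_explained(y, models)
    pd.DataFrame(
        [(f.label, f.n_obs, f.r_squared, f.p_value, ";".join(f.covariates))
         for f in fits],
        columns=["model", "n", "r_squared", "p_value", "covariates"],
    ).to_csv(out / "models.tsv", sep="\t", index=False)

    carriers = obs[obs.carries_21kiv == 1].oxpl_per_lpa_nmol_l
    others = obs[obs.carries_21kiv == 0].oxpl_per_lpa_nmol_l
    w = pm.welch_t(carriers, others)
    pd.DataFrame([{
        "comparison": "oxpl_per_lpa_by_21kiv", "t": w.t, "df": w.df, "p": w.p,
        "mean_carriers": w.mean_a, "mean_others": w.mean_b,
        "n_carriers": len(carriers), "n_others": len(others),
    }]).to_csv(out / "comparison.tsv", sep="\t", index=False)

    derived = obs[["member_id", "lpa_nmol_l", "ldl_c_mmol_l"]].copy()
    cls = [pm.classify_lpa(v) for v in derived.lpa_nmol_l]
    derived["elevated_clinical"] = [c.elevated_clinical for c in cls]
    derived["family_class"] = [c.family for c in cls]
    derived["ldl_c_corrected_mmol_l"] = [
        round(pm.corrected_ldl(l, a), 4)
        for l, a in zip(derived.ldl_c_mmol_l, derived.lpa_nmol_l)
    ]
    derived.to_csv(out / "phenotypes_derived.tsv", sep="\t", index=False)
    return ["models.tsv", "comparison.tsv", "phenotypes_derived.tsv"]


_STAGES = {
    "simulate": _stage_simulate,
    "score": _stage_score,
    "percentile": _stage_percentile,
    "segregate": _stage_segregate,
    "models": _stage_models,
}
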