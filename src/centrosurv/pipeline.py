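"""Configuration, validation and end-to-end pipeline orchestration.

A run executes the requested stages in dependency order —
ingest/simulate -> IHC scoring -> survival stratification -> CA-gene
correlation panel -> CAI -> GSEA — writing every output as CSV plus a
manifest that records the config hash, the seed and the stage seeds, so
any run is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .cohort import SyntheticCohortConfig, generate_cohort
from .enrichment import gsea, read_gmt, stratify_by_gene
from .expression import cai, correlation_panel, read_expression_csv, \
    read_series_matrix
from .ihc import compare_wi_groups, read_field_counts, score_ihc_table
from .survival import stratified_survival_analysis

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline"]

log = logging.getLogger("centrosurv")


class ConfigError(ValueError):
    """Invalid pipeline configuration; ``errors`` lists every violation."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" +
                         "\n".join(f"  - {e}" for e in self.errors))


class _Inputs(BaseModel):
    model_config = ConfigDict(extra="forbid")
    expression: Optional[str] = None       # CSV or series-matrix text
    expression_format: str = "csv"         # csv | series_matrix
    clinical: Optional[str] = None
    gene_sets: Optional[str] = None        # GMT
    ihc_counts: Optional[str] = None


class _Filters(BaseModel):
    model_config = ConfigDict(extra="forbid")
    histotype: Optional[str] = None
    site: Optional[str] = None


class _SurvivalOpts(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gene: str = "KIFC1"
    min_group_frac: float = Field(0.10, gt=0.0, lt=0.5)
    ties: str = "efron"
    n_permutations: int = Field(0, ge=0)
    adjust_for: list[str] = ["grade", "stage"]


class _GseaOpts(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_permutations: int = Field(1000, ge=1)
    weight_p: float = 1.0
    metric: str = "signal_to_noise"
    cutpoint_source: str = "survival_optimal"


class _SimulateOpts(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_samples: int = Field(154, gt=0)
    true_hr: float = Field(2.14, gt=0)
    baseline_hazard_rate: float = Field(0.02, gt=0)
    censoring_rate: float = Field(0.0225, gt=0)


class PipelineConfig(BaseModel):
    """Typed, fully validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    inputs: _Inputs = _Inputs()
    simulate: Optional[_SimulateOpts] = None
    filters: _Filters = _Filters()
    correlation_panel: Optional[list[str]] = None
    cai_panel: str | list[str] = "results"
    survival: _SurvivalOpts = _SurvivalOpts()
    gsea: _GseaOpts = _GseaOpts()
    stages: list[str] = ["survival", "correlations", "cai"]
    seed: int = 0
    output_dir: str = "centrosurv_out"

    def semantic_errors(self) -> list[str]:
        errs = []
        known = {"ihc", "survival", "correlations", "cai", "gsea"}
        for st in self.stages:
            if st not in known:
                errs.append(f"stages: unknown stage {st!r} (choose from {sorted(known)})")
        if self.simulate is None and self.inputs.expression is None:
            errs.append("inputs.expression: required unless a simulate block is given")
        if "gsea" in self.stages and self.inputs.gene_sets is None:
            errs.append("inputs.gene_sets: required when the gsea stage is requested")
        if "ihc" in self.stages and self.inputs.ihc_counts is None:
            errs.append("inputs.ihc_counts: required when the ihc stage is requested")
        if self.survival.ties not in ("efron", "breslow"):
            errs.append("survival.ties: must be 'efron' or 'breslow'")
        if self.inputs.expression_format not in ("csv", "series_matrix"):
            errs.append("inputs.expression_format: must be 'csv' or 'series_matrix'")
        for name in ("expression", "clinical", "gene_sets", "ihc_counts"):
            p = getattr(self.inputs, name)
            if p is not None and not Path(p).exists():
                errs.append(f"inputs.{name}: path {p!r} does not exist")
        return errs


def validate_config(path) -> PipelineConfig:
    """Load + validate a YAML config, reporting every violation at once."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise ConfigError([f"cannot read config file: {exc}"]) from exc
    except yaml.YAMLError as exc:
        raise ConfigError([f"config is not valid YAML: {exc}"]) from exc
    errors = []
    try:
        cfg = PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        for e in exc.errors():
            loc = ".".join(str(p) for p in e["loc"])
            errors.append(f"{loc}: {e['msg']}")
        raise ConfigError(errors) from exc
    errors.extend(cfg.semantic_errors())
    if errors:
        raise ConfigError(errors)
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seeds(seed: int, stages) -> dict:
    """Derive independent per-stage seeds from the global seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(stages))
    return {st: int(c.generate_state(1)[0] % (2 ** 31)) for st, c in
            zip(stages, children)}


def _load_inputs(cfg: PipelineConfig, stage_seed: int):
    if cfg.simulate is not None and cfg.inputs.expression is None:
        sim = cfg.simulate
        cohort = generate_cohort(SyntheticCohortConfig(
            n_samples=sim.n_samples,
            true_log_hr=float(np.log(sim.true_hr)),
            baseline_hazard_rate=sim.baseline_hazard_rate,
            censoring_rate=sim.censoring_rate,
            seed=stage_seed,
        ))
        return cohort.expression, cohort.clinical
    if cfg.inputs.expression_format == "series_matrix":
        matrix, clinical = read_series_matrix(cfg.inputs.expression)
    else:
        matrix = read_expression_csv(cfg.inputs.expression)
        clinical = None
    if cfg.inputs.clinical is not None:
        clinical = pd.read_csv(cfg.inputs.clinical)
    return matrix, clinical


def run_pipeline(config: PipelineConfig, output_dir=None) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Every stage writes its outputs as new CSV files under the output
    directory; a failure aborts the run with the stage name in the error
    and leaves the manifest marked incomplete.
    """
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    seeds = _stage_seeds(config.seed, ["ingest"] + stages)
    manifest = {
        "package": "centrosurv",
        "version": __version__,
        "config_hash": _config_hash(config),
        "config": config.model_dump(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "outputs": {},
        "stats": {},
        "complete": False,
    }
    manifest_path = outdir / "manifest.json"

    def _write_manifest():
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    current = "ingest"
    try:
        matrix, clinical = _load_inputs(config, seeds["ingest"])
        if matrix is not None:
            p = outdir / "expression_used.csv"
            matrix.to_csv(p)
            manifest["outputs"]["expression"] = str(p)
        if clinical is not None:
            p = outdir / "clinical_used.csv"
            clinical.to_csv(p, index=False)
            manifest["outputs"]["clinical"] = str(p)
            log.info("ingest: %d genes x %d samples", *matrix.shape)

        for current in stages:
            if current == "ihc":
                fields = read_field_counts(config.inputs.ihc_counts)
                wi = score_ihc_table(fields)
                p = outdir / "ihc_wi.csv"
                wi.to_csv(p, index=False)
                manifest["outputs"]["ihc_wi"] = str(p)
                if "grade" in wi.columns and wi["grade"].nunique() >= 2:
                    cmp_res = compare_wi_groups(wi["wi"], wi["grade"])
                    manifest["stats"]["ihc"] = {
                        "test": cmp_res.test,
                        "p_value": cmp_res.p_value,
                        "group_means": cmp_res.group_means,
                    }
                    if cmp_res.pairwise_adjusted_p is not None:
                        p2 = outdir / "ihc_pairwise.csv"
                        cmp_res.pairwise_adjusted_p.to_csv(p2, index=False)
                        manifest["outputs"]["ihc_pairwise"] = str(p2)
            elif current == "survival":
                filters = {k: v for k, v in
                           config.filters.model_dump().items() if v}
                res = stratified_survival_analysis(
                    matrix, clinical,
                    gene=config.survival.gene,
                    filters=filters,
                    adjust_for=tuple(config.survival.adjust_for),
                    min_group_frac=config.survival.min_group_frac,
                    n_permutations=config.survival.n_permutations,
                    seed=seeds["survival"],
                )
                res.cutpoint.scan_table.to_csv(
                    outdir / "cutpoint_scan.csv", index=False)
                res.km_high.as_frame().to_csv(outdir / "km_high.csv", index=False)
                res.km_low.as_frame().to_csv(outdir / "km_low.csv", index=False)
                res.cox_univariate.summary().to_csv(outdir / "cox_univariate.csv")
                if res.cox_multivariate is not None:
                    res.cox_multivariate.summary().to_csv(
                        outdir / "cox_multivariate.csv")
                manifest["outputs"]["survival"] = str(outdir / "cox_univariate.csv")
                manifest["stats"]["survival"] = {
                    "n": res.n,
                    "threshold": res.cutpoint.threshold,
                    "chi2_max": res.cutpoint.chi2_max,
                    "p_naive": res.cutpoint.p_naive,
                    "p_adjusted": res.cutpoint.p_adjusted,
                    "hr_univariate": float(res.cox_univariate.hazard_ratios[0]),
                    "hr_multivariate": (
                        float(res.cox_multivariate.hazard_ratios[0])
                        if res.cox_multivariate is not None else None),
                }
                log.info("survival: n=%d threshold=%.3f chi2=%.2f",
                         res.n, res.cutpoint.threshold, res.cutpoint.chi2_max)
            elif current == "correlations":
                panel = correlation_panel(
                    matrix, anchor_gene=config.survival.gene,
                    panel=config.correlation_panel)
                p = outdir / "correlation_panel.csv"
                panel.to_csv(p, index=False)
                manifest["outputs"]["correlation_panel"] = str(p)
                manifest["stats"]["correlations"] = {
                    "n_significant": int(panel["significant"].sum()),
                    "top_gene": str(panel.iloc[0]["gene"]) if len(panel) else None,
                }
            elif current == "cai":
                table = cai(matrix, panel=config.cai_panel)
                p = outdir / "cai.csv"
                table.values.to_csv(p, index=False)
                manifest["outputs"]["cai"] = str(p)
                manifest["stats"]["cai"] = {
                    "genes_used": table.genes_used,
                    "genes_missing": table.genes_missing,
                }
            elif current == "gsea":
                sets = read_gmt(config.inputs.gene_sets)
                labels = stratify_by_gene(
                    matrix, clinical, gene=config.survival.gene,
                    cutpoint_source=config.gsea.cutpoint_source,
                    min_group_frac=config.survival.min_group_frac,
                    seed=seeds["gsea"])
                results = gsea(matrix, labels, sets,
                               n_permutations=config.gsea.n_permutations,
                               weight_p=config.gsea.weight_p,
                               seed=seeds["gsea"])
                p = outdir / "gsea_results.csv"
                results.to_csv(p, index=False)
                manifest["outputs"]["gsea"] = str(p)
                manifest["stats"]["gsea"] = {
                    "n_significant": int(results["significant"].sum()),
                }
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        _write_manifest()
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc
    manifest["complete"] = True
    _write_manifest()
    return manifest
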