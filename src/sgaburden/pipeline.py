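"""End-to-end orchestration: simulate -> collapse -> match -> burden -> stats
-> prognosis model -> report, behind one structured YAML config.

One global seed fans out deterministically to per-stage seeds (via
``numpy.random.SeedSequence.spawn``), every artefact is a TSV or JSON file,
and the run manifest records a SHA-256 hash of each output so a rerun with
the same config can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import matching as matching_mod
from . import prognosis as prognosis_mod
from .cohort_stats import group_comparison_table
from .simulate import (
    FLAG_COLUMNS,
    CovariateModel,
    OutcomeModel,
    PlantedGene,
    SimulationConfig,
    simulate_cohort,
)
from .variants import collapse_counts, filter_rare

logger = logging.getLogger(__name__)

STAGES = ["simulate", "collapse", "match", "burden", "stats", "model", "report"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class MatchSettings:
    covariates: list = field(default_factory=lambda: list(matching_mod.DEFAULT_COVARIATES))
    ratio: int = 1
    caliper: float | None = None


@dataclass
class ModelSettings:
    split_ratio: float = 0.7
    alpha_screen: float = 0.05
    cv_folds: int = 10
    cv_repeats: int = 3
    grid: dict = field(default_factory=lambda: dict(prognosis_mod.GbmConfig().grid))
    genetic_feature_mode: str = "per_gene"
    validation_n: int = 115


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    af_threshold: float = 0.01
    burden: burden_mod.BurdenConfig = field(default_factory=burden_mod.BurdenConfig)
    match: MatchSettings = field(default_factory=MatchSettings)
    model: ModelSettings = field(default_factory=ModelSettings)

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s): {', '.join(unknown)}")
        enabled = set(self.stages)
        deps = {
            "collapse": {"simulate"},
            "match": {"simulate"},
            "burden": {"collapse"},
            "stats": {"simulate"},
            "model": {"collapse"},
            "report": set(),
        }
        for stage in enabled:
            missing = deps.get(stage, set()) - enabled
            if missing:
                raise ConfigError(f"stage '{stage}' requires stage(s): {', '.join(sorted(missing))}")


def _build_dataclass(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown key(s) at {path}: {', '.join(sorted(unknown))}")
    kwargs = {}
    for key, value in data.items():
        ftype = fields[key].type
        if isinstance(value, dict) and ftype in _NESTED:
            kwargs[key] = _build_dataclass(_NESTED[ftype], value, f"{path}.{key}")
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value at {path}: {exc}") from exc


_NESTED = {
    "SimulationConfig": SimulationConfig,
    "burden_mod.BurdenConfig": burden_mod.BurdenConfig,
    "BurdenConfig": burden_mod.BurdenConfig,
    "MatchSettings": MatchSettings,
    "ModelSettings": ModelSettings,
    "CovariateModel": CovariateModel,
    "OutcomeModel": OutcomeModel,
}


def load_config(path) -> PipelineConfig:
    """Parse a YAML pipeline config; absent keys take defaults, unknown keys
    are rejected (anti-typo guard)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    cfg = _build_dataclass(PipelineConfig, raw, "config")
    cfg.validate()
    logger.info("resolved config: %s", cfg)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages in order; returns and writes the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, _spawn_seeds(config.seed, len(STAGES))))
    manifest: dict = {"seed": config.seed, "stage_seeds": seeds, "stages": {}, "artifacts": {}}
    enabled = set(config.stages)

    def register(stage: str, name: str, path: Path):
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}
        manifest["stages"].setdefault(stage, []).append(name)

    t0 = time.time()
    sim = config.simulation
    sim.seed = seeds["simulate"]
    cohort = simulate_cohort(sim)
    samples, variants = cohort.samples, cohort.variants
    if "simulate" in enabled:
        paths = cohort.write(outdir)
        for name, p in paths.items():
            register("simulate", name, p)
        logger.info("simulate: %d samples, %d variant records (%.1fs)",
                    len(samples), len(variants), time.time() - t0)

    matrix = None
    if "collapse" in enabled:
        rare = filter_rare(variants, config.af_threshold)
        gene_list = [f"G{i:04d}" for i in range(sim.n_genes)]
        matrix = collapse_counts(rare, list(samples["sample_id"]), gene_list)
        long = matrix.to_long_frame()
        p = outdir / "gene_type_counts.tsv"
        long.to_csv(p, sep="\t", index=False)
        register("collapse", "gene_type_counts", p)

    match_result = None
    if "match" in enabled:
        match_result = matching_mod.match_cohort(
            samples,
            covariates=config.match.covariates,
            ratio=config.match.ratio,
            caliper=config.match.caliper,
            seed=seeds["match"],
        )
        p = outdir / "matches.tsv"
        match_result.pairs.to_csv(p, sep="\t", index=False)
        register("match", "matches", p)
        p = outdir / "balance.tsv"
        match_result.balance.to_csv(p, sep="\t", index=False)
        register("match", "balance", p)

    burden_results = None
    if "burden" in enabled:
        bcfg = dataclasses.replace(config.burden, seed=seeds["burden"])
        if match_result is not None and len(match_result.pairs):
            keep = set(match_result.matched_case_ids) | set(match_result.matched_control_ids)
            keep_mask = [s in keep for s in matrix.samples]
            sub_samples = [s for s, k in zip(matrix.samples, keep_mask) if k]
            sub_counts = {vt: m[:, np.asarray(keep_mask)] for vt, m in matrix.counts.items()}
            from .variants import GeneTypeCountMatrix

            sub_matrix = GeneTypeCountMatrix(matrix.genes, sub_samples, sub_counts)
        else:
            sub_matrix = matrix
        grp = samples.set_index("sample_id")["group"]
        is_case = np.array([grp[s] == "SGA" for s in sub_matrix.samples])
        burden_results = burden_mod.run_burden_analysis(sub_matrix, is_case, bcfg)
        p = outdir / "burden_results.tsv"
        burden_results.to_csv(p, sep="\t", index=False)
        register("burden", "burden_results", p)
        logger.info("burden: %d genes, %d risk tier, %d causative tier",
                    len(burden_results),
                    int((burden_results["tier"] != "none").sum()),
                    int((burden_results["tier"] == "potential_causative").sum()))

    if "stats" in enabled:
        variables = ["severe", "gestational_age", *FLAG_COLUMNS,
                     "maternal_hypertension", "maternal_diabetes"]
        table1 = group_comparison_table(samples, "group", variables)
        p = outdir / "table_one.tsv"
        table1.to_csv(p, sep="\t", index=False)
        register("stats", "table_one", p)
        counts_json = outdir / "table_one.json"
        counts_json.write_text(table1.to_json(orient="records", indent=2))
        register("stats", "table_one_json", counts_json)

    evaluations = None
    if "model" in enabled:
        evaluations = _run_model_stage(config, seeds, samples, matrix, outdir, register)

    if "report" in enabled:
        p = outdir / "report.md"
        p.write_text(_render_report(manifest, burden_results, evaluations))
        register("report", "report", p)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete in %.1fs -> %s", time.time() - t0, outdir)
    return manifest


def _run_model_stage(config, seeds, samples, matrix, outdir, register):
    """Prognosis modelling within the SGA cases: scan poor vs non-poor on the
    training split for risk genes, build features, train and evaluate."""
    mcfg = config.model
    sga = samples[samples["group"] == "SGA"].reset_index(drop=True)
    train, test = prognosis_mod.split_train_test(sga, ratio=mcfg.split_ratio, seed=seeds["model"])

    # risk genes from the training population only: poor vs non-poor scan
    train_ids = list(train["sample_id"])
    idx = [matrix.samples.index(s) for s in train_ids]
    from .variants import GeneTypeCountMatrix

    sub = GeneTypeCountMatrix(
        matrix.genes, train_ids, {vt: m[:, idx] for vt, m in matrix.counts.items()}
    )
    is_poor = train["poor_prognosis"].to_numpy(dtype=bool)
    bcfg = dataclasses.replace(config.burden, seed=seeds["burden"])
    scan = burden_mod.run_burden_analysis(sub, is_poor, bcfg)
    risk_genes = list(scan.loc[scan["tier"] != "none", "gene"])
    logger.info("model: %d risk genes from training scan", len(risk_genes))

    feats = prognosis_mod.burden_features(matrix, risk_genes, mode=mcfg.genetic_feature_mode)
    genetic_cols = list(feats.columns)

    def with_features(df):
        return df.merge(feats, left_on="sample_id", right_index=True, how="left").fillna({c: 0 for c in genetic_cols})

    train_f, test_f = with_features(train), with_features(test)

    # independent validation cohort: fresh SGA-only simulation, same generative model
    validation_f = None
    if mcfg.validation_n > 0:
        vcfg = dataclasses.replace(
            config.simulation,
            n_case=mcfg.validation_n,
            n_control=1,
            seed=seeds["report"] + 1,
        )
        vdata = simulate_cohort(vcfg)
        vsamples = vdata.samples[vdata.samples["group"] == "SGA"].reset_index(drop=True)
        vrare = filter_rare(vdata.variants, config.af_threshold)
        vmatrix = collapse_counts(vrare, list(vdata.samples["sample_id"]), matrix.genes)
        vfeats = prognosis_mod.burden_features(vmatrix, risk_genes, mode=mcfg.genetic_feature_mode)
        validation_f = vsamples.merge(vfeats, left_on="sample_id", right_index=True, how="left")
        if validation_f["poor_prognosis"].nunique() < 2:
            logger.warning("validation cohort has a single outcome class; skipping validation")
            validation_f = None

    clinical = prognosis_mod.select_clinical_factors(train_f, alpha=mcfg.alpha_screen)
    gbm_cfg = prognosis_mod.GbmConfig(
        cv_folds=mcfg.cv_folds, cv_repeats=mcfg.cv_repeats, grid=mcfg.grid, seed=seeds["model"]
    )
    evaluations, _ = prognosis_mod.evaluate_two_models(
        train_f, test_f, validation_f, clinical, genetic_cols, config=gbm_cfg
    )
    payload = {
        "clinical_factors": clinical,
        "risk_genes": risk_genes,
        "evaluations": [dataclasses.asdict(e) for e in evaluations],
    }
    p = outdir / "model_eval.json"
    p.write_text(json.dumps(payload, indent=2))
    register("model", "model_eval", p)
    fpath = outdir / "features.tsv"
    train_f.assign(split="train").pipe(
        lambda d: pd.concat([d, test_f.assign(split="test")], ignore_index=True)
    ).to_csv(fpath, sep="\t", index=False)
    register("model", "features", fpath)
    return evaluations


def _render_report(manifest, burden_results, evaluations) -> str:
    lines = ["# Pipeline report", ""]
    lines.append(f"Global seed: {manifest['seed']}")
    if burden_results is not None:
        causative = burden_results[burden_results["tier"] == "potential_causative"]
        lines += [
            "",
            "## Burden scan",
            f"- genes scanned: {len(burden_results)}",
            f"- background-flagged: {int(burden_results['background_flagged'].sum())}",
            f"- risk tier: {int((burden_results['tier'] != 'none').sum())}",
            f"- potential causative: {len(causative)}"
            + (f" ({', '.join(causative['gene'])})" if len(causative) else ""),
        ]
    if evaluations:
        lines += ["", "## Prognosis models", "",
                  "| model | dataset | AUC | 95% CI | paired p |", "|---|---|---|---|---|"]
        for e in evaluations:
            lines.append(
                f"| {e.model_id} | {e.dataset_id} | {e.auc:.3f} | "
                f"{e.ci_low:.2f}-{e.ci_high:.2f} | {e.paired_p:.3g} |"
            )
    lines += ["", "## Artifacts", ""]
    for name, art in sorted(manifest["artifacts"].items()):
        lines.append(f"- {name}: `{Path(art['path']).name}` sha256 {art['sha256'][:12]}")
    return "\n".join(lines) + "\n"
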