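"""End-to-end orchestration: QC -> burdens -> selection -> models -> reports.

:func:`analyze_task` is the in-memory workhorse: given genotypes,
summary statistics, gene annotation and phenotypes it runs one task
(CNAD or MCI_CP) end to end and returns every fitted model, score
table and diagnostic.  :func:`run_pipeline` wraps it with file I/O, a
config file, and a reproducibility manifest; the CLI is a thin layer
over these two functions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import burden as burden_mod
from . import interpret as interpret_mod
from . import models as models_mod
from . import prs as prs_mod
from . import qc as qc_mod
from . import selection as selection_mod
from . import stratify as stratify_mod
from .io_formats import (
    APOE_REGION,
    GenotypeMatrix,
    parse_region,
    read_gene_annotation,
    read_genotypes,
    read_phenotypes,
    read_summary_stats,
    write_scores,
)
from .models import APOEWeights

__all__ = ["PipelineConfig", "analyze_task", "run_pipeline", "TaskResult"]

_DEFAULT_CONFIG = {
    "paths": {
        "genotypes": None,
        "sumstats": None,
        "annotation": None,
        "phenotypes": None,
        "outdir": "adors_out",
    },
    "simulate": {"enabled": False, "overrides": {}},
    "qc": {
        "enabled": True,
        "max_missing_rate": 0.20,
        "hwe_alpha": 1e-6,
        "gq_min": 20,
        "dp_min": 10,
    },
    "burden": {"missing_policy": "mean", "maf_min": 0.0},
    "selection": {
        "k_per_biomarker": 20,
        "biomarkers": ["fdg_suvr", "av45_suvr"],
        "correlation_scope": "train_only",
        "ranking": "absolute_r",
    },
    "model": {
        "task": "CNAD",
        "label_policy": "text",
        "seed": 0,
        "ridge_strength": 1.0,
        "include_apoe": True,
        "apoe_beta_e2": -0.47,
        "apoe_beta_e4": 1.12,
    },
    "prs": {
        "window_kb": 1000,
        "r2_max": 0.1,
        "primary_threshold": 1e-5,
        "p_thresholds": [5e-8, 1e-5, 0.1, 0.5],
        "apoe_region": "chr19:44000000-46000000",
    },
    "report": {"n_bins": 10},
}


@dataclass
class PipelineConfig:
    """Validated nested pipeline configuration.

    Unknown blocks or keys are rejected so typos fail loudly; every
    omitted key takes its shipped default.
    """

    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {}
        for block, defaults in _DEFAULT_CONFIG.items():
            merged[block] = dict(defaults)
        for block, values in (self.config or {}).items():
            if block not in _DEFAULT_CONFIG:
                raise KeyError(f"unknown config block {block!r}")
            if not isinstance(values, dict):
                raise TypeError(f"config block {block!r} must be a mapping")
            for key, val in values.items():
                if key not in _DEFAULT_CONFIG[block]:
                    raise KeyError(f"unknown key {block}.{key}")
                merged[block][key] = val
        self.config = merged

    def __getitem__(self, block: str) -> dict:
        return self.config[block]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})


@dataclass
class TaskResult:
    """Everything one task run produces."""

    task: str
    gene_set: selection_mod.GeneSet
    burdens: burden_mod.BurdenMatrix
    labels: pd.Series
    train_ids: list[str]
    test_ids: list[str]
    models: dict[str, models_mod.RiskModel]
    reports: dict[str, models_mod.EvalReport]
    scores: pd.DataFrame  # long format: sample, score, model_name, task
    deciles: dict[str, stratify_mod.DecileTable]
    staircase: dict[str, float]
    associations: dict[str, pd.DataFrame]
    contributions: dict[str, interpret_mod.ContributionMatrix]
    contribution_summaries: dict[str, pd.DataFrame]
    qc_report: qc_mod.QCReport | None = None
    prs_model: prs_mod.PRSModel | None = None


def _phenotype_covariates(phenotypes: pd.DataFrame) -> pd.DataFrame:
    sex = phenotypes["sex"]
    if sex.dtype == object:
        sex = sex.map({"female": 0, "male": 1}).astype(float)
    return pd.DataFrame({"age": phenotypes["age"].astype(float), "sex": sex},
                        index=phenotypes.index)


def analyze_task(
    geno: GenotypeMatrix,
    sumstats: pd.DataFrame,
    annotation: pd.DataFrame,
    phenotypes: pd.DataFrame,
    config: PipelineConfig | dict | None = None,
    run_qc: bool | None = None,
    comparators: bool = True,
) -> TaskResult:
    """Run one task end to end on in-memory inputs.

    Steps: (optional) variant QC; allele alignment to the summary
    statistics; label assignment from visit sequences; a stratified
    80:20 split fixed up front (selection correlations and missing-
    dosage imputation are train-scoped); direction-corrected burdens;
    endophenotype-guided gene selection; logistic risk models for
    adORS, adORS+APOE, APOE-only, PRS and PRS+APOE; and the evaluation
    layer (CV and held-out AUROC/AUPRC, deciles, staircase, cognitive
    associations, contribution decompositions).
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig(config or {})
    task = cfg["model"]["task"]
    policy = cfg["model"]["label_policy"]
    seed = int(cfg["model"]["seed"])
    apoe_w = APOEWeights(cfg["model"]["apoe_beta_e2"], cfg["model"]["apoe_beta_e4"])
    apoe_region = parse_region(cfg["prs"]["apoe_region"])

    qc_report = None
    if run_qc if run_qc is not None else cfg["qc"]["enabled"]:
        thresholds = qc_mod.QCThresholds(
            max_missing_rate=cfg["qc"]["max_missing_rate"],
            hwe_alpha=cfg["qc"]["hwe_alpha"],
            gq_min=cfg["qc"]["gq_min"],
            dp_min=cfg["qc"]["dp_min"],
        )
        geno, qc_report = qc_mod.filter_variants(geno, thresholds)

    from .io_formats import align_alleles

    geno, _align_report = align_alleles(geno, sumstats)

    maf_min = float(cfg["burden"]["maf_min"])
    if maf_min > 0:  # optional common-variant filter, off by default
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(geno.dosage, axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        geno = geno.subset_variants(np.flatnonzero(maf >= maf_min))

    # labels and split
    labels_all = phenotypes["visits"].map(
        lambda v: models_mod.assign_labels(v, policy)
    )
    y = models_mod.task_labels(labels_all, task, policy)
    y = y.loc[[s for s in geno.samples if s in y.index]]
    train_ids, test_ids = models_mod.stratified_split(y, seed=seed)

    # gene burdens on non-APOE genes
    ann = annotation[
        ~annotation.apply(
            lambda r: r["chrom"] == apoe_region.chrom
            and r["start"] < apoe_region.end
            and r["end"] > apoe_region.start,
            axis=1,
        )
    ].reset_index(drop=True)
    gene_map, _intergenic = burden_mod.assign_variants_to_genes(geno, ann)
    directions = burden_mod.direction_map(sumstats)
    burdens = burden_mod.compute_burdens(
        geno,
        directions,
        gene_map,
        missing_policy=cfg["burden"]["missing_policy"],
        train_samples=train_ids,
    )

    sel_cfg = selection_mod.SelectionConfig(
        k_per_biomarker=int(cfg["selection"]["k_per_biomarker"]),
        biomarkers=tuple(cfg["selection"]["biomarkers"]),
        correlation_scope=cfg["selection"]["correlation_scope"],
        ranking=cfg["selection"]["ranking"],
    )
    gene_set = selection_mod.select_genes(
        burdens, phenotypes, sel_cfg,
        train_ids=train_ids if sel_cfg.correlation_scope == "train_only" else None,
    )

    covariates = _phenotype_covariates(phenotypes).loc[y.index]
    apoe_scores = phenotypes.loc[y.index, "apoe"].map(
        lambda g: models_mod.apoe_score(g, apoe_w)
    ).rename("apoe")
    burden_df = burdens.to_frame().loc[y.index, gene_set.genes]
    split = (train_ids, test_ids)
    ridge = float(cfg["model"]["ridge_strength"])

    feature_sets = {"adORS": (burden_df, covariates)}
    prs_model = None
    if comparators:
        clump_cfg = prs_mod.ClumpConfig(
            window_kb=int(cfg["prs"]["window_kb"]),
            r2_max=float(cfg["prs"]["r2_max"]),
            p_thresholds=tuple(cfg["prs"]["p_thresholds"]),
            primary_threshold=float(cfg["prs"]["primary_threshold"]),
            apoe_region=apoe_region,
        )
        prs_model = prs_mod.build_prs_model(sumstats, geno, clump_cfg)
        prs_scores = prs_mod.prs_score(
            prs_model, geno, train_samples=train_ids, task=task
        ).set_index("sample")["score"].loc[y.index].rename("prs")
        feature_sets.update(
            {
                "adORS.with.APOE": (
                    burden_df, pd.concat([covariates, apoe_scores], axis=1)
                ),
                "APOE.only": (apoe_scores.to_frame(), covariates),
                "PRS": (prs_scores.to_frame(), covariates),
                "PRS.with.APOE": (
                    pd.concat([prs_scores, apoe_scores], axis=1), covariates
                ),
            }
        )

    models, reports, score_rows = {}, {}, []
    deciles, staircase, associations = {}, {}, {}
    contributions, summaries = {}, {}
    for name, (feats, covs) in feature_sets.items():
        model, report = models_mod.fit_risk_model(
            feats, y, covs, task=task, seed=seed, ridge_strength=ridge, split=split
        )
        models[name] = model
        reports[name] = report
        st = models_mod.adors_score(model, feats, covariates=covs, model_name=name)
        score_rows.append(st)
        test_scores = st.set_index("sample").loc[test_ids]
        dt = stratify_mod.decile_table(
            test_scores["score"].to_numpy(),
            y.loc[test_ids].to_numpy(),
            sample_ids=test_ids,
            n_bins=int(cfg["report"]["n_bins"]),
        )
        deciles[name] = dt
        staircase[name] = stratify_mod.staircase_statistic(dt)
        associations[name] = models_mod.phenotype_association(
            st.set_index("sample")["score"], phenotypes
        )
        feats_cov = pd.concat([feats, covs], axis=1)
        contrib = interpret_mod.shap_additive(model, feats_cov)
        contributions[name] = contrib
        summaries[name] = interpret_mod.summarize_contributions(contrib)
    if prs_model is not None:
        contributions["PRS.by_gene"] = interpret_mod.prs_gene_contribution(
            prs_model, geno, gene_map, train_samples=train_ids
        )

    scores = pd.concat(score_rows, ignore_index=True)
    return TaskResult(
        task=task,
        gene_set=gene_set,
        burdens=burdens,
        labels=y,
        train_ids=train_ids,
        test_ids=test_ids,
        models=models,
        reports=reports,
        scores=scores,
        deciles=deciles,
        staircase=staircase,
        associations=associations,
        contributions=contributions,
        contribution_summaries=summaries,
        qc_report=qc_report,
        prs_model=prs_model,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | dict, outdir=None) -> Path:
    """File-level pipeline: read (or simulate) inputs, analyze, write reports.

    Writes scores.tsv, gene_set.tsv, eval.json, decile tables,
    association and contribution TSVs, the QC report, an echo of the
    config, and manifest.json recording input hashes, seed and
    version.  Identical config and inputs reproduce identical outputs.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig(config)
    out = Path(outdir or cfg["paths"]["outdir"])
    out.mkdir(parents=True, exist_ok=True)

    if cfg["simulate"]["enabled"]:
        from .synthetic import SimConfig, export_fixture, simulate_cohort

        sim = simulate_cohort(SimConfig(**cfg["simulate"]["overrides"]))
        fixture_dir = out / "inputs"
        paths = export_fixture(sim, fixture_dir)
        geno = read_genotypes(paths["genotypes"])
        sumstats = read_summary_stats(paths["sumstats"])
        annotation = read_gene_annotation(paths["annotation"])
        phenotypes = read_phenotypes(paths["phenotypes"])
        input_paths = {k: Path(v) for k, v in paths.items() if k != "truth"}
    else:
        p = cfg["paths"]
        for key in ("genotypes", "sumstats", "annotation", "phenotypes"):
            if not p[key]:
                raise ValueError(f"paths.{key} is required when simulate is disabled")
        geno = read_genotypes(p["genotypes"])
        sumstats = read_summary_stats(p["sumstats"])
        annotation = read_gene_annotation(p["annotation"])
        phenotypes = read_phenotypes(p["phenotypes"])
        input_paths = {
            k: Path(p[k]) for k in ("genotypes", "sumstats", "annotation", "phenotypes")
        }

    result = analyze_task(geno, sumstats, annotation, phenotypes, cfg)

    write_scores(result.scores, out / "scores.tsv")
    result.gene_set.per_biomarker.to_csv(out / "gene_set.tsv", sep="\t", index=False)
    result.burdens.to_frame().to_csv(out / "burdens.tsv", sep="\t")
    eval_payload = {
        name: report.to_dict() for name, report in result.reports.items()
    }
    eval_payload["staircase"] = result.staircase
    with open(out / "eval.json", "w") as fh:
        json.dump(eval_payload, fh, indent=1, sort_keys=True)
    for name, dt in result.deciles.items():
        dt.to_frame().to_csv(out / f"deciles_{name}.tsv", sep="\t", index=False)
    assoc = pd.concat(
        [df.assign(model_name=name) for name, df in result.associations.items()],
        ignore_index=True,
    )
    assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
    for name, summary in result.contribution_summaries.items():
        summary.to_csv(out / f"contributions_{name}.tsv", sep="\t", index=False)
    interpret_mod.contributions_long_format(
        result.contributions["adORS"]
    ).to_csv(out / "contributions_adORS_long.tsv", sep="\t", index=False)
    if result.qc_report is not None:
        result.qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        result.qc_report.per_variant.to_csv(
            out / "qc_per_variant.tsv", sep="\t", index=False
        )
    if result.prs_model is not None:
        result.prs_model.variants.to_csv(out / "prs_variants.tsv", sep="\t", index=False)

    manifest = {
        "version": _package_version(),
        "seed": int(cfg["model"]["seed"]),
        "task": cfg["model"]["task"],
        "config": cfg.config,
        "input_sha256": {k: _sha256(v) for k, v in sorted(input_paths.items())},
        "outputs": sorted(f.name for f in out.iterdir() if f.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    with open(out / "config_echo.json", "w") as fh:
        json.dump(cfg.config, fh, indent=1, sort_keys=True, default=str)
    return out


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("adors")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"
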