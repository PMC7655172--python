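"""End-to-end study-mimic workflow on simulated data.

``run_paper_mimic`` chains every stage — simulate a shared-panel study,
fit one clock per tissue, validate, predict epigenetic ages in the
two-strain experiment cohort, summarize age acceleration, run the per-CpG
ANOVA with threshold selection, and annotate the selected loci against a
synthetic genome annotation. Every intermediate table is written as TSV
and a manifest records the configuration and derived per-stage seeds so
any output is re-derivable from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .acceleration import (DEFAULT_LIFESPANS, acceleration_report,
                           build_delta_age_table, per_timepoint_comparison)
from .annotation import (build_regulatory_domains, derive_promoters,
                         derive_shores, feature_distribution)
from .association import (cluster_cpgs_by_gene, hierarchical_clustering,
                          pca_scores, per_cpg_anova, select_cpgs)
from .clock import AgeTransform, FitConfig, evaluate_clock, fit_clock, predict_dnage
from .io import drop_missing_cpgs, save_clock, write_methylation_matrix
from .simulate import (CohortDesign, CpGArchetypeSpec, simulate_annotation,
                       simulate_study)

log = logging.getLogger("tissueclock")

DEFAULT_THRESHOLDS = {"alpha_age": 1e-4, "alpha_strain": 1e-5, "alpha_interaction": 1e-5}


@dataclass
class PipelineConfig:
    """All knobs of the study-mimic run (one seed, split per stage)."""

    outdir: str = "tissueclock_run"
    seed: int = 0
    design: CohortDesign = field(default_factory=CohortDesign)
    spec: CpGArchetypeSpec = field(default_factory=CpGArchetypeSpec)
    fit: FitConfig = field(default_factory=FitConfig)
    transform: AgeTransform = field(default_factory=AgeTransform)
    lifespans: dict = field(default_factory=lambda: dict(DEFAULT_LIFESPANS))
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    n_train: int = 4
    n_validation: int = 4

    def __post_init__(self):
        for k, v in self.thresholds.items():
            if not 0 < v < 1:
                raise ValueError(f"threshold {k} must lie in (0,1), got {v}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        kwargs = {}
        for key, typ in (("design", CohortDesign), ("spec", CpGArchetypeSpec),
                         ("fit", FitConfig), ("transform", AgeTransform)):
            if key in raw:
                sub = raw.pop(key)
                for f in ("tissues", "strains", "ages_months"):
                    if isinstance(sub.get(f), list):
                        sub[f] = tuple(sub[f])
                for f in ("age_slope_range", "tissue_offset_range",
                          "strain_offset_range", "interaction_slope_range", "base_range"):
                    if isinstance(sub.get(f), list):
                        sub[f] = tuple(sub[f])
                kwargs[key] = typ(**sub)
        kwargs.update(raw)
        return cls(**kwargs)


def split_seed(seed: int, n: int) -> list[int]:
    """Derive n independent sub-seeds (< 2^31) from one master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_paper_mimic(config: PipelineConfig) -> dict:
    """Run the full simulated-study workflow; returns the summary report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(("simulate", "fit", "annotation"), split_seed(config.seed, 3)))
    report: dict = {"stages": {}, "warnings": {}}
    t0 = time.time()

    def stage(name):
        log.info("stage %s starting (elapsed %.1fs)", name, time.time() - t0)
        return time.time()

    # --- simulate -----------------------------------------------------------
    ts = stage("simulate")
    study = simulate_study(design=config.design, spec=config.spec,
                           n_train=config.n_train, n_validation=config.n_validation,
                           seed=seeds["simulate"], transform=config.transform)
    write_methylation_matrix(study.experiment, out / "experiment_matrix.tsv",
                             out / "experiment_samples.tsv")
    study.truth.table.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    report["stages"]["simulate"] = {
        "n_loci": study.experiment.shape[0],
        "n_samples": study.experiment.shape[1],
        "elapsed_s": round(time.time() - ts, 2),
    }

    # --- fit / validate / predict per tissue --------------------------------
    ts = stage("fit")
    fit_cfg = FitConfig(mixing=config.fit.mixing, lambda_grid=config.fit.lambda_grid,
                        cv_folds=config.fit.cv_folds, standardize=config.fit.standardize,
                        seed=seeds["fit"])
    models, delta_tables = {}, []
    for tissue in config.design.tissues:
        model = fit_clock(study.training[tissue], tissue, config.transform, fit_cfg)
        save_clock(model, out / f"clock_{tissue}.json")
        models[tissue] = model
        val = evaluate_clock(model, study.validation[tissue])
        report["stages"].setdefault("clocks", {})[tissue] = {
            "n_cpgs": len(model.coefficients),
            "training_r": model.training_info["pearson_r"],
            "validation_r2": val["r_squared"],
            "validation_mae_months": val["mae_months"],
        }
        warn_counter: dict = {}
        sub = study.experiment.restrict_tissue(tissue)
        table = build_delta_age_table(model, sub)
        delta_tables.append(table)
        if warn_counter:
            report["warnings"][f"imputed_{tissue}"] = warn_counter
    import pandas as pd

    delta = pd.concat(delta_tables, ignore_index=True)
    delta.to_csv(out / "delta_age.tsv", sep="\t", index=False)
    report["stages"]["fit_predict_elapsed_s"] = round(time.time() - ts, 2)

    # --- acceleration -------------------------------------------------------
    ts = stage("accelerate")
    accel = acceleration_report(delta, config.lifespans)
    for tissue in config.design.tissues:
        accel.setdefault("per_timepoint", {})[tissue] = per_timepoint_comparison(
            delta, tissue
        ).to_dict(orient="records")
    report["stages"]["acceleration"] = accel
    report["stages"]["acceleration"]["elapsed_s"] = round(time.time() - ts, 2)

    # --- ANOVA + selection --------------------------------------------------
    ts = stage("anova")
    complete = drop_missing_cpgs(study.experiment)
    anova = per_cpg_anova(complete)
    anova.to_csv(out / "anova.tsv", sep="\t", index=False)
    sel = {
        "age": select_cpgs(anova, "age", config.thresholds["alpha_age"]),
        "strain": select_cpgs(anova, "strain", config.thresholds["alpha_strain"]),
        "strain_age": select_cpgs(anova, "strain:age",
                                  config.thresholds["alpha_interaction"]),
    }
    for term, ids in sel.items():
        (out / f"selected_{term}.txt").write_text("\n".join(ids) + "\n")
    scores, evr = pca_scores(complete, n_components=3)
    scores.to_csv(out / "pca_scores.tsv", sep="\t")
    hierarchical_clustering(complete, axis="samples")
    report["stages"]["association"] = {
        "n_complete_loci": complete.shape[0],
        "n_selected": {k: len(v) for k, v in sel.items()},
        "pca_explained_variance": [float(x) for x in evr],
        "elapsed_s": round(time.time() - ts, 2),
    }

    # --- annotation ---------------------------------------------------------
    ts = stage("annotate")
    islands, genes, chrom_sizes = simulate_annotation(
        study.experiment.loci, seed=seeds["annotation"]
    )
    ann = islands.concat(derive_shores(islands, chrom_sizes))
    ann = ann.concat(derive_promoters(genes, chrom_sizes))
    by_id = {l.id: l for l in study.experiment.loci}
    sel_loci = [by_id[i] for i in sel["age"]]
    dist = feature_distribution(sel_loci, ann)
    dist.to_csv(out / "feature_distribution.tsv", sep="\t", index=False)
    domains = build_regulatory_domains(genes, chrom_sizes)
    gene_counts = cluster_cpgs_by_gene([by_id[i] for i in sel["strain_age"]], domains)
    report["stages"]["annotation"] = {
        "feature_distribution": dict(zip(dist["feature_class"], dist["count"].astype(int)))
        if len(dist) else {},
        "genes_hit_by_interaction_cpgs": len(gene_counts),
        "elapsed_s": round(time.time() - ts, 2),
    }

    # --- manifest + report --------------------------------------------------
    manifest = {
        "tissueclock_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": {
            "design": asdict(config.design), "spec": asdict(config.spec),
            "fit": {**asdict(config.fit), "seed": config.fit.seed},
            "transform": config.transform.to_dict(),
            "lifespans": config.lifespans, "thresholds": config.thresholds,
            "n_train": config.n_train, "n_validation": config.n_validation,
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=list) + "\n")
    (out / "report.json").write_text(json.dumps(report, indent=1) + "\n")
    return report
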