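"""End-to-end orchestration of the analysis stages from a single config.

Stage order mirrors the analytic framework: donor QC -> median expression
matrix -> components (+ hemisphere scaling) -> region-subset congruence CV
-> per-cohort latent-g models and factor scores -> per-region standardized
betas -> random-effects meta-analysis (+ age moderation) -> spatial
associations -> component-controlled gene and cell-type scans.  In
synthetic mode everything is generated from the seed; each run writes its
artifacts plus a manifest JSON listing every file with a content hash and
the config echoed verbatim.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .components import fit_components, loading_threshold_sets, scale_scores_by_hemisphere
from .congruence import congruence_matrix, region_subset_cv
from .expression_qc import apply_filter, donor_consistency_filter, median_regional_expression
from .gene_specific import (celltype_loading_tests, celltype_profile_regression,
                            cross_measure_intersection, gene_association_scan,
                            hemisphere_scale_genes)
from .latent_g import factor_scores, fit_indices, fit_one_factor, residualize_tests
from .meta_mapping import (MEASURES, meta_effect_map, moderator_meta_regression,
                           standardized_beta)
from .spatial_assoc import (absolute_component_association, interhemispheric_correlation,
                            map_correlation, mean_map_controls,
                            quadratic_component_association)
from .synthetic import (COHORT_AGE_MEAN, SyntheticConfig, generate_celltype_map,
                        generate_cohort, generate_expression_atlas)

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "components", "congruence", "gmodel",
          "assoc", "meta", "spatial", "genes", "celltypes")


@dataclass
class PipelineConfig:
    out_dir: str = "cortexg_run"
    seed: int = 0
    k_components: int = 2
    consistency_threshold: float = 0.446
    loading_cut: float = 0.3
    outlier_sd: float = 4.0
    fdr_alpha: float = 0.05
    cv_repeats: int = 50
    cv_folds: int = 5
    meta_method: str = "reml"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    synthetic: dict = field(default_factory=dict)   # SyntheticConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k != "stages"})
        if "stages" in raw:
            cfg.stages.update(raw["stages"])
        return cfg

    def validate(self) -> None:
        if not -1 < self.consistency_threshold < 1:
            raise ValueError("consistency_threshold must be in (-1, 1)")
        if not 0 <= self.loading_cut < 1:
            raise ValueError("loading_cut must be in [0, 1)")
        if self.outlier_sd <= 0 or not 0 < self.fdr_alpha < 1:
            raise ValueError("outlier_sd must be > 0 and fdr_alpha in (0, 1)")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


class StageSkipped(RuntimeError):
    """Raised when a stage's required upstream output is toggled off."""


def _require(artifacts: dict, key: str, stage: str, needed_by: str):
    if key not in artifacts:
        raise StageSkipped(
            f"stage {needed_by!r} requires output {key!r} from stage "
            f"{stage!r}, which is toggled off"
        )
    return artifacts[key]


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages on synthetic data; return the output manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    art: dict = {}
    manifest: dict = {"config": dataclasses.asdict(config), "files": {}, "stages": {}}

    def record(name: str, path: Path, rows: int) -> None:
        manifest["files"][name] = {"path": str(path), "sha256": cio.sha256_of(path),
                                   "rows": rows}

    def stage_on(name: str) -> bool:
        return config.stages.get(name, True)

    t_all = time.time()

    if stage_on("simulate"):
        t0 = time.time()
        scfg = SyntheticConfig(**{"seed": seed, **config.synthetic})
        profiles, summary, truth = generate_expression_atlas(scfg)
        cohorts = {i: generate_cohort(scfg, truth, i) for i in range(scfg.n_cohorts)}
        celltypes = generate_celltype_map(scfg, truth)
        art.update(profiles=profiles, summary=summary, truth=truth,
                   cohorts=cohorts, celltypes=celltypes, scfg=scfg)
        p = out / "donor_profiles.tsv"
        cio.write_donor_profiles(profiles, p)
        record("donor_profiles", p, len(profiles.table))
        p = out / "expression_matrix.tsv"
        cio.write_expression_matrix(summary, p)
        record("expression_matrix", p, summary.shape[0])
        for i, tab in cohorts.items():
            p = out / f"cohort_{i}.csv"
            tab.to_csv(p)
            record(f"cohort_{i}", p, len(tab))
        p = out / "celltype_map.tsv"
        celltypes.rename_axis("gene").to_frame().to_csv(p, sep="\t")
        record("celltype_map", p, len(celltypes))
        p = out / "ground_truth.json"
        cio.write_json({
            "specific_gene_ids": truth.specific_gene_ids,
            "inconsistent_gene_ids": truth.inconsistent_gene_ids,
            "planted_beta_maps": truth.planted_beta_maps,
            "planted_scores": truth.planted_scores,
        }, p)
        record("ground_truth", p, len(truth.planted_scores))
        log.info("stage simulate: %.2fs", time.time() - t0)
        log.info("simulate: %d donors, %d regions x %d genes",
                 scfg.n_donors, *summary.shape)

    if stage_on("qc"):
        t0 = time.time()
        profiles = _require(art, "profiles", "simulate", "qc")
        report = donor_consistency_filter(profiles, config.consistency_threshold)
        summary = _require(art, "summary", "simulate", "qc")
        filtered = apply_filter(summary, report)
        art.update(qc_report=report, expression=filtered)
        p = out / "consistency_report.tsv"
        report.per_gene.to_csv(p, sep="\t")
        record("consistency_report", p, len(report.per_gene))
        p = out / "expression_filtered.tsv"
        cio.write_expression_matrix(filtered, p)
        record("expression_filtered", p, filtered.shape[0])
        manifest["stages"]["qc"] = {
            "genes_in": summary.shape[1], "genes_retained": filtered.shape[1],
        }
        log.info("qc: %.2fs", time.time() - t0)
        log.info("qc: retained %d / %d genes", filtered.shape[1], summary.shape[1])

    if stage_on("components"):
        t0 = time.time()
        X = _require(art, "expression", "qc", "components")
        sol = fit_components(X, k=config.k_components, rotate=True)
        sol = scale_scores_by_hemisphere(sol)
        sets = loading_threshold_sets(sol, config.loading_cut)
        art.update(solution=sol, loading_sets=sets)
        p = out / "loadings.tsv"
        cio.write_loadings(sol.loadings, p)
        record("loadings", p, sol.loadings.shape[0])
        p = out / "scores.tsv"
        cio.write_scores(sol.scores, p)
        record("scores", p, sol.scores.shape[0])
        p = out / "variance.json"
        cio.write_json({
            "unrotated": sol.variance_explained_unrotated,
            "rotated": sol.variance_explained_rotated,
            "loading_set_counts": {
                **{c: {"n_below": v["n_below"], "n_above": v["n_above"]}
                   for c, v in sets["per_component"].items()},
                **sets.get("partition_counts", {}),
            },
        }, p)
        record("variance", p, config.k_components)
        log.info("stage components: %.2fs", time.time() - t0)

    if stage_on("congruence"):
        t0 = time.time()
        X = _require(art, "expression", "qc", "congruence")
        cv = region_subset_cv(X, k=config.k_components, n_repeats=config.cv_repeats,
                              n_folds=config.cv_folds, seed=seed + 11)
        art["cv"] = cv
        p = out / "cv_congruence.tsv"
        cv.records.to_csv(p, sep="\t", index=False)
        record("cv_congruence", p, len(cv.records))
        p = out / "cv_summary.json"
        cio.write_json(cv.summary, p)
        record("cv_summary", p, len(cv.summary))
        log.info("stage congruence: %.2fs", time.time() - t0)

    if stage_on("gmodel"):
        t0 = time.time()
        cohorts = _require(art, "cohorts", "simulate", "gmodel")
        g_scores, gmodels = {}, {}
        for i, tab in cohorts.items():
            tests = [c for c in tab.columns if c.startswith("test")]
            resid = residualize_tests(tab, tests)
            model = fit_one_factor(resid, tests, seed=seed + 23)
            gmodels[i] = model
            g_scores[i] = factor_scores(model, resid)
            p = out / f"gmodel_{i}.json"
            cio.write_json({"lambda": model.lam, "residual_variances":
                            pd.Series(np.diag(model.psi), index=model.tests),
                            "fit": fit_indices(model), "converged": model.converged},
                           p)
            record(f"gmodel_{i}", p, len(tests))
            p = out / f"g_scores_{i}.csv"
            g_scores[i].to_csv(p)
            record(f"g_scores_{i}", p, len(g_scores[i]))
        art.update(g_scores=g_scores, gmodels=gmodels)
        log.info("stage gmodel: %.2fs", time.time() - t0)

    if stage_on("assoc"):
        t0 = time.time()
        cohorts = _require(art, "cohorts", "simulate", "assoc")
        g_scores = _require(art, "g_scores", "gmodel", "assoc")
        estimates = []
        for i, tab in cohorts.items():
            covars = _cohort_covariates(tab)
            g = g_scores[i]
            for col in tab.columns:
                if "__" not in col:
                    continue
                region, measure = col.split("__")
                estimates.append(standardized_beta(
                    g.to_numpy(), tab[col].to_numpy(), covars, region=region,
                    measure_name=measure, cohort=f"cohort{i}",
                    sd_cut=config.outlier_sd))
        art["estimates"] = estimates
        df = pd.DataFrame([e.__dict__ for e in estimates]).drop(columns="flags")
        p = out / "effect_estimates.tsv"
        df.to_csv(p, sep="\t", index=False)
        record("effect_estimates", p, len(df))
        log.info("stage assoc: %.2fs", time.time() - t0)

    if stage_on("meta"):
        t0 = time.time()
        estimates = _require(art, "estimates", "assoc", "meta")
        pooled = meta_effect_map(estimates, method=config.meta_method)
        art["meta_map"] = pooled
        p = out / "meta_effect_map.tsv"
        pooled.to_csv(p, sep="\t", index=False)
        record("meta_effect_map", p, len(pooled))
        # mean-age moderation across cohorts, BH-FDR over all rows
        df = pd.DataFrame([e.__dict__ for e in estimates])
        ages = {f"cohort{i}": COHORT_AGE_MEAN[i % len(COHORT_AGE_MEAN)]
                for i in range(len(_require(art, "cohorts", "simulate", "meta")))}
        mod_rows = []
        for (region, measure), grp in df.groupby(["region", "measure"]):
            res = moderator_meta_regression(
                grp["beta"], grp["se"], [ages[c] for c in grp["cohort"]],
                method=config.meta_method)
            mod_rows.append({"region": region, "measure": measure, **res})
        mod = pd.DataFrame(mod_rows)
        if mod["testable"].any():
            from .gene_specific import bh_fdr
            mod.loc[mod.testable, "q"] = bh_fdr(mod.loc[mod.testable, "p"])
        art["age_moderation"] = mod
        p = out / "age_moderation.tsv"
        mod.to_csv(p, sep="\t", index=False)
        record("age_moderation", p, len(mod))
        log.info("stage meta: %.2fs", time.time() - t0)

    if stage_on("spatial"):
        t0 = time.time()
        pooled = _require(art, "meta_map", "meta", "spatial")
        sol = _require(art, "solution", "components", "spatial")
        X = _require(art, "expression", "qc", "spatial")
        beta_maps = pooled.pivot(index="region", columns="measure", values="beta")
        results: dict = {"absolute": {}, "quadratic": {}, "interhemispheric": {}}
        for m in beta_maps.columns:
            results["interhemispheric"][m] = interhemispheric_correlation(beta_maps[m])
            for c in sol.scores.columns:
                results["absolute"][f"{c}_vs_{m}"] = absolute_component_association(
                    sol.scores[c], beta_maps[m])
                results["quadratic"][f"{c}_vs_{m}"] = quadratic_component_association(
                    sol.scores[c], beta_maps[m])
        results["mean_controls"] = mean_map_controls(X, beta_maps)
        art["spatial"] = results
        p = out / "spatial_assoc.json"
        cio.write_json({sec: {k: v.__dict__ if hasattr(v, "__dict__") else v
                              for k, v in vals.items()}
                        for sec, vals in results.items() if isinstance(vals, dict)}, p)
        record("spatial_assoc", p, len(beta_maps))
        log.info("stage spatial: %.2fs", time.time() - t0)

    if stage_on("genes"):
        t0 = time.time()
        X = _require(art, "expression", "qc", "genes")
        sol = _require(art, "solution", "components", "genes")
        pooled = _require(art, "meta_map", "meta", "genes")
        beta_maps = pooled.pivot(index="region", columns="measure", values="beta")
        scaled = hemisphere_scale_genes(X)
        tables = gene_association_scan(scaled, beta_maps, sol.scores,
                                       alpha=config.fdr_alpha)
        inter = cross_measure_intersection(tables)
        art.update(gene_tables=tables, gene_intersection=inter, scaled_expression=scaled)
        for m, t in tables.items():
            p = out / f"gene_assoc_{m}.tsv"
            t.table.to_csv(p, sep="\t")
            record(f"gene_assoc_{m}", p, len(t.table))
        p = out / "gene_intersection.json"
        cio.write_json({"per_measure_counts": inter["per_measure_counts"],
                        "n_all_measures": inter["n_all_measures"],
                        "all_measures": inter["all_measures"]}, p)
        record("gene_intersection", p, inter["n_all_measures"])
        log.info("stage genes: %.2fs", time.time() - t0)

    if stage_on("celltypes"):
        t0 = time.time()
        X = _require(art, "expression", "qc", "celltypes")
        sol = _require(art, "solution", "components", "celltypes")
        pooled = _require(art, "meta_map", "meta", "celltypes")
        celltypes = _require(art, "celltypes", "simulate", "celltypes")
        beta_maps = pooled.pivot(index="region", columns="measure", values="beta")
        prof = celltype_profile_regression(celltypes, X, beta_maps, sol.scores,
                                           alpha=config.fdr_alpha)
        load_tests = {c: celltype_loading_tests(sol.loadings[c], celltypes)
                      for c in sol.loadings.columns}
        art.update(celltype_profiles=prof, celltype_loadings=load_tests)
        p = out / "celltype_profile_assoc.tsv"
        prof.to_csv(p, sep="\t", index=False)
        record("celltype_profile_assoc", p, len(prof))
        p = out / "celltype_loading_tests.json"
        cio.write_json({c: {"H": r["H"], "df": r["df"], "p": r["p"],
                            "descriptives": r["descriptives"],
                            "dunn": r["dunn"]}
                        for c, r in load_tests.items()}, p)
        record("celltype_loading_tests", p, len(load_tests))
        log.info("stage celltypes: %.2fs", time.time() - t0)

    log.info("pipeline total: %.2fs", time.time() - t_all)
    cio.write_json(manifest, out / "manifest.json")
    art["manifest"] = manifest
    return manifest


def _cohort_covariates(tab: pd.DataFrame) -> pd.DataFrame:
    cols = ["age", "sex", "head_x", "head_y", "head_z"]
    covars = tab[cols].copy()
    if tab["site"].nunique() > 1:
        covars["site"] = tab["site"]
    if tab["lag"].std() > 0:
        covars["lag"] = tab["lag"]
    return covars
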