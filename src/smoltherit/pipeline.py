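"""End-to-end orchestration: QC -> GRMs -> GREML -> liability -> GBLUP ->
correlations -> SNP scan, with per-stage TSV outputs and a run manifest."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gblup as gblup_mod
from . import grm as grm_mod
from .datatypes import CohortTable, GenotypeMatrix
from .greml import MixedModelSpec, fit_greml, liability_transform
from .io import apply_marker_qc, read_genotypes, read_phenotypes
from .snp_tests import genomewide_scan

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genotypes: str = ""
    phenotypes: str = ""
    dialect: str = "tsv"
    max_missing: float = 0.20
    min_maf: float = 0.05
    reml_tol: float = 1e-8
    reml_max_iter: int = 5000
    optimizer: str = "em"
    alpha: float = 0.05
    bonferroni_mode: str = "3m"
    out_dir: str = "smoltherit_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class StageTimer:
    manifest: dict
    name: str
    t0: float = field(default=0.0)

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        self.manifest.setdefault("stages", {})[self.name] = {
            "seconds": round(dt, 3),
            "status": "error" if exc_type else "ok",
        }
        logger.info("stage %s: %s (%.2fs)", self.name,
                    "error" if exc_type else "done", dt)
        return False


def run_pipeline(config: PipelineConfig,
                 genotypes: GenotypeMatrix | None = None,
                 cohort: CohortTable | None = None) -> dict:
    """Run every analysis stage, writing one TSV per stage plus a manifest.

    Inputs may be passed in memory (``genotypes``/``cohort``) or read from
    the paths in ``config``. Returns the manifest dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config)}

    if genotypes is None:
        genotypes = read_genotypes(config.genotypes, config.dialect)
    if cohort is None:
        cohort = read_phenotypes(config.phenotypes)
    cohort = cohort.aligned_to(genotypes)
    pops = cohort.populations

    with StageTimer(manifest, "qc"):
        g_qc, report = apply_marker_qc(genotypes, config.max_missing, config.min_maf)
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        manifest["qc"] = {"markers_in": genotypes.n_markers,
                          "markers_out": g_qc.n_markers,
                          "removed_missingness": int((~report.pass_missingness).sum()),
                          "removed_maf": int((report.pass_missingness & ~report.pass_maf).sum())}
        logger.info("QC: %d -> %d markers", genotypes.n_markers, g_qc.n_markers)

    with StageTimer(manifest, "grm"):
        joint = grm_mod.build_grms(g_qc)
        grm_mod.write_grm_text(joint.individual_ids, joint.A, joint.n_markers,
                               str(out / "grm_additive"))
        grm_mod.write_grm_text(joint.individual_ids, joint.D, joint.n_markers,
                               str(out / "grm_dominance"))

    reml_rows, liability_rows, gblup_frames = [], [], []
    for pop in pops:
        pop_ids = [i for i, p in zip(cohort.ids, cohort.table["population"]) if p == pop]
        g_pop = g_qc.subset_individuals(pop_ids)
        # re-screen for markers monomorphic within this population
        keep = ~np.isin(np.nanmean(g_pop.codes, axis=0) / 2.0, (0.0, 1.0))
        g_pop = g_pop.subset_markers(keep)
        sub_cohort = CohortTable(cohort.table[cohort.table["id"].isin(pop_ids)])
        grm_pop = grm_mod.build_grms(g_pop)
        prevalence = float(sub_cohort.smolt01().mean())
        for label, include_dom in (("additive_only", False), ("additive_dominance", True)):
            with StageTimer(manifest, f"greml_{pop}_{label}"):
                spec = MixedModelSpec.from_cohort(grm_pop, sub_cohort,
                                                  include_dominance=include_dom)
                est = fit_greml(spec, max_iter=config.reml_max_iter,
                                tol=config.reml_tol, optimizer=config.optimizer,
                                cross_check=False)
                reml_rows.append({
                    "population": pop, "model": label,
                    "sigma2_a": est.sigma2_a, "sigma2_d": est.sigma2_d,
                    "sigma2_e": est.sigma2_e,
                    "h2_a": round(est.h2_a, 3), "h2_d": round(est.h2_d, 3),
                    "H2": round(est.H2, 3),
                    "loglik": est.loglik, "n_iter": est.n_iter,
                    "converged": est.converged,
                })
                logger.info("GREML %s/%s: h2_a=%.3f h2_d=%.3f (%d iterations)",
                            pop, label, est.h2_a, est.h2_d, est.n_iter)
                if not include_dom:
                    liability_rows.append({
                        "population": pop, "prevalence": prevalence,
                        "h2_observed": est.h2_a,
                        "h2_liability": liability_transform(est.h2_a, prevalence),
                    })
                else:
                    with StageTimer(manifest, f"gblup_{pop}"):
                        preds = gblup_mod.predict(spec, est, grm_pop.individual_ids,
                                                  sub_cohort)
                        gblup_frames.append(preds.to_frame())

    pd.DataFrame(reml_rows).to_csv(out / "variance_components.tsv", sep="\t", index=False)
    pd.DataFrame(liability_rows).to_csv(out / "liability.tsv", sep="\t", index=False)
    pd.concat(gblup_frames).to_csv(out / "gblup.tsv", sep="\t", index=False)

    with StageTimer(manifest, "correlations"):
        corr_rows = []
        for which in ("additive", "dominance"):
            ids, C = grm_mod.genomic_correlations(joint, which, drop_degenerate=True)
            summaries, tests = grm_mod.summarize_correlations(ids, C, cohort,
                                                              seed=config.seed)
            for s in summaries:
                corr_rows.append({"which": which, "group": s.group,
                                  "n_pairs": s.n_pairs, "mean": s.mean, "se": s.se})
            tests.insert(0, "which", which)
            mode = "w" if which == "additive" else "a"
            tests.to_csv(out / "correlation_tests.tsv", sep="\t", index=False,
                         mode=mode, header=(mode == "w"))
        pd.DataFrame(corr_rows).to_csv(out / "correlations.tsv", sep="\t", index=False)

    with StageTimer(manifest, "snp_scan"):
        scan_frames = []
        for pop in pops:
            pop_ids = [i for i, p in zip(cohort.ids, cohort.table["population"]) if p == pop]
            sub = CohortTable(cohort.table[cohort.table["id"].isin(pop_ids)])
            records, threshold = genomewide_scan(
                g_qc.subset_individuals(pop_ids), sub,
                alpha=config.alpha, bonferroni_mode=config.bonferroni_mode)
            records.insert(0, "population", pop)
            scan_frames.append(records)
        pd.concat(scan_frames).to_csv(out / "snp_tests.tsv", sep="\t", index=False)
        manifest["snp_scan"] = {"threshold": threshold}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
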