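"""End-to-end pipeline: simulate/read -> QC -> REML -> WssGWAS -> scan -> genes.

Every stage writes a plain TSV/CSV artifact into the output directory and
the run closes with a JSON manifest (config hash, seed, package versions,
stage list) sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import genes_in_regions, overlap_with_deg, read_bed, read_deg_table, read_gff3
from .config import RunConfig
from .design import ModelSpec
from .genotypes import GenotypeMatrix
from .gwas import significant_regions
from .model import SingleStepRepeatabilityModel
from .pedigree import Pedigree
from .qc import run_qc
from .simulate import simulate_dataset

logger = logging.getLogger("wssgwas")

__all__ = ["run_pipeline"]


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by ``config``; returns the manifest."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def stage(name):
        logger.info("stage %s", name)
        stages.append({"stage": name, "t": round(time.time() - t0, 3)})

    # ------------------------------------------------ inputs
    if config.simulate is not None:
        stage("simulate")
        sim_cfg = config.simulate.model_copy(update={"rng_seed": config.rng_seed})
        data = simulate_dataset(sim_cfg)
        ped = data.pedigree
        records = data.phenotypes.records
        geno_raw = data.observed_genotypes
        ped.to_csv(out / "pedigree.csv")
        records.to_csv(out / "phenotypes.csv", index=False)
        geno_raw.to_plink(str(out / "genotypes"))
        geno_raw.to_tsv(out / "genotypes.tsv", out / "marker_map.tsv")
        data.phenotypes.qtl.to_csv(out / "true_qtl.tsv", sep="\t", index=False)
    else:
        stage("read")
        ped = Pedigree.from_csv(config.pedigree_path)
        records = pd.read_csv(config.phenotype_path)
        geno_raw = GenotypeMatrix.from_plink(config.genotype_prefix)

    # ------------------------------------------------ QC
    stage("qc")
    geno, report = run_qc(geno_raw, config.qc)
    report.to_tsv(out / "qc_report.tsv")
    for s in report.steps:
        logger.info(
            "qc %s: %d -> %d individuals, %d -> %d SNPs",
            s["step"], s["n_individuals_before"], s["n_individuals_after"],
            s["n_snps_before"], s["n_snps_after"],
        )

    # ------------------------------------------------ model + REML
    stage("reml")
    spec = ModelSpec(
        trait=config.trait, factors=config.fixed_factors, covariates=config.covariates
    )
    model = SingleStepRepeatabilityModel(
        records, spec, ped, genotypes=geno, blend_alpha=config.wssgwas.blend_alpha
    )
    results = model.fit(
        method=config.reml.method, max_iter=config.reml.max_iter, tol=config.reml.tol
    )
    results.vc.as_series().to_frame("value").to_csv(out / "variance_components.tsv", sep="\t")
    results.vc.to_frame().to_csv(out / "variance_components_se.tsv", sep="\t", index=False)
    (out / "model_summary.txt").write_text(results.summary() + "\n")
    results.gebv.to_csv(out / "gebv.tsv", sep="\t", index=False)

    # ------------------------------------------------ WssGWAS + scan
    stage("wssgwas")
    ws = results.wssgwas(
        n_iterations=config.wssgwas.n_iterations, cap_sd=config.wssgwas.cap_sd
    )
    ws.effects_frame().to_csv(out / "snp_effects.tsv", sep="\t", index=False)
    stage("scan")
    scan = ws.scan(
        window_size=config.wssgwas.window_size, step=config.wssgwas.window_step
    )
    scan["significant"] = scan["pct_variance"] >= config.wssgwas.threshold_pct
    scan.to_csv(out / "window_scan.tsv", sep="\t", index=False)
    regions = significant_regions(scan, config.wssgwas.threshold_pct)
    regions.to_csv(out / "regions.tsv", sep="\t", index=False)

    # ------------------------------------------------ annotation
    n_region_genes = None
    n_deg_overlap = None
    if config.annotation_path is not None:
        stage("annotate")
        reader = read_gff3 if config.annotation_format == "gff3" else read_bed
        annotation = reader(config.annotation_path)
        region_genes = genes_in_regions(regions, annotation)
        region_genes.to_csv(out / "region_genes.tsv", sep="\t", index=False)
        n_region_genes = len(region_genes)
        if config.deg_path is not None:
            deg = read_deg_table(config.deg_path)
            overlap = overlap_with_deg(region_genes, deg, trait=config.trait)
            overlap.to_csv(out / "deg_overlap.tsv", sep="\t", index=False)
            n_deg_overlap = len(overlap)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.model_dump(mode="json"),
        "config_hash": _config_hash(config),
        "rng_seed": config.rng_seed,
        "stages": stages,
        "n_records": len(records),
        "n_animals": ped.n,
        "n_genotyped_after_qc": geno.n_individuals,
        "n_snps_after_qc": geno.n_snps,
        "variance_components": {
            "sigma2_a": results.vc.sigma2_a,
            "sigma2_pe": results.vc.sigma2_pe,
            "sigma2_e": results.vc.sigma2_e,
            "h2": results.heritability(),
            "repeatability": results.repeatability(),
        },
        "n_significant_regions": len(regions),
        "n_region_genes": n_region_genes,
        "n_deg_overlap": n_deg_overlap,
        "runtime_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
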