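"""Configuration models for simulation, QC and the end-to-end pipeline."""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

__all__ = ["SimulationConfig", "QCConfig", "WssGwasConfig", "RunConfig"]


class SimulationConfig(BaseModel):
    """Stated world of the synthetic herd.

    Defaults emulate the study system: a multi-generation dairy pedigree with
    a genotyped cow subset, biallelic autosomal SNPs, and repeated records on
    cows with additive (sigma2_a), permanent-environmental (sigma2_pe) and
    residual (sigma2_e) variances at rectal-temperature magnitudes
    (0.015 / 0.03 / 0.20 trait^2, i.e. h2 = 0.06, repeatability = 0.18),
    fixed farm-year / parity (1,2,3+) / lactation-stage / milking-status
    effects and a linear THI covariate over the observed 70.5-90.2 range.
    """

    # pedigree
    n_founders: int = Field(100, ge=2)
    n_generations: int = Field(3, ge=0, description="descendant generations; 0 = founders only")
    n_per_generation: int = Field(100, ge=1)
    offspring_per_mating: int = Field(1, ge=1)
    sire_fraction: float = Field(0.08, gt=0, le=1, description="sires used : offspring produced")
    genotyped_fraction: float = Field(0.6, ge=0, le=1)
    genotyped_generations: int = Field(1, ge=1, description="youngest generations eligible for genotyping")
    # genome
    n_chromosomes: int = Field(5, ge=1)
    snps_per_chromosome: int = Field(200, ge=1)
    chromosome_length_bp: int = Field(100_000_000, ge=1)
    maf_low: float = Field(0.05, gt=0)
    maf_high: float = Field(0.5, le=0.5)
    recombination: Literal["independent", "haldane"] = "independent"
    # genetic architecture
    n_qtl: int = Field(0, ge=0)
    qtl_variance_fractions: list[float] = Field(
        default_factory=list,
        description="per-QTL fraction of sigma2_a; remainder is polygenic",
    )
    # trait (co)variances, trait^2 units
    sigma2_a: float = Field(0.015, ge=0)
    sigma2_pe: float = Field(0.03, ge=0)
    sigma2_e: float = Field(0.20, ge=0)
    # fixed-effect structure
    n_farm_year: int = Field(10, ge=1)
    n_parity: int = Field(3, ge=1)
    n_stage: int = Field(7, ge=1)
    n_milking: int = Field(3, ge=1)
    fixed_effect_sd: float = Field(0.1, ge=0, description="sd of factor level effects, trait units")
    trait_mean: float = 0.0
    thi_beta: float = Field(0.02, description="trait units per THI unit")
    thi_low: float = 70.5
    thi_high: float = 90.2
    records_per_animal: tuple[int, int] = (2, 4)
    record_sex: Literal["F", "all"] = "F"
    rng_seed: int = 2024

    @model_validator(mode="after")
    def _check(self):
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        if self.n_qtl > self.n_chromosomes * self.snps_per_chromosome:
            raise ValueError("n_qtl exceeds total SNPs")
        if self.qtl_variance_fractions and len(self.qtl_variance_fractions) != self.n_qtl:
            raise ValueError("qtl_variance_fractions length must equal n_qtl")
        if sum(self.qtl_variance_fractions) > 1.0 + 1e-12:
            raise ValueError("QTL variance fractions exceed sigma2_a")
        lo, hi = self.records_per_animal
        if not (1 <= lo <= hi):
            raise ValueError("records_per_animal must satisfy 1 <= low <= high")
        if self.thi_low > self.thi_high:
            raise ValueError("thi_low > thi_high")
        return self


class QCConfig(BaseModel):
    """Marker/individual quality-control thresholds (strict > comparisons)."""

    min_call_rate: float = Field(0.9, ge=0, le=1)
    min_maf: float = Field(0.05, ge=0, le=0.5)
    hwe_min_p: float = Field(1e-6, ge=0, le=1)
    autosomes: tuple[int, int] = (1, 29)  # cattle default


class WssGwasConfig(BaseModel):
    n_iterations: int = Field(3, ge=1)
    window_size: int = Field(10, ge=1)
    window_step: int = Field(1, ge=1)
    threshold_pct: float = Field(0.15, ge=0)
    cap_sd: float = Field(5.0, gt=0)
    blend_alpha: float = Field(0.05, ge=0, lt=1)


class RemlConfig(BaseModel):
    method: Literal["ai", "em", "ai-em"] = "ai-em"
    max_iter: int = Field(100, ge=1)
    tol: float = Field(1e-8, gt=0)


class RunConfig(BaseModel):
    """One-file description of a pipeline run.

    Either ``simulate`` is given (all inputs generated) or the explicit
    input paths are; annotation/DEG paths are optional in both modes.
    """

    simulate: Optional[SimulationConfig] = None
    pedigree_path: Optional[str] = None
    phenotype_path: Optional[str] = None
    genotype_prefix: Optional[str] = None  # PLINK prefix
    annotation_path: Optional[str] = None  # GFF3 or BED
    annotation_format: Literal["gff3", "bed"] = "gff3"
    deg_path: Optional[str] = None
    trait: str = "y"
    fixed_factors: list[str] = Field(
        default_factory=lambda: ["farm_year", "parity", "stage", "milking"]
    )
    covariates: list[str] = Field(default_factory=lambda: ["thi"])
    qc: QCConfig = QCConfig()
    reml: RemlConfig = RemlConfig()
    wssgwas: WssGwasConfig = WssGwasConfig()
    outdir: str = "wssgwas_run"
    rng_seed: int = 2024

    @model_validator(mode="after")
    def _check(self):
        if self.simulate is None:
            needed = (self.pedigree_path, self.phenotype_path, self.genotype_prefix)
            if any(p is None for p in needed):
                raise ValueError(
                    "either a simulate block or pedigree/phenotype/genotype paths are required"
                )
        return self
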