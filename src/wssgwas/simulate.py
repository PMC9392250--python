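"""Synthetic herd generator: pedigree, gene-dropped genotypes, phenotypes.

Everything downstream (QC, relationship matrices, REML, ssGBLUP, the
weighted GWAS scan) is testable against this module because the simulator
stores its truth: true breeding values, permanent-environmental deviations,
QTL positions and effects, and the exact variance components used.

The mating scheme is a simple dairy analogue: every generation a small set
of sires (``sire_fraction``) is drawn from the previous generation's males
and mated to random previous-generation dams. Genotypes are gene-dropped
haplotypes: founder alleles are Bernoulli(p_j) at per-SNP founder
frequencies, offspring receive one gamete per parent with either independent
segregation per SNP (default) or Haldane recombination at 1 cM/Mb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "simulate_pedigree",
    "simulate_marker_map",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "SimulatedPhenotypes",
    "SimulatedDataset",
]

PARITY_LEVELS = ["1", "2", "3+"]
STAGE_LEVELS = ["1-50", "51-100", "101-150", "151-200", "201-250", "251-300", ">300"]
MILKING_LEVELS = ["before", "after", "unknown"]


def lactation_stage_class(days_in_milk: int) -> str:
    """Map days in milk to the seven lactation-stage classes."""
    edges = [50, 100, 150, 200, 250, 300]
    for label, hi in zip(STAGE_LEVELS, edges):
        if days_in_milk <= hi:
            return label
    return STAGE_LEVELS[-1]


def _rng(config: SimulationConfig, seed=None) -> np.random.Generator:
    return np.random.default_rng(config.rng_seed if seed is None else seed)


# ----------------------------------------------------------------------
def simulate_pedigree(config: SimulationConfig, seed=None) -> Pedigree:
    """Multi-generation pedigree with parents preceding offspring.

    Founders (generation 0) have unknown parents; each later generation is
    produced by matings of randomly drawn sires and dams from the previous
    generation. A random fraction of the youngest generation(s) is flagged
    genotyped.
    """
    rng = _rng(config, seed)
    animal, sire, dam, gen, sex = [], [], [], [], []

    def balanced_sexes(k: int) -> list[str]:
        # alternate M/F then shuffle: every cohort contains both sexes
        s = ["M" if i % 2 == 0 else "F" for i in range(k)]
        rng.shuffle(s)
        return s

    next_id = 1
    for sx in balanced_sexes(config.n_founders):
        animal.append(next_id)
        sire.append(0)
        dam.append(0)
        gen.append(0)
        sex.append(sx)
        next_id += 1
    prev = list(range(config.n_founders))
    for g in range(1, config.n_generations + 1):
        males = [i for i in prev if sex[i] == "M"]
        females = [i for i in prev if sex[i] == "F"]
        if not males or not females:
            raise ValueError("previous generation lacks one sex; increase n_founders")
        n_sires = max(1, int(round(config.sire_fraction * config.n_per_generation)))
        sires = rng.choice(males, size=min(n_sires, len(males)), replace=False)
        born = 0
        new = []
        cohort_sex = iter(balanced_sexes(config.n_per_generation))
        while born < config.n_per_generation:
            s = int(rng.choice(sires))
            d = int(rng.choice(females))
            if s == d:
                continue
            for _ in range(min(config.offspring_per_mating, config.n_per_generation - born)):
                animal.append(next_id)
                sire.append(animal[s])
                dam.append(animal[d])
                gen.append(g)
                sex.append(next(cohort_sex))
                new.append(next_id - 1)
                next_id += 1
                born += 1
        prev = new
    table = pd.DataFrame(
        {"animal": animal, "sire": sire, "dam": dam, "generation": gen, "sex": sex}
    )
    eligible = table["generation"] > table["generation"].max() - config.genotyped_generations
    if config.n_generations == 0:
        eligible = table["generation"] == 0
    flags = np.zeros(len(table), dtype=bool)
    idx = np.flatnonzero(eligible.to_numpy())
    n_geno = int(round(config.genotyped_fraction * len(idx)))
    if n_geno:
        flags[rng.choice(idx, size=n_geno, replace=False)] = True
    table["genotyped"] = flags
    return Pedigree(table)


def simulate_marker_map(config: SimulationConfig, seed=None) -> pd.DataFrame:
    """Random autosomal marker map with founder allele frequencies.

    Positions are sorted unique 1-based bp per chromosome; founder
    frequencies are uniform on [maf_low, maf_high], randomly reflected to
    1 - p so the counted allele is not always the minor one.
    """
    rng = _rng(config, seed)
    rows = []
    k = 0
    for c in range(1, config.n_chromosomes + 1):
        pos = np.sort(
            rng.choice(
                np.arange(1, config.chromosome_length_bp + 1),
                size=config.snps_per_chromosome,
                replace=False,
            )
        )
        for p_bp in pos:
            k += 1
            rows.append((f"snp{k}", c, int(p_bp)))
    m = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp"])
    m["a1"] = "A"
    m["a2"] = "B"
    p = rng.uniform(config.maf_low, config.maf_high, size=len(m))
    flip = rng.random(len(m)) < 0.5
    m["founder_freq"] = np.where(flip, 1.0 - p, p)
    return m


def simulate_genotypes(
    ped: Pedigree, marker_map: pd.DataFrame, config: SimulationConfig, seed=None
) -> GenotypeMatrix:
    """Gene-drop genotypes for every pedigree animal.

    Founder haplotypes are Bernoulli(founder_freq); each offspring gamete
    copies one parental allele per SNP (independent segregation) or a
    recombinant parental haplotype under a Haldane map at 1 cM/Mb.
    """
    for c, grp in marker_map.groupby("chrom"):
        if not np.all(np.diff(grp["pos_bp"].to_numpy()) > 0):
            raise ValueError(f"positions not strictly increasing on chromosome {c}")
    rng = _rng(config, seed)
    n, m = ped.n, len(marker_map)
    freqs = marker_map["founder_freq"].to_numpy() if "founder_freq" in marker_map else np.full(m, 0.5)
    hap = np.zeros((n, 2, m), dtype=np.int8)
    chrom = marker_map["chrom"].to_numpy()
    pos = marker_map["pos_bp"].to_numpy()
    chrom_slices = [np.flatnonzero(chrom == c) for c in np.unique(chrom)]

    def gamete(parent_row: int) -> np.ndarray:
        if config.recombination == "independent":
            pick = rng.integers(0, 2, size=m)
            return hap[parent_row, pick, np.arange(m)]
        out = np.empty(m, dtype=np.int8)
        for sl in chrom_slices:
            d_morgan = np.diff(pos[sl]) * 1e-8  # 1 cM/Mb
            r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))  # Haldane
            state = np.empty(len(sl), dtype=np.int64)
            state[0] = rng.integers(0, 2)
            switches = rng.random(len(sl) - 1) < r
            state[1:] = switches
            state = np.cumsum(state) % 2
            out[sl] = hap[parent_row, state, sl]
        return out

    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        for h, p_idx in enumerate((s, d)):
            if p_idx < 0:
                hap[i, h] = (rng.random(m) < freqs).astype(np.int8)
            else:
                hap[i, h] = gamete(p_idx)
    X = hap.sum(axis=1, dtype=np.int8)
    return GenotypeMatrix(ids=ped.ids, marker_map=marker_map, X=X)


# ----------------------------------------------------------------------
@dataclass
class SimulatedPhenotypes:
    """Phenotype records plus the simulator's truth."""

    records: pd.DataFrame
    true_breeding_values: pd.Series  # per animal, trait units
    true_pe: pd.Series  # per recorded animal
    qtl: pd.DataFrame  # snp_index, snp_id, alpha, variance_fraction
    config: SimulationConfig


def simulate_phenotypes(
    ped: Pedigree,
    geno: GenotypeMatrix | None,
    config: SimulationConfig,
    seed=None,
) -> SimulatedPhenotypes:
    """Repeated records y = fixed effects + thi_beta*THI + a + pe + e.

    True breeding values are the sum of QTL dosage effects (each QTL scaled
    to its requested fraction of sigma2_a over the simulated population) and
    a pedigree-dropped polygenic term carrying the remaining additive
    variance; pe is one draw per animal, residuals one per record.
    """
    for s2 in (config.sigma2_a, config.sigma2_pe, config.sigma2_e):
        if s2 < 0:
            raise ValueError("negative variance requested")
    rng = _rng(config, seed)
    n = ped.n

    # QTL part of the breeding value
    qtl_rows = []
    a_qtl = np.zeros(n)
    if config.n_qtl > 0 and geno is None:
        raise ValueError("QTL simulation requires genotypes")
    if config.n_qtl > 0:
        fracs = config.qtl_variance_fractions or [
            0.5 / config.n_qtl for _ in range(config.n_qtl)
        ]
        maf = geno.minor_allele_freq()
        candidates = np.flatnonzero(maf >= 0.1)
        if len(candidates) < config.n_qtl:
            candidates = np.argsort(-maf)[: max(config.n_qtl, 1)]
        snp_idx = rng.choice(candidates, size=config.n_qtl, replace=False)
        for j, frac in zip(snp_idx, fracs):
            z = geno.X[:, j].astype(float)
            v = z.var()
            if v <= 0:
                continue
            alpha = np.sqrt(frac * config.sigma2_a / v) * rng.choice([-1.0, 1.0])
            a_qtl += z * alpha
            qtl_rows.append((int(j), geno.marker_map["snp_id"].iloc[j], alpha, frac))
    qtl = pd.DataFrame(qtl_rows, columns=["snp_index", "snp_id", "alpha", "variance_fraction"])
    s2_poly = config.sigma2_a * max(0.0, 1.0 - float(qtl["variance_fraction"].sum()))

    # polygenic part dropped through the pedigree with Mendelian sampling
    u = np.zeros(n)
    if s2_poly > 0:
        F = ped.inbreeding()
        dvec = ped._mendelian_variance(F)
        for i in range(n):
            s, d = ped.sire_idx[i], ped.dam_idx[i]
            mid = 0.0
            if s >= 0:
                mid += 0.5 * u[s]
            if d >= 0:
                mid += 0.5 * u[d]
            u[i] = mid + rng.normal(0.0, np.sqrt(dvec[i] * s2_poly))
    tbv = a_qtl - a_qtl.mean() + u

    # who gets records
    sexes = ped.table["sex"].to_numpy() if "sex" in ped.table else np.full(n, "F")
    if config.record_sex == "F":
        recorded = np.flatnonzero((sexes == "F") & (ped.table["generation"].to_numpy() >= 0))
    else:
        recorded = np.arange(n)
    pe = rng.normal(0.0, np.sqrt(config.sigma2_pe), size=len(recorded))

    fy_eff = rng.normal(0.0, config.fixed_effect_sd, size=config.n_farm_year)
    par_eff = rng.normal(0.0, config.fixed_effect_sd, size=config.n_parity)
    stage_eff = rng.normal(0.0, config.fixed_effect_sd, size=config.n_stage)
    milk_eff = rng.normal(0.0, config.fixed_effect_sd, size=config.n_milking)

    lo, hi = config.records_per_animal
    rows = []
    for k, i in enumerate(recorded):
        n_rec = int(rng.integers(lo, hi + 1))
        for _ in range(n_rec):
            fy = int(rng.integers(config.n_farm_year))
            par = int(rng.integers(config.n_parity))
            st = int(rng.integers(config.n_stage))
            mk = int(rng.integers(config.n_milking))
            thi = rng.uniform(config.thi_low, config.thi_high)
            e = rng.normal(0.0, np.sqrt(config.sigma2_e))
            y = (
                config.trait_mean
                + fy_eff[fy]
                + par_eff[par]
                + stage_eff[st]
                + milk_eff[mk]
                + config.thi_beta * thi
                + tbv[i]
                + pe[k]
                + e
            )
            rows.append(
                (
                    ped.ids[i],
                    f"fy{fy + 1}",
                    PARITY_LEVELS[par % len(PARITY_LEVELS)] if config.n_parity <= 3 else f"p{par + 1}",
                    STAGE_LEVELS[st % len(STAGE_LEVELS)] if config.n_stage <= 7 else f"s{st + 1}",
                    MILKING_LEVELS[mk % len(MILKING_LEVELS)] if config.n_milking <= 3 else f"m{mk + 1}",
                    thi,
                    y,
                    tbv[i],
                    pe[k],
                )
            )
    records = pd.DataFrame(
        rows,
        columns=[
            "animal", "farm_year", "parity", "stage", "milking",
            "thi", "y", "true_tbv", "true_pe",
        ],
    )
    return SimulatedPhenotypes(
        records=records,
        true_breeding_values=pd.Series(tbv, index=ped.ids, name="true_tbv"),
        true_pe=pd.Series(pe, index=ped.ids[recorded], name="true_pe"),
        qtl=qtl,
        config=config,
    )


@dataclass
class SimulatedDataset:
    pedigree: Pedigree
    genotypes: GenotypeMatrix  # all pedigree animals (truth)
    phenotypes: SimulatedPhenotypes

    @property
    def observed_genotypes(self) -> GenotypeMatrix:
        """Genotypes restricted to animals flagged genotyped."""
        return self.genotypes.subset(rows=self.pedigree.genotyped_index)


def simulate_dataset(config: SimulationConfig, seed=None) -> SimulatedDataset:
    """Pedigree + genotypes + phenotypes in one reproducible call."""
    root = np.random.default_rng(config.rng_seed if seed is None else seed)
    s1, s2, s3, s4 = root.integers(0, 2**31 - 1, size=4)
    ped = simulate_pedigree(config, seed=s1)
    marker_map = simulate_marker_map(config, seed=s2)
    geno = simulate_genotypes(ped, marker_map, config, seed=s3)
    phen = simulate_phenotypes(ped, geno, config, seed=s4)
    return SimulatedDataset(pedigree=ped, genotypes=geno, phenotypes=phen)
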