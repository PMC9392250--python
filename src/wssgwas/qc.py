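"""Genotype quality control and diagnostic PCA.

The filter chain mirrors standard SNP-chip practice: individual call rate
(> 0.9), autosome/position check, minor allele frequency (> 0.05) and a
Hardy-Weinberg exact test (keep P > 1e-6). All comparisons are strict.
Frequencies are recomputed on the retained individuals before SNP filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import QCConfig
from .genotypes import GenotypeMatrix

__all__ = [
    "QCReport",
    "filter_individual_call_rate",
    "filter_autosomes",
    "filter_maf",
    "filter_hwe",
    "hwe_exact_test",
    "run_qc",
    "genotype_pca",
]


@dataclass
class QCReport:
    """Per-step survivor counts and removal lists; counts are non-increasing."""

    steps: list[dict] = field(default_factory=list)

    def record(self, name, n_ind_before, n_ind_after, n_snp_before, n_snp_after, removed):
        self.steps.append(
            {
                "step": name,
                "n_individuals_before": n_ind_before,
                "n_individuals_after": n_ind_after,
                "n_snps_before": n_snp_before,
                "n_snps_after": n_snp_after,
                "n_removed": len(removed),
                "removed": list(removed),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{k: v for k, v in s.items() if k != "removed"} for s in self.steps]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _require_nonempty(geno: GenotypeMatrix):
    if geno.n_individuals == 0 or geno.n_snps == 0:
        raise ValueError("empty genotype matrix")


def filter_individual_call_rate(
    geno: GenotypeMatrix, threshold: float = 0.9, report: QCReport | None = None
) -> GenotypeMatrix:
    """Keep individuals whose fraction of non-missing genotypes exceeds ``threshold``."""
    _require_nonempty(geno)
    cr = geno.individual_call_rate()
    keep = cr > threshold
    if report is not None:
        report.record(
            "individual_call_rate",
            geno.n_individuals, int(keep.sum()), geno.n_snps, geno.n_snps,
            geno.ids[~keep],
        )
    return geno.subset(rows=keep)


def filter_autosomes(
    geno: GenotypeMatrix, autosomes=(1, 29), report: QCReport | None = None
) -> GenotypeMatrix:
    """Keep SNPs with known position on an autosome in [low, high]."""
    _require_nonempty(geno)
    lo, hi = autosomes
    m = geno.marker_map
    keep = (m["chrom"] >= lo) & (m["chrom"] <= hi) & (m["pos_bp"] >= 1)
    keep = keep.to_numpy()
    if report is not None:
        report.record(
            "autosome_position",
            geno.n_individuals, geno.n_individuals, geno.n_snps, int(keep.sum()),
            m["snp_id"][~keep],
        )
    return geno.subset(cols=keep)


def filter_maf(
    geno: GenotypeMatrix, min_maf: float = 0.05, report: QCReport | None = None
) -> GenotypeMatrix:
    """Keep SNPs with minor allele frequency strictly greater than ``min_maf``."""
    _require_nonempty(geno)
    maf = geno.minor_allele_freq()
    keep = maf > min_maf
    if report is not None:
        report.record(
            "maf",
            geno.n_individuals, geno.n_individuals, geno.n_snps, int(keep.sum()),
            geno.marker_map["snp_id"][~keep],
        )
    return geno.subset(cols=keep)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided Hardy-Weinberg exact test P-value.

    Full enumeration of heterozygote counts conditional on the observed
    allele counts; P is the summed probability of all configurations no more
    probable than the observed one. Monomorphic input returns 1.0 (no
    departure computable).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0
    rare = min(n_A, n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_Aa = h | n_A, n) for the conditional distribution
    homr = (rare - hets) // 2
    homc = (n - hets - homr) if n_A >= n_a else None  # placeholder, computed below
    homc = (max(n_A, n_a) - hets) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(n_A + 1)
        + gammaln(n_a + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = np.flatnonzero(hets == n_Aa)
    if len(obs) == 0:  # inconsistent counts cannot occur with valid input
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    p_obs = p[obs[0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def filter_hwe(
    geno: GenotypeMatrix, min_p: float = 1e-6, report: QCReport | None = None
) -> GenotypeMatrix:
    """Keep SNPs whose HWE exact-test P-value strictly exceeds ``min_p``."""
    _require_nonempty(geno)
    X = geno.X
    keep = np.empty(geno.n_snps, dtype=bool)
    for j in range(geno.n_snps):
        col = X[:, j]
        obs = col[col >= 0]
        pval = hwe_exact_test(int((obs == 2).sum()), int((obs == 1).sum()), int((obs == 0).sum()))
        keep[j] = pval > min_p
    if report is not None:
        report.record(
            "hwe",
            geno.n_individuals, geno.n_individuals, geno.n_snps, int(keep.sum()),
            geno.marker_map["snp_id"][~keep],
        )
    return geno.subset(cols=keep)


def run_qc(geno: GenotypeMatrix, config: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Filter chain: individual call rate -> autosome/position -> MAF -> HWE.

    A SNP failing several filters is reported under the first one that
    removes it. Raises if the chain empties the panel.
    """
    config = config or QCConfig()
    report = QCReport()
    g = filter_individual_call_rate(geno, config.min_call_rate, report)
    if g.n_individuals == 0:
        raise ValueError("all individuals removed by call-rate filter")
    g = filter_autosomes(g, config.autosomes, report)
    if g.n_snps == 0:
        raise ValueError("empty panel after autosome filter")
    g = filter_maf(g, config.min_maf, report)
    if g.n_snps == 0:
        raise ValueError("empty panel after MAF filter")
    g = filter_hwe(g, config.hwe_min_p, report)
    if g.n_snps == 0:
        raise ValueError("empty panel after HWE filter")
    return g, report


def genotype_pca(
    geno: GenotypeMatrix, n_components: int = 10, standardize: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the centered (optionally 1/sqrt(2p(1-p))-scaled) genotypes.

    Returns a score table (one row per individual) and the fraction of
    variance explained per component.
    """
    if geno.n_individuals < 2:
        raise ValueError("PCA requires at least two individuals")
    from sklearn.decomposition import PCA

    Z = geno.centered()
    if standardize:
        p = geno.allele_freq()
        scale = np.sqrt(2.0 * p * (1.0 - p))
        ok = scale > 0
        Z = Z[:, ok] / scale[ok]
    max_rank = min(geno.n_individuals - 1, Z.shape[1])
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {max_rank}; truncating",
            stacklevel=2,
        )
        n_components = max_rank
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Z)
    table = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    table.insert(0, "animal", geno.ids)
    return table, pca.explained_variance_ratio_
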