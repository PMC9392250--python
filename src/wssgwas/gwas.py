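"""Weighted single-step GWAS: SNP effect backsolving, iterative weighting,
and the 10-SNP window variance scan.

SNP effects are backsolved from the GEBV of genotyped animals,

    u_hat = (1/k) D Z' G*^-1 a_hat_g ,      k = sum_i 2 p_i (1 - p_i),

with Z the centered gene content and D the current diagonal SNP-weight
matrix. Weights follow d_i = 1.125^(|u_i|/sd(u) - 2) with the standardized
effect capped at ``cap_sd`` before the shift, then rescaled so they sum to
the number of SNPs. Each iteration rebuilds G* from the new weights,
reassembles H^-1, re-solves the mixed model equations for GEBV (the
"re-estimated GEBV" scheme) and re-backsolves; variance components are held
fixed across iterations. The scan slides windows of 10 consecutive SNPs
within each chromosome and reports the empirical variance, across genotyped
individuals, of the window's summed genomic values as a percentage of the
total additive genetic variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrices
from .genotypes import GenotypeMatrix
from .kinship import build_G, blend_tune_G, build_H_inverse, inv_psd
from .mme import assemble_mme, solve_mme
from .pedigree import Pedigree

__all__ = [
    "SNPEffectSet",
    "backsolve_snp_effects",
    "snp_weights",
    "run_wssgwas",
    "WssGwasResult",
    "window_variance_scan",
    "significant_regions",
    "manhattan_plot",
]


@dataclass
class SNPEffectSet:
    """Backsolved marker effects for one trait and weighting iteration."""

    effects: np.ndarray  # trait units per counted allele
    iteration: int
    trait: str = "y"
    sd: float = np.nan  # sd of the effect distribution used for weighting

    def to_frame(self, marker_map: pd.DataFrame) -> pd.DataFrame:
        out = marker_map[["snp_id", "chrom", "pos_bp"]].copy()
        out["effect"] = self.effects
        out["iteration"] = self.iteration
        return out


def backsolve_snp_effects(
    gebv_genotyped: np.ndarray,
    Z_centered: np.ndarray,
    weights: np.ndarray | None,
    G_star_inv: np.ndarray,
    k: float,
    iteration: int = 1,
    trait: str = "y",
) -> SNPEffectSet:
    """u_hat = (1/k) D Z' G*^-1 a_hat over the genotyped animals."""
    a = np.asarray(gebv_genotyped, dtype=float)
    if Z_centered.shape[0] != len(a) or G_star_inv.shape != (len(a), len(a)):
        raise ValueError("dimension mismatch between GEBV, Z and G*^-1")
    u = Z_centered.T @ (G_star_inv @ a) / k
    if weights is not None:
        d = np.asarray(weights, dtype=float)
        if d.shape != (Z_centered.shape[1],):
            raise ValueError("weights length must equal the number of SNPs")
        u = d * u
    return SNPEffectSet(effects=u, iteration=iteration, trait=trait, sd=float(np.std(u)))


def snp_weights(effects: SNPEffectSet | np.ndarray, cap_sd: float = 5.0) -> np.ndarray:
    """d_i = 1.125^(min(|u_i|/sd(u), cap_sd) - 2), rescaled to sum to M.

    The cap on the standardized effect prevents single-SNP weight explosion;
    rescaling keeps the total genomic variance constant across iterations.
    A degenerate all-zero effect vector yields identity weights.
    """
    u = effects.effects if isinstance(effects, SNPEffectSet) else np.asarray(effects, float)
    m = len(u)
    sd = float(np.std(u))
    if sd == 0.0:
        warnings.warn("all SNP effects zero; returning identity weights", stacklevel=2)
        return np.ones(m)
    x = np.minimum(np.abs(u) / sd, cap_sd) - 2.0
    d = 1.125**x
    return d * (m / d.sum())


@dataclass
class WssGwasResult:
    """Per-iteration SNP effects and weights plus the inputs for scanning."""

    iterations: list[SNPEffectSet]
    weights: list[np.ndarray]  # weights used to BUILD G at each iteration
    geno: GenotypeMatrix
    sigma2_a: float
    trait: str = "y"
    gebv: pd.DataFrame | None = None  # final-iteration GEBV for all animals
    meta: dict = field(default_factory=dict)

    @property
    def final_effects(self) -> SNPEffectSet:
        return self.iterations[-1]

    def scan(self, window_size: int = 10, step: int = 1) -> pd.DataFrame:
        return window_variance_scan(
            self.final_effects, self.geno, window_size=window_size,
            step=step, sigma2_a=self.sigma2_a,
        )

    def effects_frame(self) -> pd.DataFrame:
        return pd.concat(
            [it.to_frame(self.geno.marker_map) for it in self.iterations],
            ignore_index=True,
        )


def run_wssgwas(
    design: DesignMatrices,
    ped: Pedigree,
    geno: GenotypeMatrix,
    vc,
    n_iterations: int = 3,
    blend_alpha: float = 0.05,
    cap_sd: float = 5.0,
    solver: str = "direct",
    trait: str = "y",
) -> WssGwasResult:
    """Iterative weighted single-step GWAS (default three iterations).

    ``geno`` holds the QC-passed genotyped animals (a subset of the
    pedigree); iteration 1 uses D = I, later iterations rebuild G* and H^-1
    from the updated weights and re-solve the MME for fresh GEBV before
    re-backsolving. Raises if the weight spread diverges beyond 1e6.
    """
    g_idx = ped.indices_of(geno.ids)
    A_inv = ped.a_inverse()
    A22 = ped.a_submatrix(g_idx)
    A22_inv = inv_psd(A22, "A22")
    p = geno.allele_freq()
    Zc = geno.centered(p)
    iterations: list[SNPEffectSet] = []
    used_weights: list[np.ndarray] = []
    d = np.ones(geno.n_snps)
    gebv_frame = None
    for it in range(1, n_iterations + 1):
        if d.max() / d.min() > 1e6:
            raise RuntimeError(
                f"diverging SNP weights at iteration {it}: "
                f"max/min ratio {d.max() / d.min():.3e}"
            )
        G = build_G(geno, weights=None if it == 1 else d, freqs=p)
        Gs = blend_tune_G(G, A22, blend_alpha)
        Gs_inv = inv_psd(Gs.values, "G*")
        H_inv = build_H_inverse(A_inv, A22_inv, Gs_inv, g_idx)
        system = assemble_mme(design, H_inv, vc)
        sol = solve_mme(system, solver=solver)
        a_g = sol.additive[g_idx]
        eff = backsolve_snp_effects(
            a_g, Zc, None if it == 1 else d, Gs_inv, G.meta["k"],
            iteration=it, trait=trait,
        )
        iterations.append(eff)
        used_weights.append(d.copy())
        gebv_frame = pd.DataFrame(
            {
                "animal": ped.ids,
                "trait": trait,
                "gebv": sol.additive,
                "genotyped": ped.genotyped_mask
                if ped.genotyped_mask.any()
                else np.isin(ped.ids, geno.ids),
            }
        )
        d = snp_weights(eff, cap_sd=cap_sd)
    return WssGwasResult(
        iterations=iterations,
        weights=used_weights,
        geno=geno,
        sigma2_a=vc.sigma2_a,
        trait=trait,
        gebv=gebv_frame,
        meta={"blend_alpha": blend_alpha, "cap_sd": cap_sd, "n_iterations": n_iterations},
    )


# ----------------------------------------------------------------------
def window_variance_scan(
    effects: SNPEffectSet | np.ndarray,
    geno: GenotypeMatrix,
    window_size: int = 10,
    step: int = 1,
    sigma2_a: float = 1.0,
) -> pd.DataFrame:
    """Percentage of additive genetic variance per SNP window.

    For each window of ``window_size`` consecutive SNPs within a chromosome
    (sliding by ``step``), the genomic value of every genotyped individual is
    summed over the window's SNPs and its population variance (divide-by-n)
    is expressed as a percentage of ``sigma2_a``. A chromosome with fewer
    SNPs than the window yields one short, flagged window.
    """
    u = effects.effects if isinstance(effects, SNPEffectSet) else np.asarray(effects, float)
    m = geno.n_snps
    if len(u) != m:
        raise ValueError("effects length does not match the SNP panel")
    Zc = geno.centered()
    V = Zc * u  # per-individual per-SNP genomic values
    chrom = geno.marker_map["chrom"].to_numpy()
    pos = geno.marker_map["pos_bp"].to_numpy()
    rows = []
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if len(idx) < window_size:
            starts = [0]
            short = True
        else:
            starts = range(0, len(idx) - window_size + 1, step)
            short = False
        for s0 in starts:
            win = idx[s0 : s0 + window_size]
            a_w = V[:, win].sum(axis=1)
            var = float(np.var(a_w))  # population variance across individuals
            rows.append(
                {
                    "chrom": int(c),
                    "start_bp": int(pos[win[0]]),
                    "end_bp": int(pos[win[-1]]),
                    "start_index": int(win[0]),
                    "end_index": int(win[-1]),
                    "n_snps": len(win),
                    "var_window": var,
                    "pct_variance": 100.0 * var / sigma2_a,
                    "short_window": short,
                }
            )
    return pd.DataFrame(rows)


def significant_regions(scan: pd.DataFrame, threshold_pct: float = 0.15) -> pd.DataFrame:
    """Merge significant windows into regions.

    Windows at or above ``threshold_pct`` that overlap or are adjacent
    (share or abut SNP indices) on the same chromosome are merged; each
    region reports the maximum member-window percentage and the summed
    percentage of its member windows.
    """
    sig = scan[scan["pct_variance"] >= threshold_pct].sort_values(
        ["chrom", "start_index"]
    )
    regions = []
    for c, grp in sig.groupby("chrom"):
        cur = None
        for _, w in grp.iterrows():
            if cur is not None and w["start_index"] <= cur["end_index"] + 1:
                cur["end_index"] = max(cur["end_index"], w["end_index"])
                cur["end_bp"] = max(cur["end_bp"], w["end_bp"])
                cur["n_windows"] += 1
                cur["max_pct"] = max(cur["max_pct"], w["pct_variance"])
                cur["sum_pct"] += w["pct_variance"]
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {
                    "chrom": int(c),
                    "start_bp": int(w["start_bp"]),
                    "end_bp": int(w["end_bp"]),
                    "start_index": int(w["start_index"]),
                    "end_index": int(w["end_index"]),
                    "n_windows": 1,
                    "max_pct": float(w["pct_variance"]),
                    "sum_pct": float(w["pct_variance"]),
                }
        if cur is not None:
            regions.append(cur)
    cols = [
        "chrom", "start_bp", "end_bp", "start_index", "end_index",
        "n_windows", "max_pct", "sum_pct",
    ]
    return pd.DataFrame(regions, columns=cols)


def manhattan_plot(scan: pd.DataFrame, threshold_pct: float = 0.15, path=None):
    """Plain per-window Manhattan plot of the variance-percentage scan."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for c, grp in scan.groupby("chrom"):
        x = grp["start_bp"].to_numpy() + offset
        ax.scatter(x, grp["pct_variance"], s=4, color="C0" if c % 2 else "C1")
        ticks.append(offset + grp["start_bp"].max() / 2)
        labels.append(str(c))
        offset += grp["start_bp"].max()
    ax.axhline(threshold_pct, color="red", ls="--", lw=1)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("% of additive variance")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
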