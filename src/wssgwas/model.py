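"""Single-step repeatability animal model, statsmodels-style.

:class:`SingleStepRepeatabilityModel` is built from a phenotype table, a
pedigree and (optionally) QC-passed genotypes; ``fit()`` estimates the
variance components by AI-REML against the combined relationship matrix H
(or A when no genotypes are given) and returns a
:class:`SingleStepResults` carrying the estimates, their standard errors,
the BLUE fixed effects and GEBV for every pedigree animal, with
``summary()``, ``heritability()``/``repeatability()`` and ``wssgwas()``
hanging off the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .design import DesignMatrices, ModelSpec, build_design
from .genotypes import GenotypeMatrix
from .gwas import WssGwasResult, run_wssgwas
from .kinship import blend_tune_G, build_G, build_H_inverse, inv_psd
from .mme import MMESolution, assemble_mme, solve_mme
from .pedigree import Pedigree
from .reml import (
    MultiTraitVarianceComponents,
    VarianceComponents,
    genetic_correlation,
    heritability,
    reml_estimate,
    reml_estimate_multitrait,
    reml_loglike,
    repeatability,
)

__all__ = ["SingleStepRepeatabilityModel", "SingleStepResults", "MultiTraitResults"]


class SingleStepRepeatabilityModel:
    """Repeatability animal model y = Xb + Za + Wpe + e with a ~ N(0, H sigma2_a).

    Parameters
    ----------
    records : phenotype table with one row per record (columns: the trait,
        ``animal``, the fixed factors and covariates of ``spec``).
    spec : ModelSpec naming trait, factors and covariates.
    pedigree : topologically ordered Pedigree; defines the additive effect's
        dimension and A^-1.
    genotypes : QC-passed GenotypeMatrix of the genotyped subset, or None
        for plain pedigree BLUP (then H = A).
    blend_alpha : weight of A22 blended into G before inversion.
    snp_weights : optional diagonal of D for a weighted G.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        spec: ModelSpec,
        pedigree: Pedigree,
        genotypes: GenotypeMatrix | None = None,
        blend_alpha: float = 0.05,
        snp_weights: np.ndarray | None = None,
    ):
        self.records = records
        self.spec = spec
        self.pedigree = pedigree
        self.genotypes = genotypes
        self.blend_alpha = blend_alpha
        self.design: DesignMatrices = build_design(records, spec, pedigree)
        self.A_inv = pedigree.a_inverse()
        if genotypes is not None and genotypes.n_individuals > 0:
            self._g_idx = pedigree.indices_of(genotypes.ids)
            A22 = pedigree.a_submatrix(self._g_idx)
            G = build_G(genotypes, weights=snp_weights)
            G_star = blend_tune_G(G, A22, blend_alpha)
            self.G_star = G_star
            self.K_inv: sp.spmatrix = build_H_inverse(
                self.A_inv, inv_psd(A22, "A22"), inv_psd(G_star.values, "G*"), self._g_idx
            )
            self.kind = "H"
        else:
            self._g_idx = np.array([], dtype=np.int64)
            self.G_star = None
            self.K_inv = self.A_inv
            self.kind = "A"

    @classmethod
    def from_dataframe(
        cls,
        records: pd.DataFrame,
        trait: str,
        pedigree: Pedigree,
        factors: list[str] | None = None,
        covariates: list[str] | None = None,
        **kwargs,
    ) -> "SingleStepRepeatabilityModel":
        spec = ModelSpec(
            trait=trait,
            factors=factors if factors is not None else ["farm_year", "parity", "stage", "milking"],
            covariates=covariates if covariates is not None else ["thi"],
        )
        return cls(records, spec, pedigree, **kwargs)

    # ------------------------------------------------------------------
    def loglike(self, vc: VarianceComponents) -> float:
        """Restricted log-likelihood at the given variance components."""
        return reml_loglike(self.design, self.K_inv, vc)

    def fit(
        self,
        method: str = "ai-em",
        start=None,
        max_iter: int = 100,
        tol: float = 1e-8,
        solver: str = "direct",
    ) -> "SingleStepResults":
        """Estimate variance components by REML, then solve the MME."""
        vc = reml_estimate(
            self.design, self.K_inv, start=start, method=method,
            max_iter=max_iter, tol=tol, trait=self.spec.trait,
        )
        return self.solve(vc, solver=solver)

    def solve(self, vc: VarianceComponents, solver: str = "direct") -> "SingleStepResults":
        """Solve the MME at fixed variance components (no REML)."""
        system = assemble_mme(self.design, self.K_inv, vc)
        sol = solve_mme(system, solver=solver)
        return SingleStepResults(model=self, vc=vc, solution=sol)

    def fit_multitrait(
        self, traits: list[str], max_iter: int = 200, **kwargs
    ) -> "MultiTraitResults":
        """Joint REML over several traits recorded on the same records."""
        Y = self.records[traits].to_numpy(dtype=float)
        vc = reml_estimate_multitrait(
            Y, self.design, self.K_inv, traits=traits, max_iter=max_iter, **kwargs
        )
        return MultiTraitResults(model=self, vc=vc)


@dataclass
class SingleStepResults:
    """Estimates, GEBV and diagnostics of a fitted single-step model."""

    model: SingleStepRepeatabilityModel
    vc: VarianceComponents
    solution: MMESolution
    _gebv: pd.DataFrame | None = field(default=None, repr=False)

    # --------------- parameter-level accessors ------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {
                "sigma2_a": self.vc.sigma2_a,
                "sigma2_pe": self.vc.sigma2_pe,
                "sigma2_e": self.vc.sigma2_e,
            }
        )

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.vc.se)

    def heritability(self) -> float:
        return heritability(self.vc)

    def repeatability(self) -> float:
        return repeatability(self.vc)

    @property
    def fixed_effects(self) -> pd.Series:
        return pd.Series(self.solution.fixed, index=self.model.design.x_columns)

    @property
    def gebv(self) -> pd.DataFrame:
        """GEBV for every pedigree animal with phenotype/genotype flags."""
        if self._gebv is None:
            ped = self.model.pedigree
            recorded = np.isin(ped.ids, self.model.design.recorded_ids)
            genotyped = np.zeros(ped.n, dtype=bool)
            genotyped[self.model._g_idx] = True
            self._gebv = pd.DataFrame(
                {
                    "animal": ped.ids,
                    "trait": self.vc.trait,
                    "gebv": self.solution.additive,
                    "phenotyped": recorded,
                    "genotyped": genotyped,
                }
            )
        return self._gebv

    @property
    def resid(self) -> np.ndarray:
        d = self.model.design
        return (
            d.y
            - d.X @ self.solution.fixed
            - d.Za @ self.solution.additive
            - d.Wpe @ self.solution.pe
        )

    def summary(self) -> str:
        vc = self.vc
        lines = [
            "Single-step repeatability animal model (REML)",
            "=" * 52,
            f"trait: {vc.trait}    relationship: {self.model.kind}",
            f"records: {self.model.design.n_records}    animals: {self.model.pedigree.n}"
            f"    genotyped: {len(self.model._g_idx)}",
            f"REML: {vc.method}, {'converged' if vc.converged else 'NOT converged'}"
            f" in {vc.n_iter} iterations, logL = {vc.loglike:.4f}",
            "-" * 52,
            f"{'component':<12}{'estimate':>12}{'SE':>12}",
        ]
        for name in ("sigma2_a", "sigma2_pe", "sigma2_e"):
            se = vc.se.get(name, np.nan)
            lines.append(f"{name:<12}{getattr(vc, name):>12.5f}{se:>12.5f}")
        lines += [
            "-" * 52,
            f"heritability  h2 = {self.heritability():.4f}",
            f"repeatability t  = {self.repeatability():.4f}",
        ]
        if not vc.pe_identifiable:
            lines.append("note: sigma2_pe unidentifiable (single records); pinned")
        if self.model.G_star is not None:
            meta = self.model.G_star.meta or {}
            lines.append(
                f"G* blend alpha = {meta.get('blend_alpha')}, "
                f"cond(G*) = {meta.get('condition_number'):.3g}"
            )
        return "\n".join(lines)

    # --------------------- downstream analyses ------------------------
    def wssgwas(
        self, n_iterations: int = 3, cap_sd: float = 5.0, solver: str = "direct"
    ) -> WssGwasResult:
        """Iterative weighted single-step GWAS at the fitted components."""
        if self.model.genotypes is None:
            raise ValueError("wssgwas requires genotypes")
        return run_wssgwas(
            self.model.design, self.model.pedigree, self.model.genotypes, self.vc,
            n_iterations=n_iterations, blend_alpha=self.model.blend_alpha,
            cap_sd=cap_sd, solver=solver, trait=self.vc.trait,
        )


@dataclass
class MultiTraitResults:
    model: SingleStepRepeatabilityModel
    vc: MultiTraitVarianceComponents

    def genetic_correlation(self, trait_i, trait_j) -> float:
        return genetic_correlation(self.vc, trait_i, trait_j)

    def summary(self) -> str:
        t = self.vc.traits
        lines = [
            "Multi-trait repeatability model (REML, direct maximization)",
            "=" * 60,
            f"traits: {', '.join(t)}    logL = {self.vc.loglike:.4f}"
            f"    {'converged' if self.vc.converged else 'NOT converged'}",
        ]
        for name, M in (("G_a", self.vc.G_a), ("G_pe", self.vc.G_pe), ("R", self.vc.R)):
            lines.append(f"{name}:")
            lines.append(pd.DataFrame(M, index=t, columns=t).to_string(float_format="%.5f"))
        for i in range(len(t)):
            for j in range(i + 1, len(t)):
                lines.append(
                    f"r_g({t[i]}, {t[j]}) = {self.genetic_correlation(i, j):.4f}"
                )
        return "\n".join(lines)
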