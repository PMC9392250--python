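# Methods

## The model

The package fits a repeatability animal model to repeated records,

y = Xb + Za + Wpe + e,

where b collects the systematic effects (farm-year, parity 1/2/3+, one of
seven lactation-stage classes by days in milk, milking status, and the
temperature-humidity index THI as a single linear covariate), a is the
additive genetic effect of every pedigree animal, pe a permanent-
environmental effect per recorded animal, and e the record residual. The
covariance assumptions are a ~ N(0, K sigma2_a), pe ~ N(0, I sigma2_pe),
e ~ N(0, I sigma2_e), with K = A (pedigree only) or the single-step matrix
H whose inverse is

H^-1 = A^-1 + [[0, 0], [0, G*^-1 - A22^-1]]

over the genotyped block. A^-1 is assembled sparsely by Henderson's rules
with inbreeding from the Meuwissen-Luo ancestor-tracing algorithm; the
dense tabular A is used only for A22 and for test oracles. G is the
(optionally SNP-weighted) VanRaden matrix Z D Z' / sum 2 p_i (1 - p_i) with
Z the gene content centered by twice the observed allele frequency of the
genotyped set, and G* = (1 - alpha) G + alpha A22 with alpha = 0.05 by
default. Blending is required: column-centering by observed frequencies
forces G's rows to sum to zero, so unblended G is always singular. The
blend weight and the condition number of G* are reported in the model
summary.

## Variance components

Single-trait fits use AI-REML: scores and the average-information matrix
are computed from one Cholesky factorization and inverse of the mixed-model
coefficient matrix per iteration (the AI matrix needs three extra solves
against the same factor). An AI step is halved up to twice if it leaves the
parameter space and replaced by an EM step — which cannot decrease the
restricted likelihood — if it still fails or if the likelihood dropped;
convergence is declared when the relative parameter change falls below
`tol` (default 1e-8). Standard errors come from the inverse AI matrix at
convergence. Components are floored at 1e-8 x the phenotypic variance and
flagged when pinned; with one record per animal sigma2_pe is not
identifiable and is pinned with a warning. The dense factorization caps the
fit at 8000 equations — ample for the synthetic worlds this package
targets; larger problems would need a sparse-inverse (Takahashi) backend.

Multi-trait fits (used for genetic correlations) assume every trait is
recorded on every record and maximize the restricted likelihood directly
with L-BFGS-B over log-Cholesky factors of the three covariance matrices,
evaluating the likelihood through a sparse factorization of the stacked
MME. This was chosen over multi-trait AI scores for robustness and code
economy; it is cross-checked against the univariate path by the identity
that block-diagonal covariances make the joint likelihood the sum of the
per-trait ones. No SEs are reported for the multi-trait fit.

## Weighted single-step GWAS

With variance components held fixed, each weighting iteration (three by
default) solves the MME for GEBV, backsolves SNP effects from the genotyped
animals' GEBV as u = (1/k) D Z' G*^-1 a_g, and converts them to weights
d_i = 1.125^(min(|u_i|/sd(u), 5) - 2). The sd is that of the whole effect
vector for the trait (the common reading of the weighting formula; a
per-SNP posterior sd is the alternative). The cap at 5 sd prevents
single-SNP weight explosion; weights are rescaled to sum to the SNP count
each iteration so total genomic variance is conserved. Later iterations
rebuild G*, H^-1 and the GEBV from the updated weights (the re-estimated-
GEBV scheme, which the source analysis preferred over re-computing effects
only).

The scan slides a 10-SNP window by 1 SNP within each chromosome (step and
width configurable; step 10 gives the disjoint alternative), sums each
genotyped individual's centered genomic value over the window, and reports
the population (divide-by-n) variance of that sum as a percentage of
sigma2_a. Windows at or above 0.15% merge into regions when they share or
abut SNP indices; regions report the max and the sum of member-window
percentages. Chromosomes shorter than the window yield one flagged short
window.

## Synthetic world

The generator's defaults are the stated conditions of the system the
package models: variance components at the published rectal-temperature
magnitudes (0.015 / 0.03 / 0.20 trait^2: h2 = 0.06, repeatability 0.18),
parity, seven lactation-stage classes, milking status and farm-year as
fixed effects with 0.1-trait-unit level effects, THI uniform on the
observed 70.5-90.2 range entering linearly at 0.02 trait units per THI
unit (the observed phenotype-THI gradient is not published; 0.02 deg C per
THI unit is a realistic heat-stress response slope), and 2-4 records per
cow. Pedigrees use a dairy-like mating scheme: few sires (8% of the cohort
size) drawn from the previous generation's males, dams drawn at random,
balanced sexes per cohort. Genotypes are gene-dropped haplotypes from
founder frequencies uniform on [0.05, 0.5]; segregation is independent per
SNP by default, with an optional Haldane map at 1 cM/Mb. QTL effects are
scaled so each QTL explains its requested fraction of sigma2_a in the
simulated population, and the pedigree-dropped polygenic term carries the
remainder.

What the generator does not emulate: ancestral linkage disequilibrium
(founders are in linkage equilibrium, so only family LD exists), selection
and assortative mating, missing-at-random patterns beyond uniform dropout,
and ordinal score traits (scores are simulated continuous, as they are
modeled). A green recovery test therefore establishes correctness of the
estimation machinery under the model's own assumptions, not robustness to
real-data LD structure. One documented consequence: at h2 = 0.06 the GEBV
backsolve captures only ~30% of sigma2_a with 1000 genotyped animals, so a
2%-of-sigma2_a QTL's window percentage stays below the 0.15% threshold that
was designed for a 114k-SNP panel — the QTL-detection acceptance property
fails honestly at this world's heritability even though the same scan
applied to the true effect vector shows the QTL window at exactly ~2%.

## Numerical choices

- QC comparisons are strict (">"), matching the stated filters; the HWE
  test is a full-enumeration exact test (no mid-p) computed on all genotyped
  individuals (founder-only testing would be cleaner in principle but the
  genotyped set rarely separates founders), monomorphic SNPs return P = 1;
  frequencies are recomputed after individual filtering.
- Missing genotypes surviving QC are mean-imputed (2p) by centering.
- Allele frequencies for G are observed in the genotyped set (base-
  population frequencies are not available in the real data either).
- The MME are solved by dense Cholesky up to 4000 equations, sparse LU
  above, or Jacobi-preconditioned CG on request; direct solutions are
  verified to a 1e-10 relative residual, PCG to 1e-8.
- Matrices keep the pedigree (topological) order throughout; genotyped
  animals are addressed by an explicit index rather than reordered.
- Ratio tables round half away from zero to 2 decimals.

## Known limitations

Dense REML factorization bounds problem size (above); multi-trait fits
require equal designs across traits; no reliability/PEV reporting; no
metafounders, unknown-parent groups, or APY approximation; imputation and
phasing are out of scope (inputs are assumed complete after QC).
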