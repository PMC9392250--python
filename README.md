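# wssgwas

Weighted single-step GWAS for repeated records on pedigreed populations.

Physiological heat-stress indicators in dairy cattle — rectal temperature,
respiratory rate score, drooling score — are lowly heritable traits recorded
repeatedly on lactating cows, with only a subset of the herd genotyped. This
package implements the full mapping pipeline for that setting: genotype
quality control, pedigree (**A**) and genomic (**G**) relationship matrices
combined into the single-step matrix **H**, AI-REML variance components of a
repeatability animal model, genomic breeding values (GEBV) from Henderson's
mixed model equations, iteratively re-weighted SNP effects, a 10-SNP window
variance scan, and gene / differential-expression annotation of significant
regions. A first-class synthetic-data generator (pedigree simulation, gene
dropping, repeated phenotypes with farm-year / parity / lactation-stage /
milking-status effects and a linear THI covariate) makes every stage testable
without animal data.

## Model

The repeatability animal model is

```
y = Xb + Za + Wpe + e,   a ~ N(0, H sigma2_a),  pe ~ N(0, I sigma2_pe),  e ~ N(0, I sigma2_e)
```

with `H^-1 = A^-1 + [[0, 0], [0, G*^-1 - A22^-1]]` over the genotyped block,
`G = Z D Z' / sum_i 2 p_i (1 - p_i)` (VanRaden; `Z` centered gene content,
`D` diagonal SNP weights, initially `I`), and `G* = 0.95 G + 0.05 A22` for
invertibility. After solving the MME, SNP effects are backsolved from the
genotyped animals' GEBV,

```
u_hat = (1/k) D Z' G*^-1 a_hat_g,        d_i = 1.125^(|u_i|/sd(u) - 2)
```

and the weights rebuild `G*` for the next iteration (three by default). The
scan reports, for every window of 10 consecutive SNPs, the variance across
genotyped individuals of the window's summed genomic values as a percentage
of `sigma2_a`; windows at or above 0.15% merge into candidate regions, which
are annotated against GFF3/BED gene models and intersected with an external
differential-expression table (FDR < 0.05, |log2FC| >= 1).

## Worked example

```python
import wssgwas as w

cfg = w.SimulationConfig(
    n_founders=100, n_generations=2, n_per_generation=100,
    n_chromosomes=5, snps_per_chromosome=100,
    n_qtl=1, qtl_variance_fractions=[0.30],
    genotyped_fraction=1.0, genotyped_generations=2, record_sex="all",
    rng_seed=1,
)
data = w.simulate_dataset(cfg)
geno, report = w.run_qc(data.observed_genotypes)

model = w.SingleStepRepeatabilityModel.from_dataframe(
    data.phenotypes.records, "y", data.pedigree, genotypes=geno
)
results = model.fit()
print(results.summary())

scan = results.wssgwas(n_iterations=3).scan(window_size=10)
regions = w.significant_regions(scan, threshold_pct=0.15)
print(regions[["chrom", "start_bp", "end_bp", "max_pct"]])
```

This prints (numbers from this exact seed):

```
Single-step repeatability animal model (REML)
====================================================
trait: y    relationship: H
records: 899    animals: 300    genotyped: 200
REML: ai-em, converged in 11 iterations, logL = -655.8442
----------------------------------------------------
component       estimate          SE
sigma2_a         0.00629     0.00723
sigma2_pe        0.01071     0.01039
sigma2_e         0.21666     0.01263
----------------------------------------------------
heritability  h2 = 0.0269
repeatability t  = 0.0728
G* blend alpha = 0.05, cond(G*) = 223
   chrom  start_bp    end_bp   max_pct
0      1  70247644  84256260  0.217304
1      2     28921  22852247  0.192250
2      2  44136519  53950923  0.173661
3      3    232809  18326844  0.155513
4      3  75195038  82163912  0.152704
5      4  71385789  91671759  0.287718
6      5  46841702  58061648  0.186029
```

`max_pct` is the largest percentage of additive genetic variance explained
by a 10-SNP window inside each merged region. The simulated QTL sits at
49.38 Mb on chromosome 5 and falls inside the reported 46.8-58.1 Mb region;
the remaining regions are small-sample noise hovering at the 0.15%
threshold (200 genotyped animals is far below the scale the threshold was
designed for), and the variance-component estimates carry SEs of their own
magnitude at this size — the acceptance suite checks the calibrated
properties at proper sizes.

A YAML-driven command line covers the same flow stage by stage
(`wssgwas all --config config.yaml`, plus `simulate`, `qc`, `annotate`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the packaged demo end-to-end — simulation, QC, REML, three weighting
iterations, window scan, region merging and annotation against a synthetic
gene set — and writes the JSON target report to `--out`.
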