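# Demo pipeline configuration: simulated herd, full analysis.
# Run:  wssgwas all --config examples/demo_config.yaml --outdir demo_run
simulate:
  n_founders: 100
  n_generations: 2
  n_per_generation: 100
  n_chromosomes: 5
  snps_per_chromosome: 100
  n_qtl: 1
  qtl_variance_fractions: [0.30]
  genotyped_fraction: 1.0
  genotyped_generations: 2
  record_sex: all
trait: y
fixed_factors: [farm_year, parity, stage, milking]
covariates: [thi]
qc:
  min_call_rate: 0.9
  min_maf: 0.05
  hwe_min_p: 1.0e-6
wssgwas:
  n_iterations: 3
  window_size: 10
  window_step: 1
  threshold_pct: 0.15
  cap_sd: 5.0
  blend_alpha: 0.05
outdir: demo_run
rng_seed: 1
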