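# Study-scale synthetic run: 256 ascertained trios plus unrelated cases and
# controls on the 20-SNP SHANK2/SHANK3 panel, default comparison plan.
# Usage: trioassoc run --config examples/config.yaml --out results/run1
seed: 1
n_perm: 10000
sig_threshold: 0.05
gene_n_perm: 1000
qc:
  maf_min: 0.05
  miss_max: 0.10
  hwe_p_min: 0.001
  mendel_max: 0.05
synthetic:
  n_trios: 256
  n_extra_adhd: 42
  n_asd: 134
  n_adhd_asd: 109
  n_controls: 232
  pool_haplotypes: 20000
  within_block_rho: 0.8
  baseline_prevalence: 0.05
  # per_allele_or defaults to the published significant odds ratios
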