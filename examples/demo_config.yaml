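# Demo parameterization for `methcontext run --config examples/demo_config.yaml --out out/`
# Identical to the built-in demo config at seed 0.
simulate:
  seed: 0
  genome_length: 400000
  n_contigs: 2
  gc_content: 0.41
  cgi_count: 120
  cgi_length: 800
  cgi_cpg_density: 0.10
  enzyme_weights: {DNMT1: 1.0, DNMT3A: 0.8, DNMT3B: 0.1}
  baseline: 1.39          # logit units; logistic(1.39) ~ 0.80 genome-wide methylation
  site_noise_sd: 0.5
  coverage_mean: 30.0
  depletion_factors:
    day0: {}
    day4_enzyme: {DNMT1: 0.0}
    day4_cofactor: {DNMT1: 0.05, DNMT3A: 0.05, DNMT3B: 0.05}
  coupled_timepoints: [day4_cofactor]
  histone_coupling: 0.4
  chip_depth: 50.0
  conversion_failure: 0.0
analysis:
  min_coverage: 10
  correlation_method: pearson_values
  symmetrize: [DNMT3A, DNMT3B]
  tile_width: 1000
  diff_threshold: 25.0
  q_threshold: 0.01
  min_cpg: 3
  min_reads: 4
  n_bins: 10
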