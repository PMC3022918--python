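# Small end-to-end demo: sequencing platform, M-scores, fixed +/-1.3 cutoff.
platform: seq
score_method: M
cutoff: "fixed:1.3"
z: 1.96
upper: 3500.0
min_reads: 4
pseudocount: 0.0
tol: 0.01
max_iter: 10
log_level: INFO
sim:
  n_genes: 8
  junctions_per_gene: [8, 14]
  n_tissues: 5
  frac_alternative: 0.3
  delta_magnitude: 2.5
  probe_effect_sd: 1.0
  tissue_baseline_range: [-2.0, 2.0]
  noise_sd: 0.4
  seq_depth_scale: 1000.0
  seed: 20
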