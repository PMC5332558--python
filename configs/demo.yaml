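# Demo configuration: small synthetic DRB-release experiment whose
# configured wave speeds reproduce published-scale elongation rates
# (fast ~1.77/1.72 kb/min untreated, slow ~0.47/0.25 kb/min after UV),
# plus ALE splicing and assay branches. Runs end to end in well under
# five minutes.
seed: 1

annotation:
  n_genes: 4
  length_range: [80000, 110000]
  ale_fraction: 0.5

kinetics:
  conditions: [UN, UV]
  time_points: [10, 25, 40]
  # per-interval speeds (kb/min): fronts at 12.5/39/64.8 kb (UN) and
  # 10.3/17.3/21.0 kb (UV)
  speeds:
    UN: [1.25, 1.7667, 1.72]
    UV: [1.03, 0.4667, 0.2467]
  promoter_height: 20
  promoter_width: 600
  plateau_height: 5
  background: 0.0
  noise: poisson

coverage:
  extension: 250
  target_depth: 20000000
  trim: 0.05

wavefront:
  depth_threshold: 3
  halt_gap: 5000

recovery:
  time_points_hr: [2, 5, 8, 10, 12]
  speed_kb_per_min: 0.04
  n_genes: 20

splicing:
  n_events: 50
  psi_true: {UN: 0.3, UV: 0.8}
  library_size: 10000
  min_reads: 10
  min_bf: 10
  min_si: 0.25

assay:
  fold_change: 4.0
  low_weight: 0.4
  control_low_weight: 0.2
  threshold: 600
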