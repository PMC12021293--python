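# Familiarity detection with an isolated E->E rule (adaptive-threshold
# network variant): after repeated presentations of one input subset, the
# network must respond more strongly to it than to a disjoint novel subset.
variant: zenke
scale: desk
space: small
plastic_blocks: [ee]
task:
  kind: familiarity
  n_reps: 10
  multiplier: 4.0
es:
  popsize: 12
  n_trials: 4
  max_iterations: 40
lambda_l1: 0.01
seed: 1
outdir: results/familiarity_small_ee
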