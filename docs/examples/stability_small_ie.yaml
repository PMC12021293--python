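# Scaled-down stability experiment: discover an isolated I->E rule from the
# small polynomial space that holds the excitatory population at 10 Hz.
# Run with:  metaplast meta-learn docs/examples/stability_small_ie.yaml
variant: vogels
scale: desk
space: small
plastic_blocks: [ie]
task:
  kind: stability
  duration_ms: 10000
  target_rate: 10.0
es:
  popsize: 12
  n_trials: 4
  max_iterations: 40
lambda_l1: 0.01
seed: 1
outdir: results/stability_small_ie
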