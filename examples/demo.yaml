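# Fully synthetic demonstration run: plants 3 divergent lncRNA/coding-gene
# pairs among 50 decoy transcripts, simulates a duplicate two-condition
# array, a 51-patient paired cohort and a stratified single-cell population,
# then runs every analysis stage.  `cispairs run-all --config examples/demo.yaml`
out_dir: cispairs_demo
simulate: true
generator:
  seed: 1
filter:
  floor: 50.0
  min_samples: 2
fc_threshold: 2.0
max_distance: 500000
bootstrap_B: 2000
level: 0.95
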