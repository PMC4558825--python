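# Full-pipeline configuration for the default settlement scenario.
# Run:  uniline run --config examples/settlement.cfg --outdir out --seed 17
bootstrap_reps: 1000
assay_max_samples: 70
tree_max_samples: 40
sim.n_male_founders: 9
sim.n_female_founders: 12
sim.generations: 11
sim.offspring_rate: 3.0
sim.max_pop: 1400
sim.polynesian_b_prob: 0.9
sim.dropout_rate: 0.0
sim.false_positive_rate: 0.0
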