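# Small mixed-cardinality space (5 x 4 x 3 = 60 cells) with skewed
# marginals and heterogeneous correlations; population of 300 leaves a
# mid-range unique fraction so both uniqueness routes have signal.
name: tiny_mixed
population_size: 300
seed: 20260902
attributes:
  - {name: a, kind: ordinal, family: categorical, probs: {recipe: zipf, K: 5, s: 1.0}}
  - {name: b, kind: ordinal, family: categorical, probs: {recipe: zipf, K: 4, s: 0.8}}
  - {name: c, kind: ordinal, family: categorical, probs: [0.5, 0.3, 0.2]}
sigma:
  - [1.0, 0.4, 0.2]
  - [0.4, 1.0, 0.3]
  - [0.2, 0.3, 1.0]
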