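# Three correlated binary attributes in a toy population small enough
# for exhaustive enumeration (8 cells): exercises the exact-vs-simulated
# uniqueness cross-check.
name: tiny_binary
population_size: 60
seed: 20260901
attributes:
  - {name: a, kind: ordinal, family: categorical, probs: [0.6, 0.4]}
  - {name: b, kind: ordinal, family: categorical, probs: [0.55, 0.45]}
  - {name: c, kind: ordinal, family: categorical, probs: [0.7, 0.3]}
sigma: {recipe: constant, value: 0.5}
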