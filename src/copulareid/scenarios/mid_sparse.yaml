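# Census-like scenario: four ordinal attributes with Zipf-skewed
# prevalences (20,736 cells) in a population of 100,000 — low-to-mid
# population uniqueness (~0.05) driven by the rare tail.
name: mid_sparse
population_size: 100000
seed: 20260903
attributes:
  - {name: a, kind: ordinal, family: categorical, probs: {recipe: zipf, K: 12, s: 1.2}}
  - {name: b, kind: ordinal, family: categorical, probs: {recipe: zipf, K: 12, s: 1.2}}
  - {name: c, kind: ordinal, family: categorical, probs: {recipe: zipf, K: 12, s: 1.0}}
  - {name: d, kind: ordinal, family: categorical, probs: {recipe: zipf, K: 12, s: 1.0}}
sigma: {recipe: constant, value: 0.3}
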