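# High-cardinality scenario: five attributes, 172,800 cells with mild
# skew, population 100,000 — high population uniqueness (~0.4 under the
# scaled-down cardinality cap), mimicking detailed demographic
# combinations (e.g. birth date x location codes).
name: high_card
population_size: 100000
seed: 20260904
attributes:
  - {name: a, kind: ordinal, family: categorical, probs: {recipe: zipf, K: 12, s: 0.5}}
  - {name: b, kind: ordinal, family: categorical, probs: {recipe: zipf, K: 12, s: 0.5}}
  - {name: c, kind: ordinal, family: categorical, probs: {recipe: zipf, K: 12, s: 0.5}}
  - {name: d, kind: ordinal, family: categorical, probs: {recipe: zipf, K: 10, s: 0.5}}
  - {name: e, kind: ordinal, family: categorical, probs: {recipe: zipf, K: 10, s: 0.5}}
sigma: {recipe: constant, value: 0.45}
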