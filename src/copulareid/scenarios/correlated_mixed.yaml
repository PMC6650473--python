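# Mixed-family scenario: two heavy-tailed log-series attributes (count-
# like, e.g. household size) and two Zipf categoricals, coupled by
# heterogeneous correlations up to 0.6; 10,000 cells, population
# 100,000 — low uniqueness (~0.02).  All attributes are ordinal: the
# latent-copula ground truth carries ordered dependence by construction,
# so a nominal declaration would inject category-order misspecification
# that real order-free attributes do not have.
name: correlated_mixed
population_size: 100000
seed: 20260905
attributes:
  - {name: a, kind: ordinal, family: logarithmic, p: 0.85, K: 10}
  - {name: b, kind: ordinal, family: logarithmic, p: 0.8, K: 10}
  - {name: c, kind: ordinal, family: categorical, probs: {recipe: zipf, K: 10, s: 1.2}}
  - {name: d, kind: ordinal, family: categorical, probs: {recipe: zipf, K: 10, s: 1.0}}
sigma:
  - [1.0, 0.6, 0.3, 0.2]
  - [0.6, 1.0, 0.4, 0.3]
  - [0.3, 0.4, 1.0, 0.5]
  - [0.2, 0.3, 0.5, 1.0]
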