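# copulareid

Gaussian-copula estimation of re-identification risk in sampled discrete
microdata.

## The problem

Organizations release individual-level tables (census extracts, surveys,
health records) after removing direct identifiers and often after heavy
subsampling, on the argument that a record found in a small sample cannot
be confidently tied to a specific person. `copulareid` quantifies that
argument. Given a uniform sample **D** of n_D records with d discrete
(nominal or ordinal) attributes, drawn from a population of known size n,
it estimates for any record x:

- **uniqueness** ξ_x = (1 − p(x))^(n−1) — the probability that nobody
  else in the population shares x's attribute combination;
- **correctness** κ_x = (1/(n p(x)))(1 − (1 − p(x))^n) — the probability
  that matching on x picks the right person, i.e. E[1/(T+1)] with
  T ~ Binomial(n−1, p(x)) false-positive candidates; equivalently
  κ = (1/n)(1 − ξ^{n/(n−1)})/(1 − ξ^{1/(n−1)});
- **population uniqueness** Ξ = Σ_x p(x)(1 − p(x))^(n−1) — the expected
  fraction of the population unique on the attribute set.

The unknown cell probability p(x) is modeled generatively: each marginal
law Ψ_j is fitted by maximum likelihood over categorical,
negative-binomial and log-series families and selected by
BIC = −2 log L̂ + k log n_D; the dependence is a latent Gaussian copula
whose correlation matrix Σ is inferred one pair at a time by matching
adjusted mutual information, then projected onto the positive
semidefinite cone. A record's probability is the multivariate-normal mass
of the latent rectangle Π_j (Φ⁻¹(F_j(x_j − 1)), Φ⁻¹(F_j(x_j))], computed
by randomized quasi-Monte-Carlo integration.

The package is aimed at statistical-disclosure-control practitioners,
data-protection officers evaluating "anonymized" releases, and privacy
researchers who need a per-record risk score rather than a dataset-level
summary.

## Worked example

Fit on a 1% sample of a shipped synthetic ground-truth population
(100,000 people, four Zipf-skewed attributes, latent correlation 0.3):

```python
import numpy as np
from copulareid import GaussianCopulaRisk, make_scenario

scenario = make_scenario("mid_sparse")          # 100,000-person ground truth
sample = scenario.population[
    np.random.default_rng(0).choice(100_000, 1_000, replace=False)]

model = GaussianCopulaRisk(population_size=100_000, random_state=42)
model.fit(sample)                               # marginals + latent Sigma

est = model.population_uniqueness(seed=1, n_trials=5)
print(f"estimated population uniqueness: {est.xi_pop:.3f} "
      f"(+- {est.mc_error:.3f})")
print(f"actual unique fraction:          "
      f"{scenario.empirical_uniqueness():.3f}")

record = np.array([[12, 11, 9, 5]])             # one rare combination
scores = model.score_records(record)
print(f"record uniqueness  xi-hat    = {scores.xi_hat[0]:.3f}")
print(f"record correctness kappa-hat = {scores.kappa_hat[0]:.3f}")
```

prints

```
estimated population uniqueness: 0.054 (+- 0.000)
actual unique fraction:          0.054
record uniqueness  xi-hat    = 0.527
record correctness kappa-hat = 0.738
```

Trained on 1,000 of 100,000 records, the model recovers the population's
5.4% unique fraction, and flags the rare combination (12, 11, 9, 5) as
unique with probability 0.53 — so an attacker matching on it would name
the right person 74% of the time.

A command-line interface mirrors the library:

```sh
copulareid fit sample.csv config.yaml --out model/
copulareid score model/ release.csv config.yaml --out scores.csv
copulareid uniqueness model/ --trials 10
copulareid generate model/ --n 100000 --out synthetic.csv
copulareid benchmark scenario.yaml --out report.json
```

Scoring refuses to run when the training sample held fewer than 50
records (override with `--allow-small-sample`).

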