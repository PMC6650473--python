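"""Ground-truth synthetic scenarios and the evaluation harness.

A scenario is a fully specified generative model (known marginals and
latent correlations) plus one population drawn from it.  Because the
truth is available by construction, the harness can measure what no real
release allows: the error of the estimated population uniqueness under
subsampling, ROC/AUC and false-discovery rates for per-record uniqueness
prediction against exhaustively counted labels, and calibration (Brier
score) against the best constant population-level predictor
xi^(pop) = Xi_X.

All experiment randomness flows from one root seed through
numpy.random.SeedSequence.spawn, so any report cell is reproducible in
isolation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from sklearn.metrics import roc_auc_score

from . import risk
from ._seeding import seed_seq
from .copula import CopulaModel
from .estimator import GaussianCopulaRisk
from .marginals import (MarginalModel, categorical_marginal,
                        logarithmic_marginal, negative_binomial_marginal)

#: scenarios shipped with the package
SMALL_SUITE = ("tiny_binary", "tiny_mixed")
STANDARD_SUITE = ("mid_sparse", "high_card", "correlated_mixed")
ALL_SCENARIOS = SMALL_SUITE + STANDARD_SUITE

#: classification thresholds reported by default
DEFAULT_THRESHOLDS = (0.9, 0.95, 0.99)

#: sample spaces at most this large get exact cell probabilities
EXACT_CELL_CAP = 10_000


class ScenarioSpecError(ValueError):
    pass


@dataclass
class GroundTruthScenario:
    """A synthetic population with its generating model known exactly."""
    name: str
    true_sigma: np.ndarray
    true_marginals: list[MarginalModel]
    kinds: list[str]
    population: np.ndarray
    population_size: int
    seed: int
    spec: dict = field(default_factory=dict)
    _exact: tuple | None = field(default=None, repr=False)

    @property
    def model(self) -> CopulaModel:
        return CopulaModel(sigma=self.true_sigma,
                           marginals=self.true_marginals,
                           population_size=self.population_size)

    @property
    def n_cells(self) -> int:
        return int(np.prod([m.K for m in self.true_marginals]))

    def _enumerate(self):
        if self._exact is None:
            if self.n_cells > EXACT_CELL_CAP:
                raise ScenarioSpecError(
                    f"scenario {self.name!r}: sample space has "
                    f"{self.n_cells} cells, above the exact-enumeration cap")
            cells = risk._enumerate_cells([m.K for m in self.true_marginals])
            self._exact = (cells, self.model.cell_probabilities(cells))
        return self._exact

    @property
    def exact_cells(self) -> np.ndarray:
        return self._enumerate()[0]

    @property
    def exact_cell_probs(self) -> np.ndarray:
        """Per-cell p(x), enumerated on demand for small sample spaces."""
        return self._enumerate()[1]

    def empirical_uniqueness(self) -> float:
        return risk.empirical_uniqueness(self.population)

    def exact_uniqueness(self) -> float:
        p = self.exact_cell_probs
        return float(np.sum(p * risk.individual_uniqueness(
            p, self.population_size)))


def _zipf_probs(K: int, s: float) -> np.ndarray:
    w = np.arange(1, K + 1, dtype=float) ** (-s)
    return w / w.sum()


def _marginal_from_spec(att: dict) -> MarginalModel:
    family = att.get("family", "categorical")
    if family == "categorical":
        probs = att["probs"]
        if isinstance(probs, dict):
            if probs.get("recipe") != "zipf":
                raise ScenarioSpecError(f"unknown probs recipe {probs!r}")
            probs = _zipf_probs(int(probs["K"]), float(probs["s"]))
        return categorical_marginal(np.asarray(probs, dtype=float))
    if family == "logarithmic":
        return logarithmic_marginal(float(att["p"]), int(att["K"]))
    if family == "negative_binomial":
        return negative_binomial_marginal(float(att["r"]), float(att["theta"]),
                                          int(att["K"]))
    raise ScenarioSpecError(f"unknown marginal family {family!r}")


def _sigma_from_spec(spec, d: int) -> np.ndarray:
    if isinstance(spec, dict):
        if spec.get("recipe") == "constant":
            sigma = np.full((d, d), float(spec["value"]))
            np.fill_diagonal(sigma, 1.0)
            return sigma
        raise ScenarioSpecError(f"unknown sigma recipe {spec!r}")
    sigma = np.asarray(spec, dtype=float)
    if sigma.shape != (d, d):
        raise ScenarioSpecError("sigma shape does not match attribute count")
    if not np.allclose(sigma, sigma.T) or not np.allclose(np.diag(sigma), 1.0):
        raise ScenarioSpecError("sigma must be symmetric with unit diagonal")
    if np.linalg.eigvalsh(sigma).min() < -1e-10:
        raise ScenarioSpecError("sigma must be positive semidefinite")
    return sigma


def load_scenario_spec(name: str) -> dict:
    """Load one of the shipped scenario specs by name."""
    ref = importlib.resources.files("copulareid") / "scenarios" / f"{name}.yaml"
    with ref.open() as fh:
        return yaml.safe_load(fh)


def make_scenario(spec, seed=None) -> GroundTruthScenario:
    """Instantiate a scenario: build the true model and draw its population.

    ``spec`` is a mapping (see the shipped YAML files) or the name of a
    shipped scenario.  ``seed`` overrides the spec's default seed.  Exact
    per-cell probabilities are enumerated when the sample space has at
    most ``EXACT_CELL_CAP`` cells.
    """
    if isinstance(spec, str):
        spec = load_scenario_spec(spec)
    n = int(spec["population_size"])
    if n < 1:
        raise ScenarioSpecError("population_size must be >= 1")
    atts = spec["attributes"]
    margs = [_marginal_from_spec(a) for a in atts]
    kinds = [a.get("kind", "ordinal") for a in atts]
    sigma = _sigma_from_spec(spec["sigma"], len(atts))
    seed = int(spec.get("seed", 0)) if seed is None else int(seed)
    model = CopulaModel(sigma=sigma, marginals=margs, population_size=n)
    population = model.sample(n, seed=np.random.SeedSequence(seed))
    return GroundTruthScenario(name=spec.get("name", "scenario"),
                               true_sigma=sigma, true_marginals=margs,
                               kinds=kinds, population=population,
                               population_size=n, seed=seed, spec=spec)


# -- scalar metrics --------------------------------------------------------

def brier_score(scores, labels) -> float:
    """Mean squared error between probabilistic scores and binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape or scores.size == 0:
        raise ValueError("scores and labels must be equal-length, non-empty")
    return float(np.mean((labels - scores) ** 2))


def fdr_at_threshold(scores, labels, tau: float):
    """Among records scored above tau, the fraction not actually unique.

    Returns None (undefined) when no score exceeds tau.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    above = scores > tau
    if not above.any():
        return None
    return float(np.mean(labels[above] == 0))


def roc_auc(scores, labels):
    """Rank-based AUC with mid-rank tie handling; None on one-class labels."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return None
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# -- experiment harness ----------------------------------------------------

@dataclass
class EvaluationReport:
    """Results of one harness run; unused fields stay None."""
    scenario: str
    n_trials: int
    config: dict = field(default_factory=dict)
    per_fraction: list = field(default_factory=list)
    auc: float | None = None
    fdr_at: dict | None = None
    brier_model: float | None = None
    brier_baseline: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _fit_on_sample(sample, scenario, seed, **est_kwargs):
    est = GaussianCopulaRisk(population_size=scenario.population_size,
                             kinds=scenario.kinds, random_state=seed,
                             **est_kwargs)
    return est.fit(sample)


def sampling_experiment(scenario: GroundTruthScenario, fractions,
                        trials: int = 10, seed=None,
                        uniqueness_trials: int = 5,
                        **est_kwargs) -> EvaluationReport:
    """Mean absolute error of estimated population uniqueness under
    subsampling.

    For each fraction and trial: subsample the population, fit the model,
    estimate Xi on synthetic populations, and record the absolute error
    against the population's actual unique fraction.  Fractions whose
    sample would hold fewer than 50 records are skipped and flagged.
    """
    ss = seed_seq(seed)
    truth = scenario.empirical_uniqueness()
    report = EvaluationReport(scenario=scenario.name, n_trials=trials,
                              config={"fractions": list(fractions),
                                      "truth": truth})
    n_pop = scenario.population.shape[0]
    for fraction in fractions:
        n_rows = int(np.floor(fraction * n_pop + 0.5))
        entry = {"fraction": fraction, "n_rows": n_rows, "skipped": False,
                 "errors": []}
        if n_rows < risk.MIN_TRAINING_RECORDS:
            entry["skipped"] = True
            report.per_fraction.append(entry)
            continue
        for child in ss.spawn(trials):
            sub_seed, fit_seed, xi_seed = child.spawn(3)
            idx = np.random.default_rng(sub_seed).choice(
                n_pop, size=n_rows, replace=False)
            est = _fit_on_sample(scenario.population[idx], scenario,
                                 fit_seed, **est_kwargs)
            xi_hat = est.population_uniqueness(
                seed=xi_seed, n_trials=uniqueness_trials).xi_pop
            entry["errors"].append(abs(xi_hat - truth))
        errs = np.array(entry["errors"])
        entry["mae_mean"] = float(errs.mean())
        entry["mae_sd"] = float(errs.std(ddof=1)) if trials > 1 else 0.0
        report.per_fraction.append(entry)
    return report


def uniqueness_classification(scenario: GroundTruthScenario,
                              train_fraction: float = 0.01,
                              n_test: int = 1000, seed=None,
                              thresholds=DEFAULT_THRESHOLDS,
                              **est_kwargs) -> EvaluationReport:
    """Predict individual population uniqueness on held-out records.

    Trains on a single ``train_fraction`` sample, scores ``n_test``
    records drawn from the population disjointly from the training rows,
    and labels each by exhaustive counting (1 iff its full vector occurs
    once in the population).  Reports AUC, FDR at the thresholds, the
    model's Brier score, and the Brier score of the constant baseline
    xi^(pop) = Xi_X.
    """
    ss = seed_seq(seed)
    split_seed, fit_seed = ss.spawn(2)
    n_pop = scenario.population.shape[0]
    n_train = int(np.floor(train_fraction * n_pop + 0.5))
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(n_pop)
    train_idx = perm[:n_train]
    test_idx = rng.choice(perm[n_train:], size=n_test, replace=False)
    test = scenario.population[test_idx]

    _, inverse, counts = np.unique(scenario.population, axis=0,
                                   return_inverse=True, return_counts=True)
    labels = (counts[inverse] == 1)[test_idx].astype(int)

    est = _fit_on_sample(scenario.population[train_idx], scenario, fit_seed,
                         **est_kwargs)
    scores = est.predict(test)
    baseline = np.full(n_test, scenario.empirical_uniqueness())
    report = EvaluationReport(
        scenario=scenario.name, n_trials=1,
        config={"train_fraction": train_fraction, "n_test": n_test,
                "n_train": n_train},
        auc=roc_auc(scores, labels),
        fdr_at={tau: fdr_at_threshold(scores, labels, tau)
                for tau in thresholds},
        brier_model=brier_score(scores, labels),
        brier_baseline=brier_score(baseline, labels))
    return report


def perturbation_analysis(record, model: CopulaModel, attribute: int,
                          mode: str = "replace", n_draws: int = 100,
                          seed=None, wider_model: CopulaModel | None = None):
    """Distribution of xi-hat when one attribute is randomly perturbed.

    ``replace`` resamples the value of ``attribute`` from its marginal in
    ``model``; ``add`` appends a draw of attribute ``attribute`` of
    ``wider_model`` (a model over the original attributes plus the added
    one, in that order).  Returns (baseline_xi, xi_draws).
    """
    record = np.asarray(record, dtype=np.int64).ravel()
    rng = np.random.default_rng(seed)
    n = model.population_size
    baseline = risk.individual_uniqueness(model.cell_probability(record), n)
    if mode == "replace":
        if not 0 <= attribute < model.n_attributes:
            raise ValueError(f"attribute index {attribute} out of range")
        marg = model.marginals[attribute]
        draws = marg.quantile(rng.random(n_draws))
        recs = np.tile(record, (n_draws, 1))
        recs[:, attribute] = draws
        q = model.cell_probabilities(recs)
        return baseline, risk.individual_uniqueness(q, n)
    if mode == "add":
        if wider_model is None:
            raise ValueError("mode='add' needs the wider model containing "
                             "the extra attribute")
        if not 0 <= attribute < wider_model.n_attributes:
            raise ValueError(f"attribute index {attribute} out of range in "
                             f"the wider model")
        marg = wider_model.marginals[attribute]
        draws = marg.quantile(rng.random(n_draws))
        base_cols = [j for j in range(wider_model.n_attributes)
                     if j != attribute]
        recs = np.empty((n_draws, wider_model.n_attributes), dtype=np.int64)
        recs[:, base_cols] = record
        recs[:, attribute] = draws
        q = wider_model.cell_probabilities(recs)
        return baseline, risk.individual_uniqueness(
            q, wider_model.population_size)
    raise ValueError("mode must be 'replace' or 'add'")
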