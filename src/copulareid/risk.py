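"""Uniqueness and correctness calculus, and population uniqueness.

For a record x with population frequency p(x) in a population of size n:

* uniqueness  xi_x = (1 - p(x))^{n-1} — the chance that nobody else in
  the population shares x's attribute combination;
* correctness kappa_x = (1/(n p))(1 - (1-p)^n) — the chance that matching
  on x picks the right person, i.e. E[1/(T+1)] with T ~ Binomial(n-1, p)
  false-positive candidates; equivalently, in terms of uniqueness,
  kappa = (1/n)(1 - xi^{n/(n-1)}) / (1 - xi^{1/(n-1)}).

Population uniqueness Xi = sum_x p(x)(1-p(x))^{n-1} is the expected
fraction of the population unique on the attribute set; it is computed
either by exhaustive enumeration of the sample space or empirically on
synthetic populations drawn from the model.

All powers are taken in log space (log1p/expm1), stable for n ~ 1e8 and
p down to the underflow threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeding import seed_seq
from .copula import CopulaModel

#: training samples below this size refuse to score by default
MIN_TRAINING_RECORDS = 50


class GuardError(RuntimeError):
    """Raised when the training sample is too small to score reliably."""


class CapacityError(RuntimeError):
    """Raised when exhaustive enumeration would exceed the configured cap."""


def individual_uniqueness(q, n: int):
    """xi = (1 - q)^{n-1}: probability of being population-unique."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("q must lie in [0, 1]")
    if n < 1:
        raise ValueError("population size must be >= 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(q >= 1.0, 1.0 if n == 1 else 0.0,
                       np.exp((n - 1) * np.log1p(-np.minimum(q, 1 - 1e-300))))
    return out if out.ndim else float(out)


def correctness_from_p(q, n: int):
    """kappa = (1/(n q))(1 - (1-q)^n), with the q -> 0 limit equal to 1.

    Equals the binomial expectation sum_k P(T = k)/(k + 1) over the
    number of false positives T ~ B(n-1, q).
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("q must lie in [0, 1]")
    if n < 1:
        raise ValueError("population size must be >= 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        body = -np.expm1(n * np.log1p(-np.minimum(q, 1 - 1e-300)))
        out = np.where(q == 0.0, 1.0,
                       np.where(q >= 1.0, 1.0 / n,
                                body / (n * np.where(q == 0, 1.0, q))))
    return out if out.ndim else float(out)


def correctness_from_uniqueness(xi, n: int):
    """kappa expressed through uniqueness: (1/n)(1-xi^{n/(n-1)})/(1-xi^{1/(n-1)}).

    Algebraically identical to :func:`correctness_from_p` after
    q = 1 - xi^{1/(n-1)}; xi = 1 is the always-correct limit.  For large n
    this approaches (1 - xi) / (-ln xi).
    """
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0) or np.any(xi > 1):
        raise ValueError("xi must lie in [0, 1]")
    if n < 2:
        raise ValueError("population size must be >= 2")
    with np.errstate(divide="ignore", invalid="ignore"):
        # log(0) -> -inf -> expm1 -> -1 gives q = 1, the correct xi = 0 limit
        q = np.where(xi == 0.0, 1.0, -np.expm1(np.log(xi) / (n - 1)))
    out = correctness_from_p(np.clip(q, 0.0, 1.0), n)
    out = np.where(xi == 1.0, 1.0, out)
    return out if out.ndim else float(out)


@dataclass
class UniquenessEstimate:
    """Population uniqueness Xi with its provenance."""
    xi_pop: float
    method: str  # "exact_enumeration" or "synthetic_population"
    mc_error: float = 0.0  # between-trial standard error when simulated
    n_trials: int = 1

    def __post_init__(self):
        if not (0.0 <= self.xi_pop <= 1.0 + 1e-9):
            raise ValueError("Xi must lie in [0, 1]")


def empirical_uniqueness(records) -> float:
    """Fraction of rows whose full attribute vector occurs exactly once."""
    records = np.atleast_2d(np.asarray(records))
    if records.shape[0] < 1:
        raise ValueError("at least one record is required")
    _, inverse, counts = np.unique(records, axis=0, return_inverse=True,
                                   return_counts=True)
    return float(np.mean(counts[inverse] == 1))


def _enumerate_cells(cardinalities):
    grids = np.meshgrid(*[np.arange(1, k + 1) for k in cardinalities],
                        indexing="ij")
    return np.column_stack([g.ravel() for g in grids])


def population_uniqueness_exact(model: CopulaModel,
                                cell_cap: int = 100_000) -> UniquenessEstimate:
    """Xi by exhaustive enumeration of the sample space.

    Refuses (CapacityError) when the sample space exceeds ``cell_cap``
    cells; use the empirical route instead.
    """
    cards = [m.K for m in model.marginals]
    n_cells = int(np.prod(cards))
    if n_cells > cell_cap:
        raise CapacityError(
            f"sample space has {n_cells} cells (cap {cell_cap}); use "
            f"population_uniqueness_empirical")
    cells = _enumerate_cells(cards)
    q = model.cell_probabilities(cells)
    xi = float(np.sum(q * individual_uniqueness(q, model.population_size)))
    return UniquenessEstimate(xi_pop=min(xi, 1.0), method="exact_enumeration")


def population_uniqueness_empirical(model: CopulaModel, seed=None,
                                    n_trials: int = 5) -> UniquenessEstimate:
    """Xi by sampling synthetic populations of size n from the model.

    Averages the empirically unique fraction over ``n_trials`` populations
    and reports the between-trial standard error.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ss = seed_seq(seed)
    vals = np.array([
        empirical_uniqueness(model.sample(model.population_size, seed=child))
        for child in ss.spawn(n_trials)])
    se = float(vals.std(ddof=1) / np.sqrt(n_trials)) if n_trials > 1 else 0.0
    return UniquenessEstimate(xi_pop=float(vals.mean()),
                              method="synthetic_population",
                              mc_error=se, n_trials=n_trials)


@dataclass
class RiskScores:
    """Per-record risk scores with provenance."""
    xi_hat: np.ndarray
    kappa_hat: np.ndarray
    sample_unique: np.ndarray
    population_size: int
    model_fingerprint: str = ""
    restricted_to_sample_uniques: bool = False
    integration_error: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"xi_hat": self.xi_hat,
                             "kappa_hat": self.kappa_hat,
                             "sample_unique": self.sample_unique})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def sidecar(self) -> dict:
        return {"population_size": int(self.population_size),
                "model_fingerprint": self.model_fingerprint,
                "restricted_to_sample_uniques":
                    bool(self.restricted_to_sample_uniques)}


def score_dataset(model: CopulaModel, records,
                  restrict_sample_unique: bool = False,
                  allow_small_sample: bool = False) -> RiskScores:
    """Score each record's uniqueness xi-hat and correctness kappa-hat.

    Refuses to score when the model's training sample held fewer than
    50 records, unless explicitly overridden — small samples make the
    estimates unreliable rather than silently degraded.  When
    ``restrict_sample_unique`` is set, all records are still scored but
    non-sample-unique rows are flagged (only sample uniques can be
    population uniques under uniform subsampling).
    """
    records = np.atleast_2d(np.asarray(records, dtype=np.int64))
    if records.shape[1] != model.n_attributes:
        raise ValueError("records do not conform to the model's schema")
    if (model.n_train is not None and model.n_train < MIN_TRAINING_RECORDS
            and not allow_small_sample):
        raise GuardError(
            f"training sample had {model.n_train} records (< "
            f"{MIN_TRAINING_RECORDS}); pass allow_small_sample=True to "
            f"override")
    q, err = model.cell_probabilities(records, return_err=True)
    n = model.population_size
    xi = individual_uniqueness(q, n)
    kappa = correctness_from_p(q, n)
    _, inverse, counts = np.unique(records, axis=0, return_inverse=True,
                                   return_counts=True)
    return RiskScores(xi_hat=xi, kappa_hat=kappa,
                      sample_unique=counts[inverse] == 1,
                      population_size=n,
                      model_fingerprint=model.fingerprint(),
                      restricted_to_sample_uniques=restrict_sample_unique,
                      integration_error=err)
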