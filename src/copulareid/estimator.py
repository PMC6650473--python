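"""Scikit-learn-style estimator for copula-based re-identification risk.

``GaussianCopulaRisk.fit`` learns, from a uniform sample of a population
of declared size, each attribute's marginal law (BIC-selected) and the
latent pairwise correlation matrix (mutual-information-calibrated, then
projected to the PSD cone).  ``predict`` returns each record's estimated
likelihood of being unique in the full population; ``correctness``
returns the likelihood that a matched re-identification is correct.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator

from . import association, marginals, risk
from ._seeding import seed_seq
from .copula import CopulaModel
from .microdata import MicrodataTable


def _as_code_matrix(X):
    if isinstance(X, MicrodataTable):
        return X.rows, X.kinds
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix of integer codes")
    if X.shape[0] < 1:
        raise ValueError("X must contain at least one record")
    codes = X.astype(np.int64)
    if not np.array_equal(codes, np.asarray(X, dtype=float)):
        raise ValueError("X must contain integer codes")
    if codes.min() < 1:
        raise ValueError("codes are 1-based; 0 is the integration sentinel")
    return codes, None


class GaussianCopulaRisk(BaseEstimator):
    """Generative Gaussian-copula model of discrete microdata risk.

    Parameters
    ----------
    population_size : size n of the complete population the training
        sample was drawn from (required at fit time)
    kinds : "ordinal", "nominal", or a per-attribute list; nominal
        attributes get a seeded random category order at fit time
    families : candidate marginal families for BIC selection
    exact_marginals : optional dict {attribute index: per-code population
        counts} supplying exogenous exact marginals; those attributes skip
        fitting (association inference is unchanged)
    cardinalities : optional per-attribute support sizes when the sample
        may not exhibit every code
    mc_sample_size : size of the synthetic bivariate sample behind the
        pairwise-sigma objective; default max(10000, n_D)
    n_perm : permutations for the adjusted-MI chance correction
    use_adjusted_mi : match adjusted (default) rather than raw MI
    sigma_bounds : search domain of each pairwise correlation
    eigen_floor : eigenvalue floor of the PSD projection
    abs_tol, max_points : rectangle-integration accuracy/budget
    min_records : scoring guard threshold on the training-sample size
    allow_small_sample : override the guard
    random_state : root seed; all internal randomness (category orders,
        common random numbers, permutations) derives from it

    Attributes (after fit)
    ----------------------
    marginals_ : list of fitted MarginalModel
    pairwise_ : dict {(i, j): PairwiseAssociation}
    sigma_ : (d, d) latent correlation matrix, PSD-projected
    model_ : the assembled CopulaModel
    n_features_in_ : number of attributes d
    """

    def __init__(self, population_size=None, kinds="ordinal",
                 families=marginals.FAMILIES, exact_marginals=None,
                 cardinalities=None, mc_sample_size=None, n_perm=25,
                 use_adjusted_mi=True, sigma_bounds=(0.0, 1.0),
                 eigen_floor=1e-6, abs_tol=1e-6, max_points=2 ** 17,
                 min_records=risk.MIN_TRAINING_RECORDS,
                 allow_small_sample=False, random_state=None):
        self.population_size = population_size
        self.kinds = kinds
        self.families = families
        self.exact_marginals = exact_marginals
        self.cardinalities = cardinalities
        self.mc_sample_size = mc_sample_size
        self.n_perm = n_perm
        self.use_adjusted_mi = use_adjusted_mi
        self.sigma_bounds = sigma_bounds
        self.eigen_floor = eigen_floor
        self.abs_tol = abs_tol
        self.max_points = max_points
        self.min_records = min_records
        self.allow_small_sample = allow_small_sample
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y=None):
        codes, table_kinds = _as_code_matrix(X)
        n_rows, d = codes.shape
        if not isinstance(self.population_size, numbers.Integral) or \
                self.population_size < 1:
            raise ValueError("population_size must be a positive integer")
        if self.population_size < n_rows:
            raise ValueError("population_size cannot be smaller than the "
                             "training sample")
        kinds = table_kinds if table_kinds is not None else self.kinds
        if isinstance(kinds, str):
            kinds = [kinds] * d
        if len(kinds) != d:
            raise ValueError("kinds must match the number of attributes")

        ss = seed_seq(self.random_state)
        marg_seeds, pair_ss = ss.spawn(2)
        marg_seeds = marg_seeds.spawn(d)
        exact = dict(self.exact_marginals or {})
        cards = self.cardinalities or [None] * d

        self.marginals_ = []
        for j in range(d):
            if j in exact:
                self.marginals_.append(marginals.exact_marginal(exact[j]))
            else:
                self.marginals_.append(marginals.fit_marginal(
                    codes[:, j], kind=kinds[j], families=self.families,
                    seed=marg_seeds[j], cardinality=cards[j]))

        mc = self.mc_sample_size or max(10_000, n_rows)
        pair_seeds = pair_ss.spawn(d * (d - 1) // 2)
        self.pairwise_ = {}
        idx = 0
        for i in range(d):
            for j in range(i + 1, d):
                pair = association.infer_pairwise_sigma(
                    codes[:, i], codes[:, j],
                    self.marginals_[i], self.marginals_[j],
                    mc_sample_size=mc, n_perm=self.n_perm,
                    seed=pair_seeds[idx], use_adjusted=self.use_adjusted_mi,
                    sigma_bounds=self.sigma_bounds)
                pair.i, pair.j = i, j
                self.pairwise_[(i, j)] = pair
                idx += 1
        raw = association.assemble_covariance(self.pairwise_, d)
        self.sigma_ = association.project_psd(raw, eigen_floor=self.eigen_floor)
        self.model_ = CopulaModel(
            sigma=self.sigma_, marginals=self.marginals_,
            population_size=int(self.population_size), n_train=n_rows,
            abs_tol=self.abs_tol, max_points=self.max_points,
            integration_seed=int(ss.generate_state(1)[0] % (2 ** 31)))
        self.n_features_in_ = d
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this estimator is not fitted yet")

    # -- scoring ----------------------------------------------------------
    def predict(self, X):
        """Per-record estimated uniqueness xi-hat in [0, 1]."""
        return self.score_records(X).xi_hat

    def correctness(self, X):
        """Per-record estimated correctness kappa-hat in [1/n, 1]."""
        return self.score_records(X).kappa_hat

    def score_records(self, X, restrict_sample_unique: bool = False
                      ) -> risk.RiskScores:
        self._check_fitted()
        codes, _ = _as_code_matrix(X)
        return risk.score_dataset(
            self.model_, codes, restrict_sample_unique=restrict_sample_unique,
            allow_small_sample=self.allow_small_sample)

    def population_uniqueness(self, method: str = "empirical", seed=None,
                              n_trials: int = 5, cell_cap: int = 100_000
                              ) -> risk.UniquenessEstimate:
        """Estimate Xi, the expected unique fraction of the population."""
        self._check_fitted()
        if (self.model_.n_train is not None
                and self.model_.n_train < self.min_records
                and not self.allow_small_sample):
            raise risk.GuardError(
                f"training sample had {self.model_.n_train} records "
                f"(< {self.min_records})")
        if method == "exact":
            return risk.population_uniqueness_exact(self.model_,
                                                    cell_cap=cell_cap)
        if method == "empirical":
            return risk.population_uniqueness_empirical(self.model_,
                                                        seed=seed,
                                                        n_trials=n_trials)
        raise ValueError("method must be 'exact' or 'empirical'")

    def sample(self, n_out: int, seed=None) -> np.ndarray:
        """Draw synthetic records from the fitted model."""
        self._check_fitted()
        return self.model_.sample(n_out, seed=seed)


def fit_copula_model(X, population_size: int, kinds="ordinal",
                     random_state=None, **kwargs) -> CopulaModel:
    """Thin functional wrapper: fit and return the CopulaModel."""
    est = GaussianCopulaRisk(population_size=population_size, kinds=kinds,
                             random_state=random_state, **kwargs)
    return est.fit(X).model_
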