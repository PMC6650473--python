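import math

import numpy as np
import pytest

from copulareid.copula import CopulaModel
from copulareid.estimator import GaussianCopulaRisk
from copulareid.marginals import categorical_marginal
from copulareid.risk import (CapacityError, GuardError, correctness_from_p,
                             correctness_from_uniqueness,
                             empirical_uniqueness, individual_uniqueness,
                             population_uniqueness_empirical,
                             population_uniqueness_exact, score_dataset)


def kappa_binomial_oracle(q, n):
    """Brute-force E[1/(T+1)], T ~ Binomial(n-1, q)."""
    return sum(math.comb(n - 1, k) * q ** k * (1 - q) ** (n - 1 - k) / (k + 1)
               for k in range(n))


class TestUniqueness:
    def test_zero_frequency_always_unique(self):
        assert individual_uniqueness(0.0, 10 ** 8) == 1.0

    def test_population_of_one(self):
        assert individual_uniqueness(0.7, 1) == 1.0

    def test_coin_flip_collision(self):
        assert individual_uniqueness(0.5, 2) == pytest.approx(0.5)

    def test_no_underflow_at_large_n(self):
        xi = individual_uniqueness(1e-9, 10 ** 8)
        assert xi == pytest.approx(np.exp(-(10 ** 8 - 1) * 1e-9), rel=1e-9)

    def test_monotone_decreasing_in_q(self):
        q = np.linspace(0, 1, 50)
        xi = individual_uniqueness(q, 1000)
        assert np.all(np.diff(xi) <= 0)


class TestCorrectness:
    def test_everyone_identical(self):
        assert correctness_from_p(1.0, 5) == pytest.approx(0.2)

    def test_vanishing_frequency_limit(self):
        assert correctness_from_p(0.0, 1000) == 1.0
        assert correctness_from_p(1e-300, 1000) == pytest.approx(1.0)

    def test_three_person_enumeration(self):
        # q=0.5, n=3: 0.25*1 + 0.5*(1/2) + 0.25*(1/3)
        assert correctness_from_p(0.5, 3) == pytest.approx(0.25 + 0.25 + 1 / 12)

    @pytest.mark.parametrize("n", range(2, 13))
    def test_closed_form_equals_binomial_sum(self, n):
        for q in np.arange(0.1, 0.95, 0.1):
            assert correctness_from_p(q, n) == pytest.approx(
                kappa_binomial_oracle(q, n), abs=1e-12)

    def test_uniqueness_and_frequency_forms_agree(self):
        qs = np.array([1e-9, 1e-6, 1e-3, 0.01, 0.1, 0.5, 0.9, 0.999])
        for n in (2, 10, 1000, 10 ** 6):
            # the round trip runs through xi = (1-q)^{n-1}, so keep to the
            # (q, n) combinations where xi is representable in a double
            ok = (n - 1) * np.log1p(-qs) > -690
            xi = individual_uniqueness(qs[ok], n)
            assert correctness_from_uniqueness(xi, n) == pytest.approx(
                correctness_from_p(qs[ok], n), abs=1e-10)

    def test_correctness_at_high_uniqueness_large_population(self):
        # 58% unique in a multi-million population -> 77% correct match
        assert round(correctness_from_uniqueness(0.58, 6_500_000), 2) == 0.77
        # 99.7% unique -> 99.8% correct
        assert round(correctness_from_uniqueness(0.997, 6_500_000), 3) == 0.998

    def test_large_n_asymptotic(self):
        for xi in (0.1, 0.3, 0.58, 0.9, 0.99):
            asym = (1 - xi) / (-np.log(xi))
            assert correctness_from_uniqueness(xi, 10 ** 6) == \
                pytest.approx(asym, abs=1e-4)

    def test_unique_implies_always_correct(self):
        assert correctness_from_uniqueness(1.0, 100) == 1.0

    def test_monotone_and_dominating(self):
        n = 500
        xi = np.linspace(0, 1, 101)
        kappa = correctness_from_uniqueness(xi, n)
        assert np.all(np.diff(kappa) >= -1e-12)
        assert np.all(kappa >= xi - 1e-12)
        assert np.all((kappa >= 1 / n - 1e-12) & (kappa <= 1.0 + 1e-12))


class TestPopulationUniqueness:
    def test_uniform_four_cell_hand_arithmetic(self):
        model = CopulaModel(sigma=np.eye(1),
                            marginals=[categorical_marginal([0.25] * 4)],
                            population_size=3)
        est = population_uniqueness_exact(model)
        assert est.xi_pop == pytest.approx(4 * 0.25 * 0.75 ** 2)

    def test_population_of_one_is_all_unique(self):
        model = CopulaModel(sigma=np.eye(1),
                            marginals=[categorical_marginal([0.5, 0.5])],
                            population_size=1)
        assert population_uniqueness_exact(model).xi_pop == pytest.approx(1.0)

    def test_single_cell_space_has_no_uniques(self):
        model = CopulaModel(sigma=np.eye(1),
                            marginals=[categorical_marginal([1.0])],
                            population_size=5)
        assert population_uniqueness_exact(model).xi_pop == pytest.approx(0.0)
        assert population_uniqueness_empirical(model, seed=0).xi_pop == 0.0

    def test_capacity_cap(self, small_model):
        with pytest.raises(CapacityError):
            population_uniqueness_exact(small_model, cell_cap=10)

    def test_exact_matches_mean_record_uniqueness(self, small_model):
        from copulareid.risk import _enumerate_cells
        cells = _enumerate_cells([3, 4, 2])
        q = small_model.cell_probabilities(cells)
        by_hand = float(np.sum(q * individual_uniqueness(
            q, small_model.population_size)))
        assert population_uniqueness_exact(small_model).xi_pop == \
            pytest.approx(by_hand)

    def test_exact_and_empirical_agree(self, small_model):
        exact = population_uniqueness_exact(small_model).xi_pop
        emp = population_uniqueness_empirical(small_model, seed=1,
                                              n_trials=20)
        assert abs(emp.xi_pop - exact) < 3 * max(emp.mc_error, 1e-4)

    def test_sparse_space_all_unique(self):
        margs = [categorical_marginal(np.full(12, 1 / 12)) for _ in range(4)]
        model = CopulaModel(sigma=np.eye(4), marginals=margs,
                            population_size=100)
        est = population_uniqueness_empirical(model, seed=2, n_trials=3)
        assert est.xi_pop > 0.95


class TestEmpiricalUniqueness:
    def test_all_identical(self):
        assert empirical_uniqueness(np.ones((5, 2))) == 0.0

    def test_all_distinct(self):
        assert empirical_uniqueness(np.arange(8).reshape(4, 2)) == 1.0

    def test_one_of_three(self):
        assert empirical_uniqueness(np.array([[1], [1], [2]])) == \
            pytest.approx(1 / 3)


class TestScoreDataset:
    def test_independence_composition(self):
        margs = [categorical_marginal([0.6, 0.4]),
                 categorical_marginal([0.3, 0.3, 0.4])]
        model = CopulaModel(sigma=np.eye(2), marginals=margs,
                            population_size=200, n_train=100)
        recs = np.array([[1, 1], [2, 3]])
        scores = score_dataset(model, recs)
        q = margs[0].pmf(recs[:, 0]) * margs[1].pmf(recs[:, 1])
        assert scores.xi_hat == pytest.approx(
            individual_uniqueness(q, 200), abs=1e-6)
        assert scores.kappa_hat == pytest.approx(
            correctness_from_p(q, 200), abs=1e-6)
        assert np.all(scores.kappa_hat >= scores.xi_hat)

    def test_small_training_sample_guard(self, tiny_mixed):
        est = GaussianCopulaRisk(population_size=300, random_state=0)
        est.fit(tiny_mixed.population[:49])
        with pytest.raises(GuardError):
            est.predict(tiny_mixed.population[:5])
        est_ok = GaussianCopulaRisk(population_size=300, random_state=0,
                                    allow_small_sample=True)
        est_ok.fit(tiny_mixed.population[:49])
        xi = est_ok.predict(tiny_mixed.population[:5])
        assert np.all((xi >= 0) & (xi <= 1))

    def test_schema_mismatch(self, small_model):
        with pytest.raises(ValueError):
            score_dataset(small_model, np.ones((3, 2), dtype=int))

    def test_sample_unique_flags(self, small_model):
        recs = np.array([[1, 1, 1], [1, 1, 1], [2, 2, 2]])
        scores = score_dataset(small_model, recs)
        assert scores.sample_unique.tolist() == [False, False, True]

    def test_saturated_fit_recovers_population_uniqueness(self, tiny_mixed):
        """Training on the full population, the mean record-level uniqueness
        estimate tracks the actually-unique fraction."""
        est = GaussianCopulaRisk(population_size=300,
                                 families=("categorical",), random_state=5)
        est.fit(tiny_mixed.population)
        mean_xi = float(est.predict(tiny_mixed.population).mean())
        assert abs(mean_xi - tiny_mixed.empirical_uniqueness()) < 0.02
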