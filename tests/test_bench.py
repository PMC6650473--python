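import numpy as np
import pytest
from scipy.stats import chisquare

from copulareid.bench import (ScenarioSpecError, brier_score,
                              fdr_at_threshold, make_scenario,
                              perturbation_analysis, roc_auc,
                              sampling_experiment, uniqueness_classification)
from copulareid.copula import CopulaModel
from copulareid.marginals import categorical_marginal
from copulareid.risk import individual_uniqueness


def scenario_spec(**over):
    spec = {"name": "adhoc", "population_size": 5000, "seed": 1,
            "attributes": [
                {"name": "a", "kind": "ordinal", "family": "categorical",
                 "probs": {"recipe": "zipf", "K": 6, "s": 0.8}},
                {"name": "b", "kind": "ordinal", "family": "categorical",
                 "probs": [0.4, 0.3, 0.2, 0.1]},
                {"name": "c", "kind": "ordinal", "family": "logarithmic",
                 "p": 0.7, "K": 5}],
            "sigma": {"recipe": "constant", "value": 0.4}}
    spec.update(over)
    return spec


class TestMakeScenario:
    def test_single_attribute_population_follows_marginal(self):
        spec = {"name": "d1", "population_size": 20_000, "seed": 3,
                "attributes": [{"name": "a", "kind": "ordinal",
                                "family": "categorical",
                                "probs": [0.5, 0.3, 0.2]}],
                "sigma": [[1.0]]}
        sc = make_scenario(spec)
        obs = np.bincount(sc.population[:, 0], minlength=4)[1:]
        _, pval = chisquare(obs, 20_000 * np.array([0.5, 0.3, 0.2]))
        assert pval > 0.01

    def test_two_seeds_differ_but_echo_spec(self):
        a = make_scenario(scenario_spec(), seed=10)
        b = make_scenario(scenario_spec(), seed=11)
        assert not np.array_equal(a.population, b.population)
        assert a.spec == b.spec

    def test_invalid_sigma_rejected(self):
        bad = scenario_spec(sigma=[[1.0, 0.99, 0.0], [0.99, 1.0, 0.99],
                                   [0.0, 0.99, 1.0]])
        with pytest.raises(ScenarioSpecError):
            make_scenario(bad)

    def test_empirical_tracks_exact_uniqueness(self):
        spec = {"name": "k5", "population_size": 100_000, "seed": 4,
                "attributes": [
                    {"name": n, "kind": "ordinal", "family": "categorical",
                     "probs": {"recipe": "zipf", "K": 5, "s": 0.5}}
                    for n in "abc"],
                "sigma": {"recipe": "constant", "value": 0.6}}
        sc = make_scenario(spec)
        exact = sc.exact_uniqueness()
        # binomial-scale error bound on the realized unique fraction
        se = np.sqrt(max(exact * (1 - exact), 1e-6) / 100_000)
        assert abs(sc.empirical_uniqueness() - exact) < 5 * se + 5e-4


class TestMetrics:
    def test_brier_trivials_and_hand_case(self):
        labels = np.array([0, 1])
        assert brier_score(labels.astype(float), labels) == 0.0
        assert brier_score(1.0 - labels, labels) == 1.0
        assert brier_score(np.array([0.2, 0.9]), labels) == \
            pytest.approx(0.025)

    def test_brier_of_constant_half_on_balanced_labels(self):
        labels = np.array([0, 1] * 50)
        scores = np.full(100, 0.5)
        assert brier_score(scores, labels) == pytest.approx(0.25)
        assert roc_auc(scores, labels) == pytest.approx(0.5)

    def test_uniform_random_guess_brier_one_third(self):
        rng = np.random.default_rng(0)
        scores = rng.random(200_000)
        labels = rng.integers(0, 2, 200_000)
        assert brier_score(scores, labels) == pytest.approx(1 / 3, abs=0.005)

    def test_fdr_cases(self):
        scores = np.array([0.96, 0.97, 0.5])
        labels = np.array([1, 0, 1])
        assert fdr_at_threshold(scores, labels, 0.95) == pytest.approx(0.5)
        assert fdr_at_threshold(scores, labels, 0.99) is None
        assert fdr_at_threshold(np.array([0.99]), np.array([1]), 0.9) == 0.0

    def test_auc_cases(self):
        labels = np.array([0, 0, 1, 1])
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), labels) == 1.0
        assert roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), labels) == 0.0
        assert roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), labels) == \
            pytest.approx(0.75)
        assert roc_auc(np.array([0.5, 0.5]), np.array([1, 1])) is None

    def test_population_baseline_is_brier_optimal_constant(self):
        """Among constant predictors, the realized unique fraction minimizes
        the Brier score (quadratic loss is minimized at the label mean)."""
        rng = np.random.default_rng(1)
        labels = rng.random(500) < 0.23
        target = labels.mean()
        grid = np.linspace(0, 1, 201)
        losses = [brier_score(np.full(500, c), labels) for c in grid]
        best = grid[int(np.argmin(losses))]
        assert abs(best - target) <= 0.005 + 1e-12


@pytest.fixture(scope="module")
def scen():
    return make_scenario(scenario_spec())


@pytest.fixture(scope="module")
def perturb_model():
    margs = [categorical_marginal([0.5, 0.3, 0.2]),
             categorical_marginal([0.6, 0.4])]
    sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
    return CopulaModel(sigma=sigma, marginals=margs, population_size=500)


class TestHarness:
    def test_sampling_experiment_full_fraction(self, scen):
        rep = sampling_experiment(scen, [1.0], trials=2, seed=0,
                                  uniqueness_trials=3)
        cell = rep.per_fraction[0]
        assert not cell["skipped"]
        assert cell["mae_mean"] <= 0.03

    def test_small_fraction_skipped(self, scen):
        rep = sampling_experiment(scen, [0.005], trials=2, seed=0)
        assert rep.per_fraction[0]["skipped"]
        assert rep.per_fraction[0]["n_rows"] < 50

    def test_deterministic_report(self, scen):
        a = sampling_experiment(scen, [0.1], trials=1, seed=3,
                                uniqueness_trials=2).to_dict()
        b = sampling_experiment(scen, [0.1], trials=1, seed=3,
                                uniqueness_trials=2).to_dict()
        assert a == b

    def test_classification_report_fields(self, scen):
        rep = uniqueness_classification(scen, train_fraction=0.05,
                                        n_test=400, seed=5)
        assert rep.auc is None or 0.0 <= rep.auc <= 1.0
        assert 0.0 <= rep.brier_model <= 1.0
        assert 0.0 <= rep.brier_baseline <= 1.0
        assert set(rep.fdr_at) == {0.9, 0.95, 0.99}
        assert rep.config["n_train"] == 250


class TestPerturbation:
    def test_replacing_with_same_value_changes_nothing(self, perturb_model):
        model = perturb_model
        base, draws = perturbation_analysis([1, 1], model, attribute=0,
                                            mode="replace", n_draws=200,
                                            seed=0)
        rng = np.random.default_rng(0)
        vals = model.marginals[0].quantile(rng.random(200))
        same = vals == 1
        assert same.any()
        assert draws[same] == pytest.approx(base, abs=1e-9)

    def test_adding_independent_attribute_never_reduces_uniqueness(self):
        margs = [categorical_marginal([0.5, 0.3, 0.2]),
                 categorical_marginal([0.6, 0.4]),
                 categorical_marginal([0.4, 0.3, 0.3])]
        sigma = np.eye(3)
        sigma[0, 1] = sigma[1, 0] = 0.5
        wider = CopulaModel(sigma=sigma, marginals=margs, population_size=500)
        base_model = CopulaModel(sigma=sigma[:2, :2], marginals=margs[:2],
                                 population_size=500)
        base, draws = perturbation_analysis([2, 1], base_model, attribute=2,
                                            mode="add", n_draws=50, seed=1,
                                            wider_model=wider)
        assert np.all(draws >= base - 1e-9)
        # independence factorization: adding the attribute multiplies q by
        # its mass, so xi rises accordingly
        q_base = base_model.cell_probability([2, 1])
        for code in (1, 2, 3):
            xi = individual_uniqueness(
                q_base * margs[2].pmf(code), 500)
            assert np.any(np.abs(draws - xi) < 1e-6) or \
                margs[2].pmf(code) == 0

    def test_reproducible_under_seed(self, perturb_model):
        a = perturbation_analysis([1, 2], perturb_model, 1, "replace", 50,
                                  seed=7)
        b = perturbation_analysis([1, 2], perturb_model, 1, "replace", 50,
                                  seed=7)
        assert a[0] == b[0] and np.array_equal(a[1], b[1])

    def test_invalid_attribute_index(self, perturb_model):
        with pytest.raises(ValueError):
            perturbation_analysis([1, 1], perturb_model, 5, "replace", 10,
                                  seed=0)
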