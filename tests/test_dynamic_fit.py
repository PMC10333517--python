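import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burstlin.cme_models import CMEDistribution, TelegraphParams2, solve_model
from burstlin.dynamic_fit import (
    GAConfig,
    aic,
    empirical_cdf,
    filter_aic_outliers,
    fit_condition,
    fraction_three_state,
    multinomial_loglik,
    objective,
    select_model,
)
from burstlin.synthetic_data import sample_from_cme

KD = np.log(2) / 30.0
TRUTH = TelegraphParams2(k_on=0.02, k_off=0.74, k_t=1.2, k_d=KD)
SMALL_GA = GAConfig(population=16, elite=2, crossover=0.6, generations=5, n_runs=2)


class TestEmpiricalCDF:
    def test_hand_example(self):
        values, cdf = empirical_cdf(np.array([0, 0, 1]))
        np.testing.assert_array_equal(values, [0, 1])
        np.testing.assert_allclose(cdf, [2 / 3, 1.0])

    def test_constant_vector_single_step(self):
        values, cdf = empirical_cdf(np.full(5, 7))
        np.testing.assert_array_equal(values, [7])
        np.testing.assert_allclose(cdf, [1.0])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.integers(0, 50), min_size=1, max_size=200))
    def test_nondecreasing_and_ends_at_one(self, counts):
        _, cdf = empirical_cdf(np.array(counts))
        assert (np.diff(cdf) >= 0).all()
        assert cdf[-1] == pytest.approx(1.0)


class TestObjective:
    def test_zero_when_model_equals_empirical(self):
        counts = sample_from_cme(TRUTH, t=120.0, n_cells=400, seed=0)
        dist = solve_model(TRUTH, 120.0, n_alleles=2)
        values, ecdf = empirical_cdf(counts)
        # replace the model CDF by the empirical one: distance must vanish
        from burstlin.dynamic_fit import model_cdf_at

        fake = CMEDistribution(
            pmf=np.bincount(counts) / len(counts), t=120.0, n_alleles=2
        )
        assert np.mean(np.abs(model_cdf_at(fake, values) - ecdf)) < 1e-12

    def test_hand_arithmetic(self):
        # ECDF [0.5, 1.0] vs model CDF [0.6, 1.0] -> mean |diff| = 0.05
        from burstlin.dynamic_fit import model_cdf_at

        fake = CMEDistribution(pmf=np.array([0.6, 0.4]), t=1.0, n_alleles=2)
        counts = np.array([0, 1])

        values, ecdf = empirical_cdf(counts)
        val = float(np.mean(np.abs(model_cdf_at(fake, values) - ecdf)))
        assert val == pytest.approx(0.05)

    def test_truth_beats_doubled_transcription(self):
        wins = 0
        for seed in range(10):
            counts = sample_from_cme(TRUTH, t=120.0, n_cells=5000, seed=seed)
            f_truth = objective(TRUTH, counts, 120.0)
            doubled = TelegraphParams2(TRUTH.k_on, TRUTH.k_off, 2 * TRUTH.k_t, KD)
            wins += f_truth < objective(doubled, counts, 120.0)
        assert wins >= 9

    def test_permutation_invariance(self):
        counts = sample_from_cme(TRUTH, t=120.0, n_cells=500, seed=1)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(counts)
        assert objective(TRUTH, counts, 120.0) == objective(TRUTH, shuffled, 120.0)


class TestFitCondition:
    def test_uninformative_condition_skipped(self):
        assert fit_condition(np.zeros(100, dtype=int), 120.0, KD, "two_state") is None

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fit_condition(np.array([0.5, 1.5]), 120.0, KD, "two_state")

    def test_deterministic_given_seed(self):
        counts = sample_from_cme(TRUTH, t=120.0, n_cells=800, seed=3)
        a = fit_condition(counts, 120.0, KD, "two_state", ga=SMALL_GA, seed=5)
        b = fit_condition(counts, 120.0, KD, "two_state", ga=SMALL_GA, seed=5)
        assert a.params == b.params
        assert a.objective == b.objective

    def test_bounds_honored_and_argmin_contract(self):
        counts = sample_from_cme(TRUTH, t=120.0, n_cells=800, seed=4)
        res = fit_condition(counts, 120.0, KD, "two_state", ga=SMALL_GA, seed=6)
        p = res.params
        assert 0 <= p.k_on <= 1 and 0 <= p.k_off <= 1 and 0 <= p.k_t <= 50
        assert res.objective <= min(res.run_objectives) + 1e-12

    def test_best_of_n_monotone(self):
        """The best objective never worsens as runs accumulate."""
        counts = sample_from_cme(TRUTH, t=120.0, n_cells=800, seed=7)
        ga4 = GAConfig(population=16, elite=2, crossover=0.6, generations=5,
                      n_runs=4, refine=False)
        res = fit_condition(counts, 120.0, KD, "two_state", ga=ga4, seed=8)
        running = np.minimum.accumulate(res.run_objectives)
        assert (np.diff(running) <= 0).all()
        assert res.objective == pytest.approx(running[-1])

    def test_zero_hour_uses_steady_state_init(self):
        counts = sample_from_cme(TRUTH, t=600.0, n_cells=500, seed=9)
        res = fit_condition(counts, 0.0, KD, "two_state", ga=SMALL_GA, seed=10)
        assert res.steady_init


class TestLikelihoodAIC:
    def test_hand_multinomial(self):
        # counts {0: 2, 1: 1}, P(0)=P(1)=0.5 -> L = 3 * 0.125
        dist = CMEDistribution(pmf=np.array([0.5, 0.5]), t=1.0, n_alleles=2)
        logL = multinomial_loglik(dist, np.array([0, 0, 1]))
        assert logL == pytest.approx(np.log(0.375), abs=1e-10)

    def test_single_cell_certain_outcome(self):
        dist = CMEDistribution(pmf=np.array([1.0]), t=1.0, n_alleles=2)
        assert multinomial_loglik(dist, np.array([0])) == 0.0

    def test_zero_probability_observed_is_minus_inf(self):
        dist = CMEDistribution(pmf=np.array([1.0, 0.0]), t=1.0, n_alleles=2)
        assert multinomial_loglik(dist, np.array([0, 1])) == -np.inf

    def test_binomial_toy_maximised_at_empirical_frequency(self):
        counts = np.array([0] * 30 + [1] * 70)
        lls = []
        for p in np.linspace(0.3, 0.95, 40):
            dist = CMEDistribution(pmf=np.array([1 - p, p]), t=1.0, n_alleles=2)
            lls.append(multinomial_loglik(dist, counts))
        assert np.linspace(0.3, 0.95, 40)[np.argmax(lls)] == pytest.approx(0.7, abs=0.02)

    def test_aic_values(self):
        assert aic(0.0, 3) == 6.0
        assert aic(0.0, 7) == 14.0
        assert aic(np.log(0.375), 3) == pytest.approx(6 - 2 * np.log(0.375))


class TestOutlierFilter:
    def test_stated_quantile_convention(self):
        aics = [10.0, 12.0, 14.0, 16.0, 100.0]
        kept = filter_aic_outliers(aics)
        # Q1=12, Q3=16 by linear interpolation -> fence at 22
        np.testing.assert_array_equal(kept, [True, True, True, True, False])

    def test_all_equal_none_dropped(self):
        assert filter_aic_outliers([5.0] * 6).all()

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        aics = np.concatenate([rng.normal(50, 5, 40), [400.0, 500.0]])
        kept = filter_aic_outliers(aics)
        again = filter_aic_outliers(aics[kept])
        assert again.all()

    def test_too_few_fits_raise(self):
        with pytest.raises(ValueError):
            filter_aic_outliers([1.0, 2.0, 3.0])


class TestSelection:
    def test_clear_winner_under_all_rules(self):
        for rule in ("absolute", "half", "twofold"):
            assert select_model(100.0, 40.0, rule) == "three_state"

    def test_moderate_winner_only_absolute(self):
        assert select_model(100.0, 60.0, "absolute") == "three_state"
        assert select_model(100.0, 60.0, "half") == "tie"

    def test_equal_aics_tie_everywhere(self):
        for rule in ("absolute", "half", "twofold"):
            assert select_model(50.0, 50.0, rule) == "tie"

    def test_missing_fit_wins_by_presence(self):
        assert select_model(np.nan, 40.0) == "three_state"
        assert select_model(40.0, np.nan) == "two_state"

    def test_factor_two_rules_nest_in_absolute(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a2, a3 = rng.uniform(10, 200, 2)
            absolute = select_model(a2, a3, "absolute")
            half = select_model(a2, a3, "half")
            two = select_model(a2, a3, "twofold")
            if half != "tie":
                assert half == absolute
            if two != "tie":
                assert two == absolute

    def test_fraction_three_state(self):
        sels = ["three_state"] * 3 + ["two_state"] * 17
        assert fraction_three_state(sels) == pytest.approx(0.15)
        assert fraction_three_state(["three_state"] * 4) == 1.0
        with pytest.raises(ValueError):
            fraction_three_state([])
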