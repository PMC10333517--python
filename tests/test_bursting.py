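import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burstlin.bursting import (
    BurstEstimates,
    bs_bf_relation,
    burst_estimates,
    classify_mode,
    gene_rrmse,
    modulation_fold_changes,
    moment_burst,
    mu_grid,
    rrmse,
    summarize_gene,
    theoretical_curves,
)
from burstlin.dataio import identity_normalize
from burstlin.mean_variance import ConditionMoments, fit_gene_panel, fit_huber_line
from burstlin.synthetic_data import generate_linear_family


def fit_from_line(alpha, alpha0, mus):
    pts = [
        ConditionMoments("g", ("LPS", 2.0, f"r{i}"), m, alpha * m + alpha0, 1000)
        for i, m in enumerate(mus)
    ]
    return fit_huber_line(pts)


def estimates_from_bs(alpha, alpha0, bs_values):
    """Estimates lying on the fitted line with the requested burst sizes."""
    out = []
    for i, bs in enumerate(bs_values):
        # bs = alpha0/mu + alpha  ->  mu = alpha0 / (bs - alpha)
        mu = alpha0 / (bs - alpha)
        var = alpha * mu + alpha0
        out.append(BurstEstimates("g", ("LPS", 2.0, f"r{i}"), mu, var, bs, mu / bs))
    return out


class TestMomentBurst:
    def test_poisson_case(self):
        bs, bf = moment_burst(10.0, 10.0)
        assert bs == pytest.approx(1.0)
        assert bf == pytest.approx(10.0)

    def test_arithmetic(self):
        bs, bf = moment_burst(10.0, 30.0)
        assert bs == pytest.approx(3.0)
        assert bf == pytest.approx(10.0 / 3.0)

    def test_undefined_flags_nan(self):
        assert np.isnan(moment_burst(0.0, 5.0)[0])
        assert np.isnan(moment_burst(5.0, 0.0)[1])

    @settings(deadline=None, max_examples=200)
    @given(
        st.floats(0.01, 1e4),
        st.floats(0.01, 1e6),
    )
    def test_product_identity(self, mu, var):
        bs, bf = moment_burst(mu, var)
        assert bs * bf == pytest.approx(mu, rel=1e-9)


class TestTheoreticalCurves:
    def test_printed_parameter_evaluation(self):
        fit = fit_from_line(20.0, 100.0, [5.0, 10.0, 20.0, 40.0])
        mus, bs, bf = theoretical_curves(fit, np.array([10.0]))
        assert bs[0] == pytest.approx(30.0)
        assert bf[0] == pytest.approx(1.0 / 3.0)

    def test_zero_intercept_constant_burst_size(self):
        fit = fit_from_line(20.0, 0.0, [5.0, 10.0, 20.0, 40.0])
        mus, bs, bf = theoretical_curves(fit, np.linspace(1, 50, 25))
        np.testing.assert_allclose(bs, 20.0, atol=1e-8)
        np.testing.assert_allclose(bf, mus / 20.0, rtol=1e-8)

    def test_negative_intercept_minimum_location(self):
        """Numerical minimum of b_f at mu = 2|a0|/a with value 4|a0|/a^2."""
        fit = fit_from_line(20.0, -100.0, [6.0, 10.0, 20.0, 40.0])
        grid = np.linspace(5.01, 60.0, 20_000)
        mus, _, bf = theoretical_curves(fit, grid)
        i = np.argmin(bf)
        assert mus[i] == pytest.approx(2 * 100.0 / 20.0, abs=0.01)
        assert bf[i] == pytest.approx(4 * 100.0 / 20.0**2, abs=1e-4)

    def test_out_of_domain_points_dropped(self):
        fit = fit_from_line(20.0, -100.0, [6.0, 10.0, 20.0, 40.0])
        mus, bs, bf = theoretical_curves(fit, np.array([1.0, 10.0]))
        assert len(mus) == 1  # mu=1 is below |a0|/a = 5

    def test_monotonicity_follows_intercept_sign(self):
        for alpha0, sign in [(100.0, -1), (-100.0, +1)]:
            fit = fit_from_line(20.0, alpha0, [6.0, 10.0, 20.0, 40.0])
            mus, bs, _ = theoretical_curves(fit, np.linspace(5.5, 80, 500))
            assert np.all(sign * np.diff(bs) > 0)

    def test_exact_coincidence_with_moment_estimators(self):
        """Points on the line: analytic curves equal moment estimators."""
        alpha, alpha0 = 7.0, 30.0
        mus = np.array([4.0, 9.0, 25.0, 60.0])
        fit = fit_from_line(alpha, alpha0, mus)
        _, bs_curve, bf_curve = theoretical_curves(fit, mus)
        for mu, bs_c, bf_c in zip(mus, bs_curve, bf_curve):
            bs_m, bf_m = moment_burst(mu, alpha * mu + alpha0)
            assert bs_m == pytest.approx(bs_c, rel=1e-12)
            assert bf_m == pytest.approx(bf_c, rel=1e-12)


class TestBsBfRelation:
    def test_printed_evaluation(self):
        fit = fit_from_line(20.0, 100.0, [5.0, 10.0, 20.0, 40.0])
        bs, bf = bs_bf_relation(fit, np.array([25.0]))
        assert bf[0] == pytest.approx(100.0 / (25.0 * 5.0))

    def test_negative_intercept_minimum_at_half_alpha(self):
        fit = fit_from_line(20.0, -100.0, [6.0, 10.0, 20.0, 40.0])
        grid = np.linspace(0.01, 19.99, 20_000)
        bs, bf = bs_bf_relation(fit, grid)
        assert bs[np.argmin(bf)] == pytest.approx(20.0 / 2.0, abs=0.01)

    def test_asymptote_to_zero(self):
        fit = fit_from_line(20.0, 100.0, [5.0, 10.0, 20.0, 40.0])
        bs, bf = bs_bf_relation(fit, np.array([1e3, 1e6]))
        assert bf[1] < bf[0] < 1e-2

    def test_pole_and_domain_excluded(self):
        fit = fit_from_line(20.0, 100.0, [5.0, 10.0, 20.0, 40.0])
        bs, _ = bs_bf_relation(fit, np.array([5.0, 20.0, 25.0]))
        np.testing.assert_array_equal(bs, [25.0])


class TestRRMSE:
    def test_identical_vectors_zero(self):
        assert rrmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_arithmetic(self):
        assert rrmse([10.0], [11.0]) == pytest.approx(10.0)

    def test_scale_invariance(self):
        m = np.array([3.0, 5.0, 9.0])
        d = np.array([3.2, 4.9, 9.4])
        assert rrmse(7.0 * m, 7.0 * d) == pytest.approx(rrmse(m, d), rel=1e-12)

    def test_zero_model_flagged(self):
        assert np.isnan(rrmse([0.0, 0.0], [1.0, 2.0]))

    def test_small_on_self_consistent_synthetic_data(self):
        """Curves vs data on an 8-condition linear family: < 2% each."""
        ds = generate_linear_family(3.0, 0.0, n_cells=20_000, seed=11)
        fit = fit_gene_panel(identity_normalize(ds))[0]
        errors = gene_rrmse(fit)
        for key, value in errors.items():
            assert value < 2.0, key


class TestModulation:
    def test_constant_bs_is_frequency_dominant(self):
        est = [
            BurstEstimates("g", i, mu, 2 * mu, 2.0, mu / 2.0)
            for i, mu in enumerate([2.0, 4.0, 10.0])
        ]
        dbs, dbf, ratio, dom = modulation_fold_changes(est)
        assert dbs == 0.0
        assert ratio == np.inf
        assert dom == "frequency"

    def test_comparable_modulation(self):
        est = [
            BurstEstimates("g", 0, 6.0, 12.0, 2.0, 3.0),
            BurstEstimates("g", 1, 24.0, 96.0, 4.0, 6.0),
        ]
        dbs, dbf, ratio, dom = modulation_fold_changes(est)
        assert dbs == pytest.approx(1.0)
        assert dbf == pytest.approx(1.0)
        assert ratio == pytest.approx(1.0)
        assert dom == "comparable"

    def test_zero_intercept_gene_is_frequency_dominant(self):
        ds = generate_linear_family(3.0, 0.0, n_cells=20_000, seed=2)
        fit = fit_gene_panel(identity_normalize(ds))[0]
        scheme = summarize_gene(fit)
        assert scheme.dominance == "frequency"


class TestClassifyMode:
    def test_positive_intercept_always_inverse(self):
        fit = fit_from_line(20.0, 100.0, [5.0, 10.0, 20.0, 40.0])
        est = estimates_from_bs(20.0, 100.0, [25.0, 40.0])
        assert classify_mode(fit, est) == "inverse"

    def test_u_shape_straddles_half_alpha(self):
        fit = fit_from_line(20.0, -100.0, [6.0, 10.0, 20.0, 40.0])
        est = estimates_from_bs(20.0, -100.0, [5.0, 15.0])
        assert classify_mode(fit, est) == "U_shape"

    def test_concurrent_above_half_alpha(self):
        fit = fit_from_line(20.0, -100.0, [6.0, 10.0, 20.0, 40.0])
        est = estimates_from_bs(20.0, -100.0, [12.0, 18.0])
        assert classify_mode(fit, est) == "concurrent"

    def test_inverse_below_half_alpha(self):
        fit = fit_from_line(20.0, -100.0, [6.0, 10.0, 20.0, 40.0])
        est = estimates_from_bs(20.0, -100.0, [4.0, 8.0])
        assert classify_mode(fit, est) == "inverse"

    def test_zero_intercept_is_frequency_only(self):
        fit = fit_from_line(20.0, 0.0, [5.0, 10.0, 20.0, 40.0])
        fit.alpha0 = 0.0
        est = estimates_from_bs(20.0, 1.0, [21.0, 22.0])
        assert classify_mode(fit, est) == "frequency_only"


class TestSummary:
    def test_grid_respects_domain(self):
        fit = fit_from_line(20.0, -100.0, [6.0, 10.0, 20.0, 40.0])
        grid = mu_grid(fit)
        assert grid.min() >= 5.0 * 1.01 - 1e-9
        assert grid.max() == pytest.approx(40.0)

    def test_excluded_conditions_counted(self):
        pts = [
            ConditionMoments("g", ("LPS", 2.0, "r0"), 0.0, 0.0, 100),
            ConditionMoments("g", ("LPS", 4.0, "r0"), 10.0, 35.0, 100),
            ConditionMoments("g", ("LPS", 6.0, "r0"), 20.0, 65.0, 100),
            ConditionMoments("g", ("PIC", 2.0, "r0"), 40.0, 125.0, 100),
        ]
        fit = fit_huber_line(pts[1:])
        fit.moments = pts
        scheme = summarize_gene(fit)
        assert scheme.n_excluded == 1
        assert len(scheme.estimates) == 3
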