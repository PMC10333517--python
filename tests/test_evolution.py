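import numpy as np
import pytest

from burstlin.dataio import identity_normalize
from burstlin.evolution import (
    complexity_slope_correlation,
    pairwise_species,
    response_divergence,
    slope_ttest,
    stratify_divergence,
)
from burstlin.mean_variance import ConditionMoments, fit_gene_panel, fit_huber_line
from burstlin.synthetic_data import generate_species_panel


def fit_with(alpha, se, n, gene="g"):
    mus = np.linspace(10, 40, n)
    f = fit_huber_line(
        [
            ConditionMoments(gene, ("LPS", 2.0, f"r{i}"), m, alpha * m + 1.0, 500)
            for i, m in enumerate(mus)
        ]
    )
    f.alpha = alpha
    f.se_alpha = se
    return f


class TestSlopeTTest:
    def test_equal_slopes_give_p_one(self):
        c = slope_ttest(fit_with(3.0, 0.5, 8), fit_with(3.0, 0.5, 8))
        assert c.t == 0.0
        assert c.p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        c = slope_ttest(fit_with(3.0, 0.5, 20), fit_with(1.0, 0.5, 12))
        assert c.t == pytest.approx(2.0 / np.sqrt(0.5), rel=1e-12)
        assert c.dof == 28
        assert c.k == pytest.approx(3.0)

    def test_too_few_points_raise(self):
        a, b = fit_with(3.0, 0.5, 3), fit_with(1.0, 0.5, 3)
        b.n_conditions = 1
        with pytest.raises(ValueError):
            slope_ttest(a, b)

    def test_type_one_error_calibrated(self, null_ttest_rejections):
        """Same-slope species panels: rejection rate near nominal 5%."""
        rej, n_seeds = null_ttest_rejections
        assert 0.02 * n_seeds <= rej <= 0.08 * n_seeds


class TestPairwise:
    def _fits(self, alphas):
        return {
            sp: {"g": fit_with(a, 0.3, 10, "g")} for sp, a in alphas.items()
        }

    def test_four_species_six_comparisons(self):
        comps, counts = pairwise_species(
            self._fits({"mouse": 3.0, "rat": 3.1, "pig": 2.9, "rabbit": 3.2})
        )
        assert len(comps) == 6
        assert counts.loc["g"] >= 0

    def test_identical_fits_nothing_significant(self):
        comps, counts = pairwise_species(
            self._fits({"a": 3.0, "b": 3.0, "c": 3.0, "d": 3.0})
        )
        assert counts.loc["g"] == 0

    def test_k_symmetric(self):
        comps, _ = pairwise_species(self._fits({"a": 6.0, "b": 3.0}))
        assert comps[0].k == pytest.approx(2.0)
        comps2, _ = pairwise_species(self._fits({"a": 3.0, "b": 6.0}))
        assert comps2[0].k == pytest.approx(2.0)

    def test_divergent_species_pairs_detected(self):
        """One species at a 5x slope: its pairs reach significance."""
        hits = 0
        for seed in range(10):
            panel = generate_species_panel(
                {"A": 3.0, "B": 3.0, "C": 15.0}, n_cells=10_000, seed=seed
            )
            fits = {
                sp: {"g": fit_gene_panel(identity_normalize(ds))[0]}
                for sp, ds in panel.items()
            }
            comps, counts = pairwise_species(fits)
            sig = {
                frozenset((c.species_a, c.species_b)) for c in comps if c.q < 0.05
            }
            hits += frozenset(("A", "C")) in sig and frozenset(("B", "C")) in sig
        assert hits >= 9


class TestStratify:
    def _comps(self, alpha_a, alpha_b):
        fits = {
            "A": {"g": fit_with(alpha_a, 0.3, 10, "g")},
            "B": {"g": fit_with(alpha_b, 0.3, 10, "g")},
        }
        comps, _ = pairwise_species(fits)
        return comps

    def test_divergent_a(self):
        cls = stratify_divergence(self._comps(10.0, 4.0), ("A", "B"))
        assert cls.loc["g"] == "divergent_A"

    def test_non_divergent(self):
        cls = stratify_divergence(self._comps(10.0, 6.0), ("A", "B"))
        assert cls.loc["g"] == "non_divergent"

    def test_antisymmetric(self):
        cls = stratify_divergence(self._comps(4.0, 10.0), ("A", "B"))
        assert cls.loc["g"] == "divergent_B"

    def test_divergent_species_has_higher_bs_lower_normalized_bf(self):
        """k = 2 panel: group-level burst size up, mean-normalised
        frequency down in the divergent species (paired one-sided)."""
        from scipy import stats as sps

        from burstlin.bursting import burst_estimates
        from burstlin.mean_variance import compute_moments

        n_genes = 30
        panel = generate_species_panel(
            {"A": 3.0, "B": 6.0},
            n_cells=2000,
            seed=123,
            n_genes=n_genes,
        )
        per_species = {}
        for sp, ds in panel.items():
            moments = compute_moments(identity_normalize(ds))
            bs_by_gene = {}
            bfn_by_gene = {}
            for est in burst_estimates(moments):
                if np.isfinite(est.bs):
                    bs_by_gene.setdefault(est.gene_id, []).append(est.bs)
                    # mean-normalised frequency: b_f / mu = mu / var
                    bfn_by_gene.setdefault(est.gene_id, []).append(est.bf / est.mu)
            per_species[sp] = (
                {g: np.mean(v) for g, v in bs_by_gene.items()},
                {g: np.mean(v) for g, v in bfn_by_gene.items()},
            )
        genes = sorted(per_species["A"][0])
        bs_a = np.array([per_species["A"][0][g] for g in genes])
        bs_b = np.array([per_species["B"][0][g] for g in genes])
        bf_a = np.array([per_species["A"][1][g] for g in genes])
        bf_b = np.array([per_species["B"][1][g] for g in genes])
        assert sps.wilcoxon(bs_b, bs_a, alternative="greater").pvalue < 0.05
        assert sps.wilcoxon(bf_b, bf_a, alternative="less").pvalue < 0.05

    def test_theoretical_ratio_scaling(self):
        """alpha2 = k alpha1 with zero intercept: fitted burst-size ratio
        approaches k and frequency ratio 1/k at matched means."""
        panel = generate_species_panel({"A": 3.0, "B": 6.0}, n_cells=20_000, seed=7)
        fits = {
            sp: fit_gene_panel(identity_normalize(ds))[0] for sp, ds in panel.items()
        }
        from burstlin.bursting import theoretical_curves

        mus = np.array([30.0, 40.0, 50.0])
        _, bs_a, bf_a = theoretical_curves(fits["A"], mus)
        _, bs_b, bf_b = theoretical_curves(fits["B"], mus)
        np.testing.assert_allclose(bs_b / bs_a, 2.0, rtol=0.15)
        np.testing.assert_allclose(bf_b / bf_a, 0.5, rtol=0.15)


class TestResponseDivergence:
    def test_symbolic_evaluation(self):
        score = response_divergence(8.0, [2.0, 2.0, 2.0])
        assert score == pytest.approx(np.log(np.log(4.0) ** 2))

    def test_identical_fold_changes_undefined(self):
        with pytest.raises(ValueError):
            response_divergence(2.0, [2.0, 2.0, 2.0])

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ValueError):
            response_divergence(-1.0, [2.0, 2.0, 2.0])

    def test_invariant_to_common_scaling(self):
        a = response_divergence(8.0, [2.0, 3.0, 5.0])
        b = response_divergence(8.0 * 9.0, [18.0, 27.0, 45.0])
        assert a == pytest.approx(b, rel=1e-12)


class TestComplexityCorrelation:
    def test_perfect_monotone_gives_r_one(self):
        x = np.array([1.0, 1.5, 2.0, 3.0, 5.0])
        r, p = complexity_slope_correlation(x, x**2)
        assert r == pytest.approx(1.0)

    def test_null_is_near_zero(self):
        rng = np.random.default_rng(0)
        ok = 0
        for _ in range(100):
            x = rng.random(50)
            y = rng.random(50)
            r, _ = complexity_slope_correlation(x, y)
            ok += abs(r) < 0.3
        assert ok >= 90

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            complexity_slope_correlation([1.0, 2.0], [1.0, 2.0])
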