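"""Edgewise regressions, effect sizes, and QC statistics."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from shaman import (EdgewiseOLS, effect_percentile, matrix_similarity,
                    motion_fc, trait_fc, trait_fd_corr, variance_reduction)
from shaman.traitqc import relative_reduction_from_proportions


class TestTraitFC:
    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(0)
        n, E = 6, 3
        trait = rng.uniform(size=n)
        fd = rng.uniform(0.1, 0.5, size=n)
        Y = rng.standard_normal((n, E))
        eff = trait_fc(Y, trait, covariates=fd.reshape(-1, 1))
        X = sm.add_constant(np.column_stack([trait, fd]))
        for e in range(E):
            fit = sm.OLS(Y[:, e], X).fit()
            assert np.isclose(eff.beta[e], fit.params[1], atol=1e-10)
            assert np.isclose(eff.t[e], fit.tvalues[1], atol=1e-10)

    def test_null_trait_t_centred(self):
        rng = np.random.default_rng(1)
        n, E = 200, 60
        eff = trait_fc(rng.standard_normal((n, E)), rng.standard_normal(n))
        assert abs(eff.t.mean()) < 0.5
        assert 0.5 < eff.t.std() < 2.0

    def test_planted_slope_recovered_within_ci(self):
        rng = np.random.default_rng(2)
        n = 500
        trait = rng.standard_normal(n)
        Y = np.outer(trait, [0.3, 0.0]) + 0.1 * rng.standard_normal((n, 2))
        eff = trait_fc(Y, trait)
        assert np.isclose(eff.beta[0], 0.3, atol=0.02)
        assert abs(eff.beta[1]) < 0.02

    def test_t_to_r_identity(self):
        rng = np.random.default_rng(3)
        eff = trait_fc(rng.standard_normal((20, 10)), rng.standard_normal(20))
        assert np.allclose(eff.r_effect**2,
                           eff.t**2 / (eff.t**2 + eff.df), atol=1e-12)
        assert (np.abs(eff.r_effect) < 1).all()

    def test_trait_scale_invariance(self):
        rng = np.random.default_rng(4)
        Y = rng.standard_normal((15, 4))
        trait = rng.uniform(1, 2, size=15)
        a = trait_fc(Y, trait)
        b = trait_fc(Y, 10 * trait)
        assert np.allclose(b.beta, a.beta / 10)
        assert np.allclose(b.t, a.t, atol=1e-10)

    def test_model_string(self):
        rng = np.random.default_rng(5)
        eff = trait_fc(rng.standard_normal((8, 3)), rng.standard_normal(8),
                       covariates=rng.standard_normal((8, 1)),
                       trait_name="bmi")
        assert eff.model == "FC ~ 1 + bmi + FD"


class TestMotionFC:
    def test_exact_linear_relationship(self):
        fd = np.linspace(0.1, 0.6, 12)
        Y = np.outer(fd, [2.5, -1.0]) + 0.7
        eff = motion_fc(Y, fd)
        assert np.allclose(eff.beta, [2.5, -1.0], atol=1e-12)

    def test_null_calibration(self):
        rng = np.random.default_rng(6)
        eff = motion_fc(rng.standard_normal((300, 40)), rng.uniform(size=300))
        assert abs(eff.beta.mean()) < 0.1

    def test_constant_fd_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            motion_fc(np.zeros((5, 2)), np.full(5, 0.3))

    def test_recovers_motion_pattern_in_cohort(self, tiny_cohort):
        from shaman import edges, mean_fd

        table = np.stack([edges(ts).z for ts in tiny_cohort.participants])
        fds = np.array([mean_fd(ts) for ts in tiny_cohort.participants])
        eff = motion_fc(table, fds)
        mask = tiny_cohort.basis_motion.offdiag_mask()
        # beta magnitude should concentrate on injected motion edges
        assert np.abs(eff.beta[mask]).mean() > np.abs(eff.beta[~mask]).mean()


class TestEffectSummaries:
    def test_constant_r_any_percentile(self):
        r = np.full(30, 0.25)
        assert np.isclose(effect_percentile(r_to_effect(r), 50), 0.25)
        assert np.isclose(effect_percentile(r_to_effect(r), 98), 0.25)

    def test_linear_interpolation_oracle(self):
        r = np.arange(0.01, 1.01, 0.01)
        assert np.isclose(effect_percentile(r, 98), 0.9802, atol=1e-12)

    def test_max_at_q100_and_monotone(self):
        rng = np.random.default_rng(7)
        r = rng.uniform(size=50)
        qs = [effect_percentile(r, q) for q in (10, 50, 90, 98, 100)]
        assert qs == sorted(qs)
        assert np.isclose(qs[-1], np.abs(r).max())


def r_to_effect(r):
    # effect_percentile accepts a plain |r| vector
    return np.asarray(r)


class TestTraitFDCorr:
    def test_identical_inputs(self):
        x = np.random.default_rng(8).uniform(size=30)
        out = trait_fd_corr(x, x)
        assert np.isclose(out["pearson_r"], 1.0)
        assert np.isclose(out["spearman_rho"], 1.0)

    def test_monotone_transform_spearman_invariant(self):
        fd = np.random.default_rng(9).uniform(0.1, 1.0, size=50)
        out = trait_fd_corr(np.exp(3 * fd), fd)
        assert np.isclose(out["spearman_rho"], 1.0)
        assert out["pearson_r"] < 1.0

    def test_independent_draws_small_r(self):
        rng = np.random.default_rng(10)
        out = trait_fd_corr(rng.standard_normal(10_000),
                            rng.standard_normal(10_000))
        assert abs(out["pearson_r"]) < 0.03

    def test_exact_small_n_p_matches_enumeration_extreme(self):
        # perfectly monotone n=5: only orderings +/- reach |rho| = 1
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        out = trait_fd_corr(x, y)
        assert np.isclose(out["spearman_p"], 2 / 120)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            trait_fd_corr(np.ones(5), np.arange(5.0))


class TestMatrixSimilarity:
    def test_self_similarity(self):
        v = np.random.default_rng(11).standard_normal(20)
        r, rho = matrix_similarity(v, v)
        assert np.isclose(r, 1.0) and np.isclose(rho, 1.0)

    def test_negation(self):
        v = np.random.default_rng(12).standard_normal(20)
        r, rho = matrix_similarity(v, -v)
        assert np.isclose(r, -1.0) and np.isclose(rho, -1.0)

    def test_matches_scipy_directly(self):
        rng = np.random.default_rng(13)
        a, b = rng.standard_normal((2, 15))
        r, rho = matrix_similarity(a, b)
        assert np.isclose(r, stats.pearsonr(a, b).statistic)
        assert np.isclose(rho, stats.spearmanr(a, b).statistic)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            matrix_similarity(np.zeros(3), np.zeros(4))


class TestVarianceReduction:
    def test_worked_proportions_example(self):
        # rho^2 0.73 before and 0.23 after denoising -> 68.5% ~ 69% reduction
        red = relative_reduction_from_proportions(0.73, 0.23)
        assert np.isclose(red, 1 - 0.23 / 0.73)
        assert round(100 * red) == 68 or round(100 * red) == 69
        assert np.isclose(red, 0.684931506849, atol=1e-9)

    def test_identity_gives_zero_reduction(self):
        rng = np.random.default_rng(14)
        fd = rng.uniform(0.1, 1.0, size=40)
        var = np.exp(2 * np.log(fd) + 0.1 * rng.standard_normal(40))
        out = variance_reduction(var, var, fd)
        assert np.isclose(out.relative_reduction, 0.0)

    def test_denoised_independent_gives_near_total_reduction(self):
        rng = np.random.default_rng(15)
        fd = rng.uniform(0.1, 1.0, size=400)
        before = np.exp(2 * np.log(fd) + 0.05 * rng.standard_normal(400))
        after = np.exp(rng.standard_normal(400) * 0.3 + 1)
        out = variance_reduction(before, after, fd)
        assert out.relative_reduction > 0.9

    def test_monotone_fd_transform_invariance(self):
        rng = np.random.default_rng(16)
        fd = rng.uniform(0.1, 1.0, size=60)
        before = fd ** 1.5 * np.exp(0.1 * rng.standard_normal(60))
        after = fd ** 0.5 * np.exp(0.4 * rng.standard_normal(60))
        a = variance_reduction(before, after, fd)
        b = variance_reduction(before, after, fd**3 + 2 * fd)
        assert np.isclose(a.relative_reduction, b.relative_reduction)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            variance_reduction([1.0, -1.0], [1.0, 1.0], [0.1, 0.2])


class TestEdgewiseOLSEstimator:
    def test_sklearn_api(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((30, 2))
        Y = rng.standard_normal((30, 5))
        est = EdgewiseOLS(predictor_col=0).fit(X, Y)
        assert est.beta_.shape == (5,)
        assert est.get_params()["predictor_col"] == 0
        assert est.df_ == 30 - 3

    def test_missing_values_rejected(self):
        X = np.array([[1.0], [np.nan], [2.0], [0.5]])
        with pytest.raises(ValueError, match="missing"):
            EdgewiseOLS().fit(X, np.zeros((4, 2)))
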