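"""Residual-difference regression, NPC combining, and orchestration."""

import numpy as np
import pytest
import statsmodels.api as sm

from shaman import (ImpactMap, MotionImpactScore, NullEnsemble, TraitModel,
                    assign_halves, directional_scores, impact_glm,
                    npc_stouffer, residual_difference, run_shaman,
                    stouffer_z, summarize_half)
from shaman.split import HalfSummary
from shaman.fc import EdgeVector


def make_halves(Ylow, Yhigh, fd_low, fd_high, n_nodes):
    out = []
    for yl, yh, fl, fh in zip(Ylow, Yhigh, fd_low, fd_high):
        out.append(HalfSummary(
            edges_low=EdgeVector(z=yl, n_nodes=n_nodes),
            edges_high=EdgeVector(z=yh, n_nodes=n_nodes),
            fd_low=fl, fd_high=fh, n_low=10, n_high=10))
    return out


class TestResidualDifference:
    def test_identical_halves_give_zero(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((5, 3))
        fd = rng.uniform(size=5)
        halves = make_halves(Y, Y, fd, fd, 3)
        assert np.allclose(residual_difference(halves), 0.0)

    def test_linear_in_fd_gives_zero(self):
        fd_low = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        fd_high = fd_low + 0.2
        Ylow = np.outer(2 + 3 * fd_low, np.ones(3))
        Yhigh = np.outer(1 - 2 * fd_high, np.ones(3))
        halves = make_halves(Ylow, Yhigh, fd_low, fd_high, 3)
        assert np.allclose(residual_difference(halves), 0.0, atol=1e-12)

    def test_matches_statsmodels_residuals(self):
        rng = np.random.default_rng(1)
        n, E = 5, 6
        Ylow, Yhigh = rng.standard_normal((2, n, E))
        fd_low, fd_high = rng.uniform(0.05, 0.5, size=(2, n))
        halves = make_halves(Ylow, Yhigh, fd_low, fd_high, 4)
        got = residual_difference(halves)
        for e in range(E):
            rl = sm.OLS(Ylow[:, e], sm.add_constant(fd_low)).fit().resid
            rh = sm.OLS(Yhigh[:, e], sm.add_constant(fd_high)).fit().resid
            assert np.allclose(got[:, e], rh - rl, atol=1e-10)

    def test_constant_fd_rejected(self):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((4, 3))
        halves = make_halves(Y, Y, np.full(4, 0.2), rng.uniform(size=4), 3)
        with pytest.raises(ValueError, match="rank"):
            residual_difference(halves)


class TestImpactGLM:
    def test_zero_diff_gives_zero_map(self):
        model = TraitModel(trait=np.arange(1.0, 7.0))
        m = impact_glm(np.zeros((6, 4)), model)
        assert np.allclose(m.beta, 0) and np.allclose(m.t, 0)

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(3)
        trait = rng.uniform(1, 3, size=200)
        diff = np.outer(trait, [2.0, -1.5]) + 1e-4 * rng.standard_normal((200, 2))
        m = impact_glm(diff, TraitModel(trait=trait))
        assert np.allclose(m.beta, [2.0, -1.5], rtol=0.01)

    def test_matches_statsmodels_with_covariate(self):
        rng = np.random.default_rng(4)
        n = 6
        trait = rng.uniform(size=n)
        cov = rng.uniform(size=(n, 1))
        diff = rng.standard_normal((n, 5))
        m = impact_glm(diff, TraitModel(trait=trait, covariates=cov))
        X = sm.add_constant(np.column_stack([trait, cov]))
        for e in range(5):
            fit = sm.OLS(diff[:, e], X).fit()
            assert np.isclose(m.beta[e], fit.params[1], atol=1e-10)
            assert np.isclose(m.t[e], fit.tvalues[1], atol=1e-10)
        assert m.df == n - 3

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            impact_glm(np.zeros((2, 3)), TraitModel(trait=np.array([1.0, 2.0])))


class TestStouffer:
    def test_closed_form_hand_example(self):
        assert np.isclose(stouffer_z([0.5, 1.5, -1.0]), 0.5773502691896258,
                          atol=1e-12)

    def test_closed_form_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            E = rng.integers(1, 101)
            z = rng.standard_normal(E)
            assert np.isclose(stouffer_z(z), z.sum() / np.sqrt(E), atol=1e-12)

    def test_single_edge_reduces_to_edge_z(self):
        rng = np.random.default_rng(6)
        obs = np.array([3.0])
        null = rng.standard_normal((99, 1))
        Z, p, edge_z, _ = npc_stouffer(obs, null, direction="two_sided")
        assert np.isclose(Z, edge_z[0])

    def test_addone_counting_oracle(self):
        rng = np.random.default_rng(7)
        E, P = 4, 99
        null = rng.standard_normal((P, E))
        obs = np.abs(null).max(axis=0) + 1.0  # beats every null at every edge
        Z, p, edge_z, _ = npc_stouffer(obs, null, direction="two_sided")
        assert p == pytest.approx(1 / 100)
        from scipy.stats import norm
        assert np.allclose(edge_z, norm.isf(1 / 100))

    def test_empty_include_warns_and_degenerates(self):
        rng = np.random.default_rng(8)
        with pytest.warns(UserWarning):
            Z, p, *_ = npc_stouffer(rng.standard_normal(3),
                                    rng.standard_normal((10, 3)),
                                    include=np.zeros(3, bool))
        assert Z == 0.0 and p == 1.0


class TestDirectionalScores:
    def test_fully_gated_degenerates(self):
        rng = np.random.default_rng(9)
        impact = ImpactMap(beta=np.zeros(4), t=rng.standard_normal(4), df=10)
        null = NullEnsemble(stats=rng.standard_normal((20, 4)))
        with pytest.warns(UserWarning):
            over_z, over_p, under_z, under_p = directional_scores(
                impact, np.full(4, 1.0), null, gate=2)
        assert over_p == 1.0 and under_p == 1.0

    def test_aligned_signs_empty_underestimation_set(self):
        t = np.array([3.0, -4.0, 5.0])
        impact = ImpactMap(beta=t, t=t, df=10)
        null = NullEnsemble(stats=np.random.default_rng(10).standard_normal((50, 3)))
        over_z, over_p, under_z, under_p = directional_scores(impact, t, null)
        assert over_z > 0
        assert over_p < under_p

    def test_trait_negation_invariance(self):
        rng = np.random.default_rng(11)
        t_imp = rng.standard_normal(6) * 3
        t_fc = rng.standard_normal(6) * 3
        null = rng.standard_normal((40, 6))
        a = directional_scores(ImpactMap(beta=t_imp, t=t_imp, df=9), t_fc,
                               NullEnsemble(stats=null))
        b = directional_scores(ImpactMap(beta=-t_imp, t=-t_imp, df=9), -t_fc,
                               NullEnsemble(stats=-null))
        assert np.allclose(a, b)

    def test_disjoint_sets_never_double_count(self):
        # impact sign equal vs opposite to trait-FC sign partitions the
        # non-gated edges; scoring both directions on a one-edge problem
        # can never mark the same edge over- and under-estimated
        t_fc = np.array([5.0])
        for t_val in (3.0, -3.0):
            impact = ImpactMap(beta=np.array([t_val]), t=np.array([t_val]), df=8)
            null = NullEnsemble(stats=np.random.default_rng(12).standard_normal((30, 1)))
            over_z, _, under_z, _ = directional_scores(impact, t_fc, null)
            assert (over_z != 0) != (under_z != 0)


class TestRunShaman:
    def test_determinism(self, tiny_cohort):
        model = TraitModel(trait=tiny_cohort.trait)
        a = run_shaman(tiny_cohort.participants, model, n_perm=8, seed=3)
        b = run_shaman(tiny_cohort.participants, model, n_perm=8, seed=3)
        assert a.omnibus_z == b.omnibus_z
        assert a.omnibus_p == b.omnibus_p
        assert np.array_equal(a.null.stats, b.null.stats)

    def test_p_floor_respected(self, tiny_cohort):
        model = TraitModel(trait=tiny_cohort.trait)
        res = run_shaman(tiny_cohort.participants, model, n_perm=8, seed=4)
        for p in (res.omnibus_p, res.over_p, res.under_p):
            assert 1 / 9 <= p <= 1

    def test_invalid_n_perm(self, tiny_cohort):
        with pytest.raises(ValueError):
            run_shaman(tiny_cohort.participants,
                       TraitModel(trait=tiny_cohort.trait), n_perm=0, seed=0)

    def test_estimator_api(self, tiny_cohort):
        est = MotionImpactScore(n_perm=8, random_state=5)
        est.fit(tiny_cohort.participants, tiny_cohort.trait)
        assert hasattr(est, "omnibus_z_") and hasattr(est, "over_p_")
        assert est.edge_z_.shape[0] == 16 * 15 // 2
        params = est.get_params()
        assert params["n_perm"] == 8 and params["random_state"] == 5
        clone_params = MotionImpactScore(**params).get_params()
        assert clone_params == params
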