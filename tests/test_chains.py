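import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evograph.chains import (
    bd_chain_absorption,
    complete_fixation_prob,
    directed_line_times,
    family_chain,
    star_chain,
    star_extinction,
    star_fixation,
    star_neutral_closed_forms,
    star_neutral_tau_T_closed,
    star_phi_T,
    star_temperature_summary,
)

from _oracles import bd_dense_oracle, bd_tau1_nested_sum, star_dense_oracle


class TestStarChainStructure:
    def test_unit_star_transition_probabilities(self):
        c = star_chain(2, 1.0, 1.0, 1.0)
        np.testing.assert_allclose(c.T_up_center()[0], 1 / 3)
        np.testing.assert_allclose(c.T_down_center()[0], 2 / 3)
        np.testing.assert_allclose(c.T_up_leaf()[0], 1 / 3)
        np.testing.assert_allclose(c.T_down_leaf()[0], 1 / 6)
        assert c.pi_up_center == pytest.approx(1 / 3)

    @given(
        n=st.integers(2, 30),
        lam=st.floats(0.05, 1.0),
        delta=st.floats(0.05, 1.0),
        r=st.floats(0.1, 10.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conditional_probabilities_and_sojourns(self, n, lam, delta, r):
        c = star_chain(n, lam, delta, r)
        assert c.pi_up_center + c.pi_down_center == pytest.approx(1.0, abs=1e-12)
        assert c.pi_up_leaf + c.pi_down_leaf == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            c.sojourn_center() * (c.T_up_center() + c.T_down_center()), 1.0, atol=1e-12
        )
        np.testing.assert_allclose(
            c.sojourn_leaf() * (c.T_up_leaf() + c.T_down_leaf()), 1.0, atol=1e-12
        )
        w_c, w_l = c.temperature_weights()
        assert w_c + w_l == pytest.approx(1.0, abs=1e-12)

    def test_neutral_sojourn_closed_form(self):
        c = star_chain(2, 0.5, 0.25, 1.0)
        assert c.sojourn_center()[0] == pytest.approx(2.4)


class TestStarAbsorption:
    """Frozen values from the exact 5-state chain at n = 2."""

    def test_unit_star_fixation(self):
        fix = star_fixation(star_chain(2, 1.0, 1.0, 1.0))
        assert fix.phi_center[0] == pytest.approx(1 / 5, rel=1e-12)
        assert fix.phi_leaf[1] == pytest.approx(2 / 5, rel=1e-12)
        assert fix.tau_0_center == pytest.approx(6.2, rel=1e-12)
        assert fix.tau_1_leaf == pytest.approx(7.2, rel=1e-12)

    def test_weighted_star_fixation(self):
        fix = star_fixation(star_chain(2, 0.5, 0.25, 1.0))
        assert fix.tau_0_center == pytest.approx(364 / 15, rel=1e-12)
        assert fix.tau_1_leaf == pytest.approx(400 / 15, rel=1e-12)

    def test_unit_star_extinction(self):
        ext = star_extinction(star_chain(2, 1.0, 1.0, 1.0))
        assert ext.phi_leaf[1] == pytest.approx(3 / 5, rel=1e-12)
        assert ext.tau_1_leaf == pytest.approx(5.2, rel=1e-12)
        assert ext.tau_0_center == pytest.approx(2.2, rel=1e-12)

    def test_temperature_summary(self):
        s = star_temperature_summary(star_chain(2, 1.0, 1.0, 1.0))
        assert s.phi_T == pytest.approx(4 / 15, rel=1e-12)
        assert s.tau_T == pytest.approx(98 / 15, rel=1e-12)
        assert s.tau_ext_T == pytest.approx(3.2, rel=1e-12)
        s2 = star_temperature_summary(star_chain(2, 0.5, 0.25, 1.0))
        assert s2.tau_T == pytest.approx(379 / 15, rel=1e-12)

    def test_fixation_time_from_center_is_one_sojourn_above_state_one(self):
        # tau_0 = tau_1 + t_0 (the +1 form holds when the sojourn is one step)
        fix = star_fixation(star_chain(4, 1.0, 1.0, 1.0))
        assert fix.tau_center[0] == pytest.approx(fix.tau_center[1] + 1.0, rel=1e-10)
        c = star_chain(3, 0.5, 0.25, 1.0)
        fix = star_fixation(c)
        assert fix.tau_center[0] == pytest.approx(
            fix.tau_center[1] + c.sojourn_center()[0], rel=1e-10
        )

    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("n", [2, 3, 4, 6])
    def test_extinction_probability_is_fixation_complement(self, n, r):
        c = star_chain(n, 0.7, 0.4, r)
        fix, ext = star_fixation(c), star_extinction(c)
        np.testing.assert_allclose(fix.phi_center + ext.phi_center, 1.0, atol=1e-12)
        np.testing.assert_allclose(fix.phi_leaf + ext.phi_leaf, 1.0, atol=1e-12)

    def test_boundary_leaf_state_cannot_fix(self):
        fix = star_fixation(star_chain(5, 0.3, 0.9, 1.7))
        assert fix.phi_leaf[0] == 0.0

    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    def test_dense_chain_oracle_equivalence(self, r):
        for n in (2, 3, 4):
            for lam, delta in ((1.0, 1.0), (0.5, 0.5), (1 / n, 1 / n**2), (0.25, 1.0)):
                c = star_chain(n, lam, delta, r)
                oracle = star_dense_oracle(c)
                fix, ext = star_fixation(c), star_extinction(c)
                np.testing.assert_allclose(fix.phi_center, oracle["phi_center"], rtol=1e-9)
                np.testing.assert_allclose(fix.phi_leaf, oracle["phi_leaf"], rtol=1e-9)
                np.testing.assert_allclose(
                    fix.tau_center[:-1], oracle["tau_fix_center"][:-1], rtol=1e-9
                )
                np.testing.assert_allclose(
                    fix.tau_leaf[1:], oracle["tau_fix_leaf"][1:], rtol=1e-9
                )
                np.testing.assert_allclose(
                    ext.tau_center[:-1], oracle["tau_ext_center"][:-1], rtol=1e-9
                )
                np.testing.assert_allclose(
                    ext.tau_leaf[1:], oracle["tau_ext_leaf"][1:], rtol=1e-9
                )

    def test_closed_phi_T_matches_summary(self):
        for n, lam, delta, r in [(5, 1.0, 1.0, 0.7), (9, 1 / 9, 1 / 81, 2.0), (4, 0.5, 0.8, 1.0)]:
            summary = star_temperature_summary(star_chain(n, lam, delta, r))
            assert star_phi_T(n, lam, delta, r) == pytest.approx(summary.phi_T, rel=1e-10)


class TestStarNeutralClosedForms:
    @pytest.mark.parametrize("n", [2, 5, 20, 80, 200])
    def test_closed_form_equals_recursion(self, n):
        for lam, delta in ((1.0, 1.0), (0.5, 0.25), (1 / n, 1 / n**2)):
            want = star_neutral_closed_forms(n, lam, delta)
            got = star_temperature_summary(star_chain(n, lam, delta, 1.0))
            assert got.tau_T == pytest.approx(want["tau_T"], rel=1e-8)
            fix = star_fixation(star_chain(n, lam, delta, 1.0))
            assert fix.tau_0_center == pytest.approx(want["tau_0_center"], rel=1e-8)
            assert fix.tau_1_leaf == pytest.approx(want["tau_1_leaf"], rel=1e-8)

    @pytest.mark.parametrize("n", [2, 3, 10, 100, 1000])
    def test_reduced_variants_agree_with_generic_form(self, n):
        assert star_neutral_tau_T_closed(n, "selflooped_weighted") == pytest.approx(
            star_neutral_closed_forms(n, 1 / n, 1 / n**2)["tau_T"], rel=1e-10
        )
        assert star_neutral_tau_T_closed(n, "star") == pytest.approx(
            star_neutral_closed_forms(n, 1.0, 1.0)["tau_T"], rel=1e-10
        )

    def test_selflooped_weighted_star_reaches_n5_scaling(self):
        n = 4000
        assert star_neutral_tau_T_closed(n, "selflooped_weighted") / n**5 == pytest.approx(
            1.0, rel=2e-3
        )

    def test_neutral_fixation_probabilities(self):
        # phi_center = (delta + i n lam)/(delta + n^2 lam) at neutrality
        n, lam, delta = 6, 0.37, 0.81
        fix = star_fixation(star_chain(n, lam, delta, 1.0))
        i = np.arange(n + 1)
        np.testing.assert_allclose(
            fix.phi_center, (delta + i * n * lam) / (delta + n**2 * lam), rtol=1e-10
        )
        np.testing.assert_allclose(
            fix.phi_leaf, i * n * lam / (delta + n**2 * lam), rtol=1e-10
        )


class TestBDChains:
    def test_neutral_complete_values(self):
        s = bd_chain_absorption(family_chain("complete", 3, 1.0))
        assert s.phi_T == pytest.approx(1 / 3, rel=1e-12)
        assert s.tau_T == pytest.approx(4.0, rel=1e-12)

    def test_complete_N2_equals_direct_formula(self):
        s = bd_chain_absorption(family_chain("complete", 2, 2.0))
        assert s.phi_T == pytest.approx(complete_fixation_prob(2.0, 1.0, 2), rel=1e-12)
        assert s.phi_T == pytest.approx(2 / 3, rel=1e-12)

    @pytest.mark.parametrize("N,expected", [(3, 4.0), (4, 10.0), (10, 165.0)])
    def test_neutral_cycle_times(self, N, expected):
        s = bd_chain_absorption(family_chain("cycle", N, 1.0))
        assert s.tau_T == pytest.approx(expected, rel=1e-12)

    def test_complete_N2_neutral_transition_probabilities(self):
        c = family_chain("complete", 2, 1.0)
        assert c.T_plus[0] == pytest.approx(0.5)
        assert c.T_minus[0] == pytest.approx(0.5)

    def test_isothermal_families_share_gamma_and_phi(self):
        cc = family_chain("complete", 5, 2.0)
        cy = family_chain("cycle", 5, 2.0)
        np.testing.assert_allclose(cc.gamma(), cy.gamma(), rtol=1e-12)
        np.testing.assert_allclose(
            bd_chain_absorption(cc).fixation_prob,
            bd_chain_absorption(cy).fixation_prob,
            rtol=1e-12,
        )

    @pytest.mark.parametrize("family", ["complete", "cycle"])
    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    def test_tridiagonal_solve_matches_nested_sum_and_dense_oracle(self, family, r):
        for N in (5, 10):
            c = family_chain(family, N, r)
            s = bd_chain_absorption(c)
            assert s.tau_T == pytest.approx(bd_tau1_nested_sum(c), rel=1e-10)
            oracle = bd_dense_oracle(c)
            np.testing.assert_allclose(s.fixation_prob, oracle["phi"], atol=1e-12)
            np.testing.assert_allclose(
                s.cond_fixation_time[1:], oracle["tau_fix"][1:], rtol=1e-9
            )
            np.testing.assert_allclose(
                s.cond_extinction_time[:-1], oracle["tau_ext"][:-1], rtol=1e-9
            )

    def test_extinction_only_chain_is_flagged(self):
        from evograph.chains import BDChain

        c = BDChain(N=3, T_plus=np.array([0.0, 0.2]), T_minus=np.array([0.3, 0.2]))
        s = bd_chain_absorption(c)
        assert s.meta.get("extinction_only") is True
        assert s.fixation_prob[1] == 0.0


class TestCompleteFixationProb:
    def test_neutral_limit(self):
        assert complete_fixation_prob(3.0, 3.0, 17) == pytest.approx(1 / 17)

    def test_examples(self):
        assert complete_fixation_prob(2.0, 1.0, 2) == pytest.approx(2 / 3, rel=1e-12)
        assert complete_fixation_prob(2.0, 1.0, 10) == pytest.approx(0.5 / (1 - 2**-10), rel=1e-12)

    def test_monotone_in_mutant_fitness(self):
        r = np.linspace(0.2, 5.0, 50)
        phi = complete_fixation_prob(r, np.ones_like(r), 10)
        assert np.all(np.diff(phi) > 0)

    def test_large_N_stability(self):
        assert complete_fixation_prob(2.0, 1.0, 10**6) == pytest.approx(0.5, rel=1e-9)
        assert complete_fixation_prob(1.0, 2.0, 10**6) == pytest.approx(0.0, abs=1e-300)
        assert complete_fixation_prob(1.0, 2.0, 50) > 0


class TestDirectedLine:
    def test_fixation_time_closed_form(self):
        assert directed_line_times(10, 1.0).tau_fix == pytest.approx(180.0, rel=1e-12)
        for N, r in [(5, 0.3), (50, 2.0), (200, 7.0)]:
            assert directed_line_times(N, r).tau_fix == pytest.approx(
                N * (N - 1) * (1 + 1 / r), rel=1e-12
            )

    def test_extinction_approximation_small_case(self):
        dl = directed_line_times(3, 1.0)
        np.testing.assert_allclose(dl.tau_ext_per_node, [7.0, 12.0])
        # temperature weights on non-root nodes: bulk 1, terminal 3/2
        assert dl.tau_ext_T == pytest.approx((1 * 7 + 1.5 * 12) / 2.5, rel=1e-12)

    def test_infinite_fitness_limit(self):
        assert directed_line_times(10, 1e12).tau_fix == pytest.approx(90.0, rel=1e-9)


class TestFixationExtinctionOrdering:
    """Near neutrality the fixation of a mutant takes longer than its loss."""

    R_GRID = np.logspace(np.log10(0.25), np.log10(4.0), 13)

    @pytest.mark.parametrize("family", ["complete", "cycle"])
    def test_isothermal_times_ordered_and_peaked(self, family):
        taus = {}
        for r in self.R_GRID:
            s = bd_chain_absorption(family_chain(family, 10, float(r)))
            assert s.tau_T > s.tau_ext_T, (family, r)
            taus[float(r)] = s.tau_T
        peak = max(taus, key=taus.get)
        assert 0.8 <= peak <= 1.25

    @pytest.mark.parametrize("lam,delta", [(1.0, 1.0), (1 / 9, 1 / 81)])
    def test_star_times_ordered_and_peaked(self, lam, delta):
        taus = {}
        for r in self.R_GRID:
            s = star_temperature_summary(star_chain(9, lam, delta, float(r)))
            assert s.tau_T > s.tau_ext_T, r
            taus[float(r)] = s.tau_T
        peak = max(taus, key=taus.get)
        assert 0.8 <= peak <= 1.25
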