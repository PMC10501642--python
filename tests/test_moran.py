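import numpy as np
import pytest

from evograph.chains import star_chain, star_temperature_summary
from evograph.graphs import build_family
from evograph.kernels import MutationKernel
from evograph.moran import (
    PopulationState,
    initial_mutant_node,
    moran_step,
    run_mutation_selection,
    run_two_type_fixation,
)

from conftest import F_MIN, F_MAX, assert_within_se


class TestMoranStep:
    def test_reproducer_is_fitness_proportional(self, uniform_kernel, rng):
        g = build_family("complete", 2)
        state = PopulationState(np.array([1.0, 3.0]))
        picks = np.array(
            [moran_step(state, g, uniform_kernel, 0.0, rng)[1].reproducer for _ in range(4000)]
        )
        p_hat = (picks == 0).mean()
        assert_within_se(p_hat, 0.25, np.sqrt(0.25 * 0.75 / 4000), label="reproducer prob")

    def test_self_replacement_through_the_loop(self, uniform_kernel, rng):
        g = build_family("selflooped_complete", 2)
        state = PopulationState(np.array([1.0, 1.0]))
        infos = [moran_step(state, g, uniform_kernel, 0.0, rng)[1] for _ in range(4000)]
        self_hits = np.array([i.target == i.reproducer for i in infos])
        assert_within_se(self_hits.mean(), 0.5, np.sqrt(0.25 / 4000), label="self-loop prob")

    def test_no_mutation_only_copies_values(self, uniform_kernel, rng):
        g = build_family("cycle", 5)
        state = PopulationState(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        for _ in range(50):
            state, info = moran_step(state, g, uniform_kernel, 0.0, rng)
            assert set(np.round(state.fitness, 12)) <= {1.0, 2.0, 3.0, 4.0, 5.0}
            assert not info.mutated

    def test_sink_reproducer_changes_nothing(self, uniform_kernel, rng):
        g = build_family("burst", 4)
        state = PopulationState(np.array([1.0, 100.0, 100.0, 100.0]))
        # leaves carry almost all fitness, so a sink reproducer is near-certain
        new, info = moran_step(state, g, uniform_kernel, 1.0, rng)
        if info.target == -1:
            np.testing.assert_array_equal(new.fitness, state.fitness)

    def test_contract_errors(self, uniform_kernel, rng):
        g = build_family("complete", 3)
        with pytest.raises(ValueError, match="mutation probability"):
            moran_step(PopulationState(np.ones(3)), g, uniform_kernel, 1.5, rng)
        with pytest.raises(ValueError, match="dimensions"):
            moran_step(PopulationState(np.ones(4)), g, uniform_kernel, 0.5, rng)
        with pytest.raises(ValueError, match="positive"):
            PopulationState(np.array([1.0, 0.0]))


class TestMutationSelection:
    def test_zero_mutation_homogeneous_state_is_frozen(self, uniform_kernel):
        g = build_family("complete", 6)
        s = run_mutation_selection(
            g, uniform_kernel, 0.0, 2000, 4, seed=1, initial_fitness=2.5
        )
        np.testing.assert_array_equal(s.mean_series, 2.5)
        np.testing.assert_array_equal(s.final_fitness, 2.5)

    def test_seed_reproducibility(self, uniform_kernel):
        g = build_family("selflooped_complete", 5)
        a = run_mutation_selection(g, uniform_kernel, 1.0, 1000, 5, seed=3)
        b = run_mutation_selection(g, uniform_kernel, 1.0, 1000, 5, seed=3)
        np.testing.assert_array_equal(a.mean_series, b.mean_series)
        np.testing.assert_array_equal(a.final_fitness, b.final_fitness)
        c = run_mutation_selection(g, uniform_kernel, 1.0, 1000, 5, seed=4)
        assert not np.array_equal(a.final_fitness, c.final_fitness)

    def test_high_mu_reference_mean(self, uniform_kernel):
        g = build_family("selflooped_complete", 10)
        s = run_mutation_selection(g, uniform_kernel, 1.0, 4000, 300, seed=21)
        sd_pred = (F_MAX - F_MIN) / np.sqrt(12 * 10)
        assert_within_se(
            s.ensemble_mean, (F_MIN + F_MAX) / 2, sd_pred / np.sqrt(300), label="SC mean"
        )

    def test_selflooped_star_center_runs_hotter_than_leaves(self, uniform_kernel):
        g = build_family("selflooped_weighted_star", 10)
        s = run_mutation_selection(g, uniform_kernel, 1.0, 10_000, 300, seed=8)
        per_rep_center = s.node_avg[:, 0]
        per_rep_leaves = s.node_avg[:, 1:].mean(axis=1)
        diff = per_rep_center - per_rep_leaves
        se = diff.std(ddof=1) / np.sqrt(diff.size)
        assert diff.mean() > 3 * se

    def test_directed_line_root_is_coldest(self, uniform_kernel):
        g = build_family("selflooped_directed_line", 10)
        s = run_mutation_selection(g, uniform_kernel, 1.0, 10_000, 300, seed=9)
        node_avg = s.node_time_average()
        assert node_avg[0] == node_avg.min()

    def test_truncated_gaussian_fitness_stays_in_domain(self):
        k = MutationKernel("truncated_gaussian", F_MIN, F_MAX, sigma=0.5)
        g = build_family("complete", 5)
        s = run_mutation_selection(g, k, 1.0, 3000, 4, seed=5)
        assert s.final_fitness.min() >= F_MIN and s.final_fitness.max() <= F_MAX

    def test_contract_errors(self, uniform_kernel):
        g = build_family("complete", 4)
        with pytest.raises(ValueError, match="n_steps"):
            run_mutation_selection(g, uniform_kernel, 1.0, 0, 4, seed=1)
        with pytest.raises(ValueError, match="replicates"):
            run_mutation_selection(g, uniform_kernel, 1.0, 10, 1, seed=1)
        with pytest.raises(ValueError, match="burn_in"):
            run_mutation_selection(g, uniform_kernel, 1.0, 10, 4, seed=1, burn_in_fraction=1.0)


class TestTwoTypeFixation:
    def test_neutral_complete_fixation_probability(self):
        g = build_family("complete", 3)
        est = run_two_type_fixation(g, 1.0, "uniform", 3000, seed=5)
        assert_within_se(est.phi, 1 / 3, est.phi_se, label="neutral phi")
        assert est.n_truncated == 0

    def test_star_temperature_init_matches_chain_analytics(self):
        g = build_family("star", 3)
        est = run_two_type_fixation(g, 1.0, "temperature", 4000, seed=6)
        exact = star_temperature_summary(star_chain(2, 1.0, 1.0, 1.0))
        assert_within_se(est.phi, exact.phi_T, est.phi_se, label="star phi")
        assert_within_se(est.tau_fix_T, exact.tau_T, est.tau_fix_T_se, label="star tau")
        assert_within_se(est.tau_ext_T, exact.tau_ext_T, est.tau_ext_T_se, label="star tau ext")
        assert est.tau_fix > est.tau_ext

    @pytest.mark.parametrize("family,r", [("complete", 2.0), ("cycle", 0.5), ("star", 1.0)])
    def test_families_match_chain_phi(self, family, r):
        from evograph.chains import bd_chain_absorption, family_chain

        g = build_family(family, 6)
        est = run_two_type_fixation(g, r, "temperature", 2000, seed=13)
        if family == "star":
            exact = star_temperature_summary(star_chain(5, 1.0, 1.0, r)).phi_T
        else:
            exact = bd_chain_absorption(family_chain(family, 6, r)).phi_T
        assert_within_se(est.phi, exact, max(est.phi_se, 1e-9), label=f"{family} phi")

    def test_mutant_off_root_of_directed_line_never_fixes(self):
        g = build_family("selflooped_directed_line", 5)
        est = run_two_type_fixation(g, 5.0, 3, 200, seed=7)
        assert est.n_fixed == 0 and est.no_fixation_observed
        assert np.isnan(est.tau_fix)

    def test_initial_node_schemes(self, rng):
        g = build_family("star", 10)
        T = g.temperatures()
        draws = np.array([initial_mutant_node(g, "temperature", rng) for _ in range(4000)])
        p_center = (draws == 0).mean()
        assert_within_se(
            p_center, T[0] / 10, np.sqrt(p_center * (1 - p_center) / 4000), label="temp init"
        )
        assert initial_mutant_node(g, 4, rng) == 4
        with pytest.raises(ValueError):
            initial_mutant_node(g, 99, rng)
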