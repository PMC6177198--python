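"""Monte-Carlo simulator checks: payoff collection, elementary updates,
neutral drift, ergodicity, and agreement with the enumerated-chain oracle."""

import numpy as np
import pytest

from aspiradyn.dynamics import (
    SimulationConfig,
    focal_payoff_averaged,
    focal_payoff_single,
    run_chain,
    step,
)
from aspiradyn.exact_solver import build_chain, exact_abundance
from aspiradyn.model_core import AspirationProfile, PayoffTable, fermi_function
from aspiradyn.structures import make_random_graph, make_ring, make_well_mixed


class TestSingleGamePayoff:
    def test_row_and_column_selection(self, fig_table, rng):
        ring = make_ring(6)
        state = np.array([1, 0, 0, 0, 0, 0], dtype=np.int8)
        # focal 0 plays A against B,B -> a_0 = 3
        assert focal_payoff_single(ring, state, fig_table, 0, rng) == 3.0
        # focal 1 plays B against coplayers (A, B) -> b_1 = 1
        assert focal_payoff_single(ring, state, fig_table, 1, rng) == 1.0

    def test_homogeneous_states_force_extreme_columns(self, fig_table, rng):
        ring = make_ring(6)
        all_a = np.ones(6, dtype=np.int8)
        all_b = np.zeros(6, dtype=np.int8)
        assert focal_payoff_single(ring, all_a, fig_table, 2, rng) == fig_table.a[-1]
        assert focal_payoff_single(ring, all_b, fig_table, 2, rng) == fig_table.b[0]


class TestAveragedPayoff:
    def test_homogeneous_states(self, fig_table):
        ring = make_ring(6)
        assert focal_payoff_averaged(ring, np.zeros(6, dtype=np.int8), fig_table, 1) == 4.0
        assert focal_payoff_averaged(ring, np.ones(6, dtype=np.int8), fig_table, 1) == 1.0

    def test_hand_enumerated_four_cycle(self, fig_table):
        # ring 0-1-2-3-0, state (A,B,A,B), focal 0: own game coplayers
        # {1,3} -> a_0 = 3; games organised by 1 and 3 each have coplayers
        # with one A -> a_1 = 2 twice; mean = 7/3
        ring = make_ring(4)
        state = np.array([1, 0, 1, 0], dtype=np.int8)
        assert focal_payoff_averaged(ring, state, fig_table, 0) == pytest.approx(7.0 / 3.0)

    def test_rejects_non_regular_structures(self, fig_table):
        ba = make_random_graph(30, "barabasi_albert", m=2, rng_seed=0)
        with pytest.raises(ValueError):
            focal_payoff_averaged(ba, np.zeros(30, dtype=np.int8), fig_table, 0)


class TestStep:
    def test_changes_at_most_one_individual(self, fig_table, rng):
        ring = make_ring(10)
        profile = AspirationProfile(e=rng.uniform(0, 5, 10))
        cfg = SimulationConfig(beta=0.5, n_steps=10, rng_seed=0)
        g = fermi_function()
        state = np.zeros(10, dtype=np.int8)
        for _ in range(100):
            before = state.copy()
            state = step(ring, state, fig_table, profile, g, cfg, rng)
            assert np.sum(before != state) <= 1

    def test_neutral_flip_rate_is_one_half(self, fig_table, rng, fermi):
        ring = make_ring(10)
        profile = AspirationProfile(e=rng.uniform(0, 5, 10))
        cfg = SimulationConfig(beta=0.0, n_steps=10, rng_seed=0)
        flips = 0
        state = np.zeros(10, dtype=np.int8)
        n_trials = 4000
        for _ in range(n_trials):
            before = state.copy()
            state = step(ring, state, fig_table, profile, fermi, cfg, rng)
            flips += int(np.any(before != state))
        assert flips / n_trials == pytest.approx(0.5, abs=0.03)

    def test_satisfied_individual_keeps_strategy_under_strong_selection(
        self, fig_table, fermi, rng
    ):
        # aspiration far below payoff: flip probability ~ 0
        ring = make_ring(6)
        profile = AspirationProfile(e=np.full(6, -100.0))
        cfg = SimulationConfig(beta=10.0, n_steps=10, rng_seed=0)
        state = np.zeros(6, dtype=np.int8)
        for _ in range(300):
            state = step(ring, state, fig_table, profile, fermi, cfg, rng)
        assert np.all(state == 0)


class TestRunChain:
    def test_neutral_drift_centres_on_one_half(self, fig_table, fermi):
        ring = make_ring(50)
        profile = AspirationProfile(e=np.linspace(-3, 3, 50))
        cfg = SimulationConfig(beta=0.0, n_steps=2_100_000, burn_in=100_000, rng_seed=7)
        res = run_chain(ring, fig_table, profile, fermi, cfg)
        assert abs(res.mean_abundance_a - 0.5) <= 3 * res.std_error

    def test_equal_payoffs_neutral_at_strong_selection(self, fermi):
        wm = make_well_mixed(40)
        profile = AspirationProfile(e=np.linspace(0, 5, 40))
        cfg = SimulationConfig(beta=1.0, n_steps=2_100_000, burn_in=100_000, rng_seed=8)
        res = run_chain(wm, PayoffTable.constant(3, 2.0), profile, fermi, cfg)
        assert abs(res.mean_abundance_a - 0.5) <= 3 * res.std_error

    @pytest.mark.parametrize("beta", [0.0, 0.05, 0.5])
    def test_matches_exact_solver_on_small_ring(self, fig_table, fermi, beta):
        ring = make_ring(6)
        rng = np.random.default_rng(31)
        profile = AspirationProfile(e=rng.uniform(0, 5, 6))
        exact = exact_abundance(build_chain(ring, fig_table, profile, fermi, beta))
        cfg = SimulationConfig(beta=beta, n_steps=4_200_000, burn_in=200_000, rng_seed=17)
        res = run_chain(ring, fig_table, profile, fermi, cfg)
        assert res.mean_abundance_a == pytest.approx(exact, abs=4 * res.std_error)

    def test_well_mixed_matches_exact_marginalisation(self, fig_table, fermi):
        wm = make_well_mixed(6)
        rng = np.random.default_rng(32)
        profile = AspirationProfile(e=rng.uniform(0, 5, 6))
        exact = exact_abundance(build_chain(wm, fig_table, profile, fermi, 0.5))
        cfg = SimulationConfig(beta=0.5, n_steps=4_200_000, burn_in=200_000, rng_seed=18)
        res = run_chain(wm, fig_table, profile, fermi, cfg)
        assert res.mean_abundance_a == pytest.approx(exact, abs=4 * res.std_error)

    def test_averaged_scheme_matches_exact(self, fig_table, fermi):
        ring = make_ring(6)
        rng = np.random.default_rng(33)
        profile = AspirationProfile(e=rng.uniform(0, 5, 6))
        exact = exact_abundance(
            build_chain(ring, fig_table, profile, fermi, 0.3, "averaged_d_games")
        )
        cfg = SimulationConfig(
            beta=0.3, n_steps=4_200_000, burn_in=200_000,
            payoff_scheme="averaged_d_games", rng_seed=19,
        )
        res = run_chain(ring, fig_table, profile, fermi, cfg)
        assert res.mean_abundance_a == pytest.approx(exact, abs=4 * res.std_error)

    def test_python_fallback_agrees_with_kernel(self, fig_table, fermi):
        # same semantics, different loop: compare a non-fermi-named copy
        from aspiradyn.model_core import DecisionFunction
        from scipy.special import expit

        slow_fermi = DecisionFunction(
            evaluate=expit, derivative_at_zero=0.25,
            second_derivative_at_zero=0.0, name="fermi-python",
        )
        ring = make_ring(8)
        profile = AspirationProfile(e=np.linspace(0, 4, 8))
        cfg = SimulationConfig(beta=0.4, n_steps=220_000, burn_in=20_000, rng_seed=3)
        res_fast = run_chain(ring, fig_table, profile, fermi, cfg)
        res_slow = run_chain(ring, fig_table, profile, slow_fermi, cfg)
        joint = np.hypot(res_fast.std_error, res_slow.std_error)
        assert abs(res_fast.mean_abundance_a - res_slow.mean_abundance_a) <= 4 * joint

    def test_ergodicity_start_independence(self, fig_table, fermi):
        # no absorbing state: all-A and all-B starts reach the same regime
        ring = make_ring(20)
        profile = AspirationProfile(e=np.full(20, 2.0))
        results = []
        for start in (np.ones(20, dtype=np.int8), np.zeros(20, dtype=np.int8)):
            cfg = SimulationConfig(beta=0.5, n_steps=2_100_000, burn_in=100_000, rng_seed=5)
            results.append(run_chain(ring, fig_table, profile, fermi, cfg, initial_state=start))
        joint = np.hypot(results[0].std_error, results[1].std_error)
        assert abs(results[0].mean_abundance_a - results[1].mean_abundance_a) <= 4 * joint

    def test_label_swap_symmetry_same_seed(self, fig_table, fermi):
        ring = make_ring(30)
        profile = AspirationProfile(e=np.full(30, 2.0))
        cfg = SimulationConfig(beta=0.2, n_steps=4_100_000, burn_in=100_000, rng_seed=77)
        x = run_chain(ring, fig_table, profile, fermi, cfg)
        y = run_chain(ring, fig_table.swapped(), profile, fermi, cfg)
        joint = np.hypot(x.std_error, y.std_error)
        assert x.mean_abundance_a + y.mean_abundance_a == pytest.approx(1.0, abs=4 * joint)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(beta=-0.1, n_steps=100)
        with pytest.raises(ValueError):
            SimulationConfig(beta=0.1, n_steps=100, burn_in=100)
        with pytest.raises(ValueError):
            SimulationConfig(beta=0.1, n_steps=100, init_fraction_a=1.5)
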