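"""Evolutionary engine: initialization, round payoffs, learning rules, runs."""

import math

import numpy as np
import pytest

from mobilize_net import (
    GeneratorConfig,
    LearningParameters,
    SimulationConfig,
    Strategy,
    TypedNetwork,
    adoption_probability,
    initialize_strategies,
    play_round,
    run_simulation,
    select_learning_target,
    selection_probabilities,
    step,
)
from mobilize_net.engine import RoundPayoffs

POS, NEG = Strategy.POSITIVE, Strategy.NEGATIVE


def all_with(net, strategy):
    return {n: strategy for n in net.node_ids}


class TestInitialization:
    @pytest.mark.parametrize(
        "m0,r0,exp_srs,exp_grs",
        [(0.0, 0.0, 0, 0), (1.0, 1.0, 49, 19), (0.1, 0.4, 5, 8)],
    )
    def test_exact_counts(self, default_network, m0, r0, exp_srs, exp_grs):
        rng = np.random.default_rng(0)
        strat = initialize_strategies(default_network, m0, r0, rng)
        srs_pos = sum(
            strat[n] is POS for n in default_network.nodes_with_role("SRS")
        )
        grs_pos = sum(
            strat[n] is POS for n in default_network.nodes_with_role("GRS")
        )
        assert (srs_pos, grs_pos) == (exp_srs, exp_grs)

    def test_invalid_proportion_rejected(self, default_network):
        with pytest.raises(ValueError):
            initialize_strategies(default_network, 1.2, 0.0, np.random.default_rng(0))


class TestPlayRound:
    def test_isolated_node_has_zero_gain(self, base_params):
        net = TypedNetwork(
            [("s1", "SRS"), ("g1", "GRS"), ("lone", "SRS")], [("s1", "g1")]
        )
        u = play_round(net, all_with(net, NEG), base_params).u
        assert u["lone"] == 0.0

    def test_single_positive_pair_with_reward(self, tiny_pair, base_params):
        params = base_params.replace(gamma=0.6)
        u = play_round(tiny_pair, all_with(tiny_pair, POS), params).u
        assert u["s1"] == pytest.approx(6.6)
        assert u["g1"] == pytest.approx(-2.0)

    def test_same_role_edges_carry_no_payoff(self, base_params):
        net = TypedNetwork(
            [("a", "SRS"), ("b", "SRS"), ("c", "SRS")],
            [("a", "b"), ("b", "c"), ("a", "c")],
        )
        strat = {"a": POS, "b": NEG, "c": POS}
        u = play_round(net, strat, base_params).u
        assert all(v == 0.0 for v in u.values())

    def test_gains_sum_over_cross_neighbors(self, base_params):
        net = TypedNetwork(
            [("s1", "SRS"), ("g1", "GRS"), ("g2", "GRS")],
            [("s1", "g1"), ("s1", "g2")],
        )
        strat = {"s1": NEG, "g1": POS, "g2": NEG}
        u = play_round(net, strat, base_params).u
        assert u["s1"] == pytest.approx(8 + 8)  # delta = 0
        assert u["g1"] == pytest.approx(-2)
        assert u["g2"] == pytest.approx(-3)


class TestLearningRules:
    def test_equal_gains_give_uniform_selection(self, default_network):
        node = default_network.node_ids[0]
        payoffs = RoundPayoffs(u={n: 3.0 for n in default_network.node_ids})
        probs = selection_probabilities(
            node, default_network, payoffs, LearningParameters()
        )
        k = len(default_network.neighbors(node))
        assert all(p == pytest.approx(1 / k) for p in probs.values())

    def test_two_neighbor_softmax_value(self):
        net = TypedNetwork(
            [("i", "SRS"), ("a", "GRS"), ("b", "GRS")], [("i", "a"), ("i", "b")]
        )
        payoffs = RoundPayoffs(u={"i": 0.0, "a": 1.0, "b": 0.0})
        probs = selection_probabilities(
            "i", net, payoffs, LearningParameters(lam=1.0)
        )
        e = math.e
        assert probs["a"] == pytest.approx(e / (1 + e))
        assert probs["b"] == pytest.approx(1 / (1 + e))

    def test_selection_matches_brute_force_normalization(self, default_network):
        rng = np.random.default_rng(5)
        u = {n: float(rng.normal(scale=10)) for n in default_network.node_ids}
        learning = LearningParameters(lam=1.7, alpha=0.4)
        node = default_network.node_ids[3]
        probs = selection_probabilities(
            node, default_network, RoundPayoffs(u=u), learning
        )
        raw = {
            j: math.exp((u[j] + learning.alpha) / learning.lam)
            for j in default_network.neighbors(node)
        }
        z = sum(raw.values())
        for j, p in probs.items():
            assert p == pytest.approx(raw[j] / z, rel=1e-12)

    def test_large_lambda_approaches_uniform(self):
        net = TypedNetwork(
            [("i", "SRS"), ("a", "GRS"), ("b", "GRS")], [("i", "a"), ("i", "b")]
        )
        payoffs = RoundPayoffs(u={"i": 0.0, "a": 50.0, "b": -50.0})
        probs = selection_probabilities(
            "i", net, payoffs, LearningParameters(lam=1e9)
        )
        assert probs["a"] == pytest.approx(0.5, abs=1e-6)

    def test_isolated_node_selects_nothing(self, base_params):
        net = TypedNetwork([("a", "SRS"), ("b", "GRS")], [])
        payoffs = RoundPayoffs(u={"a": 0.0, "b": 0.0})
        j = select_learning_target(
            "a", net, payoffs, LearningParameters(), np.random.default_rng(0)
        )
        assert j is None

    def test_fermi_values(self):
        assert adoption_probability(1.0, 1.0, xi=1.0) == pytest.approx(0.5)
        assert adoption_probability(1.0, 0.0, xi=1.0) == pytest.approx(
            1 / (1 + math.e)
        )
        # xi -> 0: deterministic imitation of the better-off neighbor
        assert adoption_probability(0.0, 1.0, xi=1e-12) == pytest.approx(1.0)
        assert adoption_probability(1.0, 0.0, xi=1e-12) == pytest.approx(0.0)

    def test_fermi_requires_positive_noise(self):
        with pytest.raises(ValueError):
            adoption_probability(0.0, 1.0, xi=0.0)

    def test_learning_parameter_invariants(self):
        with pytest.raises(ValueError):
            LearningParameters(lam=0)
        with pytest.raises(ValueError):
            LearningParameters(xi=-1)


class TestStep:
    @pytest.mark.parametrize("strategy", [POS, NEG])
    def test_homogeneous_states_absorbing(self, default_network, base_params, strategy):
        strat = all_with(default_network, strategy)
        rng = np.random.default_rng(3)
        new = step(default_network, strat, base_params, LearningParameters(), rng)
        assert new == strat

    def test_low_noise_forces_adoption_from_richer_neighbor(self, tiny_pair, base_params):
        # positive SRS earns 6, its negative GRS partner earns -1:
        # with xi -> 0 the GRS must copy the SRS strategy
        strat = {"s1": POS, "g1": NEG}
        learning = LearningParameters(xi=1e-9)
        rng = np.random.default_rng(0)
        new = step(tiny_pair, strat, base_params, learning, rng)
        assert new["g1"] is POS
        assert new["s1"] is POS  # SRS is richer; keeps its strategy

    def test_role_restricted_learning_switch(self, base_params):
        # with cross-role learning off, a GRS whose only neighbor is an SRS
        # has no learning object and can never change strategy
        net = TypedNetwork([("s1", "SRS"), ("g1", "GRS")], [("s1", "g1")])
        strat = {"s1": POS, "g1": NEG}
        learning = LearningParameters(xi=1e-9)
        for seed in range(5):
            new = step(
                net,
                strat,
                base_params,
                learning,
                np.random.default_rng(seed),
                cross_role_learning=False,
            )
            assert new == strat


class TestRunSimulation:
    def test_all_positive_start_stays_positive(self, base_params):
        cfg = SimulationConfig(
            params=base_params,
            network=GeneratorConfig(seed=0),
            m0=1.0,
            r0=1.0,
            rounds=30,
            reps=3,
            seed=11,
        )
        traj = run_simulation(cfg)
        assert np.all(traj.pps_all == 1.0)

    def test_all_negative_start_and_gain_level(self, base_params):
        cfg = SimulationConfig(
            params=base_params,
            network=GeneratorConfig(seed=0),
            m0=0.0,
            r0=0.0,
            rounds=10,
            reps=2,
            seed=11,
        )
        traj = run_simulation(cfg)
        assert np.all(traj.pps_all == 0.0)
        # every cross edge yields pi_e + (-c_v - c_s) = 8 - 3 = 5 total
        net = cfg.resolve_network()
        n_cross = sum(
            1 for a, b in net.edges if net.role(a) is not net.role(b)
        )
        expected = 5.0 * n_cross / len(net)
        assert np.all(np.isclose(traj.mean_gain, expected))

    def test_pps_conservation_identity(self, base_params):
        cfg = SimulationConfig(
            params=base_params.replace(gamma=0.6),
            network=GeneratorConfig(seed=2),
            m0=0.3,
            r0=0.6,
            rounds=40,
            reps=4,
            seed=5,
        )
        traj = run_simulation(cfg)
        lhs = traj.pps_all * (traj.n_grs + traj.n_srs)
        rhs = traj.pps_grs * traj.n_grs + traj.pps_srs * traj.n_srs
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_bit_identical_reruns(self, base_params):
        cfg = dict(
            params=base_params.replace(delta=1.6),
            network=GeneratorConfig(seed=4),
            m0=0.4,
            r0=0.1,
            rounds=50,
            reps=5,
            seed=42,
        )
        a = run_simulation(SimulationConfig(**cfg))
        b = run_simulation(SimulationConfig(**cfg))
        assert np.array_equal(a.pps_all, b.pps_all)
        assert np.array_equal(a.mean_gain, b.mean_gain)
        assert np.array_equal(a.absorption_round, b.absorption_round)

    def test_meanfield_echo_direction(self, base_params):
        """With gamma+delta < c_e the SRS positive fraction declines on the
        generated network, matching the sign of the mean-field drift of the
        participation fraction (negative participation pays c_e more)."""
        cfg = SimulationConfig(
            params=base_params,
            network=GeneratorConfig(seed=0),
            m0=0.5,
            r0=0.5,
            rounds=80,
            reps=6,
            seed=9,
        )
        traj = run_simulation(cfg)
        assert traj.pps_srs[:, -1].mean() < traj.pps_srs[:, 0].mean() - 0.05

    def test_trajectory_dataframe_shape(self, base_params):
        cfg = SimulationConfig(
            network=GeneratorConfig(seed=0), rounds=10, reps=2, seed=0
        )
        traj = run_simulation(cfg)
        df = traj.to_dataframe()
        assert len(df) == 2 * 11
        assert set(df.columns) == {
            "rep",
            "round",
            "pps_all",
            "pps_grs",
            "pps_srs",
            "mean_gain",
        }
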