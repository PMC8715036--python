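"""Graph construction, similarity merging and kernel-softmax transitions."""

import math

import numpy as np
import pytest

from patientsim import (
    ActionError,
    ClinicalHistory,
    GraphSim,
    GraphSimConfig,
    InputError,
    SimilarityUndefinedError,
    StateError,
    TransitionGraph,
    build_graph,
    merge_similar_states,
    run_episode,
    transition_distribution,
)
from patientsim.graphsim import Arc
from patientsim.synthetic import generate_histories

from conftest import random_graph


def brute_force_eq7(graph, node, action, config):
    """Literal double-indicator-sum oracle for the kernel-softmax transition law.

    p(s'|s, a_t) = sum over ALL arcs of 1[src=s] 1[tgt=s'] w(a) divided by
    the sum over ALL arcs of 1[src=s] w(a), with w the configured kernel.
    """

    def weight(a):
        d2 = float(np.sum((np.asarray(action) - a.action) ** 2))
        if config.literal_eq7_sign:
            return math.exp(d2 / 2.0)
        return math.exp(-d2 / (2.0 * config.kernel_bandwidth**2))

    denom = sum(weight(a) for a in graph.arcs if a.source == node)
    probs = {}
    for target in range(graph.n_nodes):
        num = sum(
            weight(a) for a in graph.arcs if a.source == node and a.target == target
        )
        if num > 0:
            probs[target] = num / denom
    return probs


class TestBuildGraph:
    def test_single_history_node_and_arc_counts(self, three_step_history):
        g = build_graph([three_step_history])
        assert g.n_nodes == 4  # 3 states + 1 terminal
        assert len(g.arcs) == 3
        assert g.initial_nodes == [0]

    def test_closed_form_counts_for_many_histories(self, small_histories):
        g = build_graph(small_histories)
        total_steps = sum(h.n_steps for h in small_histories)
        assert g.n_nodes == total_steps + len(small_histories)
        assert len(g.arcs) == total_steps
        assert len(g.initial_nodes) == len(small_histories)

    def test_outcome_label_propagates_to_terminal_node(self):
        h = ClinicalHistory("p", [[1.0, 2.0]], [[0.5]], "death")
        g = build_graph([h])
        terminals = [i for i in range(g.n_nodes) if g.terminal[i]]
        assert len(terminals) == 1
        assert g.outcomes[terminals[0]] == "death"

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            build_graph([])

    def test_ragged_dimensions_rejected(self):
        a = ClinicalHistory("a", [[1.0, 2.0]], [[0.5]], "death")
        b = ClinicalHistory("b", [[1.0, 2.0, 3.0]], [[0.5]], "death")
        with pytest.raises(InputError):
            build_graph([a, b])

    def test_terminal_nodes_have_no_outgoing_arcs(self, small_histories):
        g = build_graph(small_histories)
        for i in range(g.n_nodes):
            if g.terminal[i]:
                assert g.out_arcs(i) == []


class TestMerging:
    @staticmethod
    def chain_graph(states, outcome="discharge"):
        h = ClinicalHistory("p", states, [[0.0]] * len(states), outcome)
        return build_graph([h])

    def test_identical_states_merge_into_one(self):
        a = ClinicalHistory("a", [[1.0, 2.0]], [[0.1]], "discharge")
        b = ClinicalHistory("b", [[1.0, 2.0]], [[0.9]], "death")
        g = merge_similar_states(build_graph([a, b]), c_min=0.99)
        nonterm = [i for i in range(g.n_nodes) if not g.terminal[i]]
        assert len(nonterm) == 1
        assert np.allclose(g.states[nonterm[0]], [1.0, 2.0])
        assert len(g.arcs) == 2  # arc multiset preserved

    def test_orthogonal_states_do_not_merge(self):
        a = ClinicalHistory("a", [[1.0, 0.0]], [[0.0]], "discharge")
        b = ClinicalHistory("b", [[0.0, 1.0]], [[0.0]], "discharge")
        g = merge_similar_states(build_graph([a, b]), c_min=0.5)
        assert sum(not t for t in g.terminal) == 2

    def test_similar_pair_merges_to_arithmetic_mean(self):
        # cos((1,0), (0.8,0.6)) = 0.8 >= 0.75, mean = (0.9, 0.3)
        a = ClinicalHistory("a", [[1.0, 0.0]], [[0.0]], "discharge")
        b = ClinicalHistory("b", [[0.8, 0.6]], [[0.0]], "discharge")
        g = merge_similar_states(build_graph([a, b]), c_min=0.75)
        nonterm = [i for i in range(g.n_nodes) if not g.terminal[i]]
        assert len(nonterm) == 1
        assert np.allclose(g.states[nonterm[0]], [0.9, 0.3])

    def test_node_count_nonincreasing_as_threshold_drops(self, small_histories):
        g = build_graph(small_histories)
        counts = [
            merge_similar_states(g, c_min).n_nodes for c_min in (1.0, 0.999, 0.9, 0.5, 0.0)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_arc_count_invariant_under_merging(self, small_histories):
        g = build_graph(small_histories)
        for c_min in (0.999, 0.5):
            assert len(merge_similar_states(g, c_min).arcs) == len(g.arcs)

    def test_terminal_nodes_never_merge(self, small_histories):
        g = build_graph(small_histories)
        merged = merge_similar_states(g, c_min=-1.0)
        assert sum(merged.terminal) == sum(g.terminal)

    def test_zero_norm_state_raises(self):
        g = self.chain_graph([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(SimilarityUndefinedError):
            merge_similar_states(g, c_min=0.9)

    def test_initial_nodes_follow_merge(self):
        a = ClinicalHistory("a", [[1.0, 2.0], [3.0, 1.0]], [[0.1], [0.2]], "discharge")
        b = ClinicalHistory("b", [[1.0, 2.0]], [[0.9]], "death")
        merged = merge_similar_states(build_graph([a, b]), c_min=0.999)
        assert len(merged.initial_nodes) == 1


class TestTransitionDistribution:
    def test_single_arc_gets_all_mass_regardless_of_action(self):
        g = TransitionGraph(
            states=[np.array([1.0, 0.0]), np.array([0.0, 1.0])],
            terminal=[False, True],
            outcomes=[None, "discharge"],
            arcs=[Arc(0, np.array([5.0]), 1)],
            initial_nodes=[0],
        )
        for a in (np.array([-100.0]), np.array([5.0]), np.array([40.0])):
            assert transition_distribution(g, 0, a) == pytest.approx({1: 1.0})

    def test_equidistant_actions_split_evenly(self):
        g = TransitionGraph(
            states=[np.ones(2), np.zeros(2) + 2, np.zeros(2) + 3],
            terminal=[False, True, True],
            outcomes=[None, "death", "discharge"],
            arcs=[Arc(0, np.array([1.0]), 1), Arc(0, np.array([-1.0]), 2)],
            initial_nodes=[0],
        )
        probs = transition_distribution(g, 0, np.array([0.0]))
        assert probs[1] == pytest.approx(0.5)
        assert probs[2] == pytest.approx(0.5)

    def test_gaussian_kernel_two_arc_values(self):
        # distances 0 and sqrt(2) with sigma = 1: weights 1 and e^-1
        g = TransitionGraph(
            states=[np.ones(2), np.zeros(2) + 2, np.zeros(2) + 3],
            terminal=[False, True, True],
            outcomes=[None, "death", "discharge"],
            arcs=[Arc(0, np.array([0.0, 0.0]), 1), Arc(0, np.array([1.0, 1.0]), 2)],
            initial_nodes=[0],
        )
        probs = transition_distribution(g, 0, np.array([0.0, 0.0]), GraphSimConfig())
        assert probs[1] == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), abs=1e-12)
        assert probs[2] == pytest.approx(math.exp(-1.0) / (1.0 + math.exp(-1.0)), abs=1e-12)

    @pytest.mark.parametrize("literal", [False, True])
    def test_matches_brute_force_oracle_on_random_graphs(self, literal):
        rng = np.random.default_rng(42)
        cfg = GraphSimConfig(literal_eq7_sign=literal, kernel_bandwidth=1.3)
        for _ in range(30):
            g = random_graph(rng)
            for node in range(g.n_nodes):
                if g.terminal[node] or not g.out_arcs(node):
                    continue
                action = rng.normal(size=2)
                got = transition_distribution(g, node, action, cfg)
                want = brute_force_eq7(g, node, action, cfg)
                assert set(got) == set(want)
                for t in got:
                    assert got[t] == pytest.approx(want[t], abs=1e-12)
                assert sum(got.values()) == pytest.approx(1.0, abs=1e-12)

    def test_terminal_node_rejected(self, three_step_history):
        g = build_graph([three_step_history])
        term = next(i for i in range(g.n_nodes) if g.terminal[i])
        with pytest.raises(StateError):
            transition_distribution(g, term, np.array([0.0]))

    def test_action_dimension_mismatch_rejected(self, three_step_history):
        g = build_graph([three_step_history])
        with pytest.raises(ActionError):
            transition_distribution(g, 0, np.array([0.0, 1.0]))


class TestGraphSimEnv:
    def test_single_initial_node_always_starts_there(self, three_step_history):
        env = GraphSim(build_graph([three_step_history]))
        for seed in range(5):
            assert np.allclose(env.reset(seed), three_step_history.states[0])

    def test_two_initial_nodes_sampled_uniformly(self):
        a = ClinicalHistory("a", [[1.0, 0.0]], [[0.0]], "discharge")
        b = ClinicalHistory("b", [[0.0, 1.0]], [[0.0]], "death")
        env = GraphSim(build_graph([a, b]))
        first = sum(np.allclose(env.reset(s), [1.0, 0.0]) for s in range(10_000))
        assert abs(first / 10_000 - 0.5) < 0.02

    def test_observation_dimension_matches_histories(self, merged_graph, ground_truth):
        env = GraphSim(merged_graph)
        assert env.reset(0).shape == (ground_truth.state_dim,)

    def test_deterministic_chain_replays_source_history(self, three_step_history):
        env = GraphSim(build_graph([three_step_history]))
        trace = run_episode(env, lambda o: np.array([1.0]), seed=0)
        assert trace.terminated
        assert len(trace) == 3
        for obs, state in zip(trace.observations[:3], three_step_history.states):
            assert np.allclose(obs, state)
        assert trace.rewards[:-1] == [0.0, 0.0]
        assert trace.rewards[-1] == 1.0  # discharge

    def test_terminal_rewards_reflect_outcome(self, ground_truth):
        histories = generate_histories(ground_truth, n_patients=50, seed=11)
        env = GraphSim.from_histories(histories, GraphSimConfig(c_min=0.999))
        rng = np.random.default_rng(1)
        protos = ground_truth.action_prototypes
        seen = set()
        for ep in range(200):
            env.reset(ep)
            for _ in range(env.spec.horizon):
                res = env.step(protos[rng.integers(len(protos))])
                if res.terminated and "outcome" in res.info:
                    expected = 1.0 if res.info["outcome"] == "discharge" else -1.0
                    assert res.reward == expected
                    seen.add(res.info["outcome"])
                    break
                if res.terminated:
                    break
        assert seen == {"death", "discharge"}

    def test_wrong_action_dimension_rejected(self, merged_graph):
        env = GraphSim(merged_graph)
        env.reset(0)
        with pytest.raises(ActionError):
            env.step(np.zeros(merged_graph.state_dim + 5))

    def test_graph_json_round_trip(self, merged_graph):
        back = TransitionGraph.from_json(merged_graph.to_json())
        assert back.n_nodes == merged_graph.n_nodes
        assert back.initial_nodes == merged_graph.initial_nodes
        assert all(
            np.allclose(a, b) for a, b in zip(back.states, merged_graph.states)
        )
        assert all(
            a.source == b.source and a.target == b.target and np.allclose(a.action, b.action)
            for a, b in zip(back.arcs, merged_graph.arcs)
        )

    def test_to_networkx_preserves_structure(self, merged_graph):
        g = merged_graph.to_networkx()
        assert g.number_of_nodes() == merged_graph.n_nodes
        assert g.number_of_edges() == len(merged_graph.arcs)
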