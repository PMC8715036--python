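import numpy as np
import pytest
from hypothesis import settings

from patientsim import ClinicalHistory, HeartPole, load_default_catalogue
from patientsim.graphsim import build_graph, merge_similar_states
from patientsim.synthetic import generate_histories, sample_ground_truth

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalogue():
    return load_default_catalogue()


@pytest.fixture()
def heartpole():
    return HeartPole()


@pytest.fixture(scope="session")
def ground_truth():
    return sample_ground_truth(seed=0)


@pytest.fixture(scope="session")
def small_histories(ground_truth):
    return generate_histories(ground_truth, n_patients=30, seed=1)


@pytest.fixture(scope="session")
def merged_graph(small_histories):
    return merge_similar_states(build_graph(small_histories), c_min=0.999)


@pytest.fixture()
def three_step_history():
    return ClinicalHistory(
        patient_id="p0",
        states=np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
        actions=np.array([[0.5], [1.5], [2.5]]),
        outcome="discharge",
    )


def random_graph(rng, max_arcs=20):
    """Small random transition graph for oracle comparisons."""

    from patientsim.graphsim import Arc, TransitionGraph

    d, k = 3, 2
    n_nonterm = int(rng.integers(2, 6))
    n_term = int(rng.integers(1, 3))
    n = n_nonterm + n_term
    states = [rng.normal(size=d) + 2.0 for _ in range(n)]
    terminal = [i >= n_nonterm for i in range(n)]
    outcomes = [None] * n_nonterm + [
        ("death" if rng.random() < 0.5 else "discharge") for _ in range(n_term)
    ]
    n_arcs = int(rng.integers(n_nonterm, max_arcs + 1))
    arcs = []
    for src in range(n_nonterm):  # every non-terminal node gets at least one arc
        arcs.append(Arc(src, rng.normal(size=k), int(rng.integers(n))))
    for _ in range(n_arcs - n_nonterm):
        arcs.append(Arc(int(rng.integers(n_nonterm)), rng.normal(size=k), int(rng.integers(n))))
    return TransitionGraph(states, terminal, outcomes, arcs, [0])
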