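"""GraphSim: a patient simulator compressed from logged clinical histories.

Each logged history is a chain in an oriented graph whose nodes are patient
states (vectors of vitals and labs) and whose arcs carry the treatment
action (a drug-dose vector) administered between consecutive states; a
terminal node per patient records the outcome (death or discharge).  States
from different patients that are sufficiently similar — cosine similarity at
least ``c_min`` — are merged into their arithmetic mean, so the disjoint
chains knit into one graph in which several "timelines" leave a shared
state.

The merged graph then serves as an environment: the simulated patient starts
at one of the logged initial states, and when the agent plays action ``a_t``
at node ``s_t`` the next node is drawn from a softmax over the outgoing
arcs, weighted by an action-similarity kernel
``exp(-||a_t - a||^2 / (2 sigma^2))`` — the closer the agent's action is to
a logged doctor action, the likelier that doctor's timeline is followed.
(The printed form of this kernel has a positive exponent, which up-weights
*dissimilar* actions; it is available via ``literal_eq7_sign`` for fidelity
experiments but the Gaussian kernel is the default, being the only reading
under which the choice of timeline tracks the agent's action.)

Rewards are terminal-only: 0 at every interior transition, ``r_death`` or
``r_discharge`` on entering a terminal node.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .core import (
    ActionError,
    ConfigurationError,
    ContinuousActions,
    EnvSpec,
    Environment,
    InputError,
    PatientSimError,
    StepResult,
)
from .histories import ClinicalHistory, _check_consistent

__all__ = [
    "StateError",
    "SimilarityUndefinedError",
    "Arc",
    "TransitionGraph",
    "GraphSimConfig",
    "build_graph",
    "merge_similar_states",
    "transition_distribution",
    "sample_transition",
    "GraphSim",
    "graph_from_histories",
]


class StateError(PatientSimError):
    """Operation on a node that cannot support it (terminal, arc-less, unknown)."""


class SimilarityUndefinedError(PatientSimError):
    """Cosine similarity undefined for a zero-norm state vector."""


@dataclass(frozen=True)
class Arc:
    source: int
    action: np.ndarray
    target: int


@dataclass
class TransitionGraph:
    """Oriented transition graph: state nodes, action-labelled arcs, outcomes.

    ``states[i]`` is node ``i``'s state vector; terminal nodes additionally
    carry the final observed state of their history so the graph remains a
    pure vector container.  Terminal nodes have no outgoing arcs.
    """

    states: list[np.ndarray]
    terminal: list[bool]
    outcomes: list[str | None]  # outcome label for terminal nodes, None otherwise
    arcs: list[Arc]
    initial_nodes: list[int]
    _out: dict[int, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = len(self.states)
        if not (len(self.terminal) == len(self.outcomes) == n):
            raise InputError("states, terminal and outcomes must have equal length")
        if not self.initial_nodes:
            raise ConfigurationError("graph has no initial nodes")
        for arc in self.arcs:
            if not (0 <= arc.source < n and 0 <= arc.target < n):
                raise InputError(f"arc {arc} references a missing node")
            if self.terminal[arc.source]:
                raise InputError(f"terminal node {arc.source} has an outgoing arc")
        self._reindex()

    def _reindex(self) -> None:
        self._out = {}
        for idx, arc in enumerate(self.arcs):
            self._out.setdefault(arc.source, []).append(idx)

    @property
    def n_nodes(self) -> int:
        return len(self.states)

    @property
    def state_dim(self) -> int:
        return len(self.states[0])

    def out_arcs(self, node: int) -> list[Arc]:
        return [self.arcs[i] for i in self._out.get(node, [])]

    def to_json(self) -> str:
        return json.dumps(
            {
                "states": [s.tolist() for s in self.states],
                "terminal": self.terminal,
                "outcomes": self.outcomes,
                "arcs": [
                    {"source": a.source, "action": a.action.tolist(), "target": a.target}
                    for a in self.arcs
                ],
                "initial_nodes": self.initial_nodes,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TransitionGraph":
        d = json.loads(text)
        return cls(
            states=[np.asarray(s, dtype=float) for s in d["states"]],
            terminal=list(d["terminal"]),
            outcomes=list(d["outcomes"]),
            arcs=[
                Arc(int(a["source"]), np.asarray(a["action"], dtype=float), int(a["target"]))
                for a in d["arcs"]
            ],
            initial_nodes=[int(i) for i in d["initial_nodes"]],
        )

    def to_networkx(self):
        """Export as a ``networkx.MultiDiGraph`` (node attrs: state, terminal, outcome)."""

        import networkx as nx

        g = nx.MultiDiGraph()
        for i, s in enumerate(self.states):
            g.add_node(i, state=s, terminal=self.terminal[i], outcome=self.outcomes[i])
        for a in self.arcs:
            g.add_edge(a.source, a.target, action=a.action)
        return g


@dataclass(frozen=True)
class GraphSimConfig:
    """GraphSim knobs.

    ``c_min`` — cosine-similarity threshold at or above which states merge.
    ``kernel_bandwidth`` — sigma of the Gaussian action kernel, in action
    units.  ``literal_eq7_sign`` — use the printed positive exponent instead
    of the Gaussian kernel.  ``standardize`` — compute similarities on
    per-feature standardized vectors (useful when state features mix units;
    off by default so that identical raw states are always mergeable and
    distinct noiseless states never spuriously align).
    """

    c_min: float = 0.97
    kernel_bandwidth: float = 1.0
    literal_eq7_sign: bool = False
    r_death: float = -1.0
    r_discharge: float = 1.0
    standardize: bool = False
    horizon: int = 200

    def __post_init__(self) -> None:
        if not (-1.0 <= self.c_min <= 1.0):
            raise ConfigurationError(f"c_min must lie in [-1, 1], got {self.c_min}")
        if self.kernel_bandwidth <= 0:
            raise ConfigurationError("kernel_bandwidth must be > 0")


def build_graph(histories: Sequence[ClinicalHistory]) -> TransitionGraph:
    """Assemble the unmerged transition graph from logged histories.

    One node per (patient, step) state plus one outcome-labelled terminal
    node per history (carrying the final observed state); one arc per
    consecutive step pair and one from each last state to its terminal node.
    A history with T steps contributes T + 1 nodes and T arcs.
    """

    _check_consistent(histories)
    states: list[np.ndarray] = []
    terminal: list[bool] = []
    outcomes: list[str | None] = []
    arcs: list[Arc] = []
    initial: list[int] = []
    for h in histories:
        first = len(states)
        initial.append(first)
        for t in range(h.n_steps):
            states.append(h.states[t].copy())
            terminal.append(False)
            outcomes.append(None)
        term_id = len(states)
        states.append(h.states[-1].copy())
        terminal.append(True)
        outcomes.append(h.outcome)
        for t in range(h.n_steps):
            target = first + t + 1 if t < h.n_steps - 1 else term_id
            arcs.append(Arc(first + t, h.actions[t].copy(), target))
    return TransitionGraph(states, terminal, outcomes, arcs, initial)


def _similarity_space(graph: TransitionGraph, standardize: bool) -> np.ndarray:
    x = np.stack(graph.states)
    if standardize:
        nonterm = ~np.asarray(graph.terminal)
        mu = x[nonterm].mean(axis=0)
        sd = x[nonterm].std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    return x


def merge_similar_states(
    graph: TransitionGraph, c_min: float, standardize: bool = False
) -> TransitionGraph:
    """Greedy agglomerative merging of similar non-terminal states.

    Repeatedly merges the most cosine-similar eligible pair with similarity
    >= ``c_min`` into the arithmetic mean ``(s_A + s_B) / 2``, redirecting
    all arcs and recomputing similarities, until no eligible pair remains.
    Ties break towards the lowest node ids.  Terminal nodes never merge; the
    arc multiset is preserved (only endpoints are relabelled).

    Exactly identical non-terminal states are collapsed in a first pass —
    the greedy order would take those cosine-1 pairs first anyway — which
    keeps merging tractable on histories with many repeated states.
    """

    if not (-1.0 <= c_min <= 1.0):
        raise ConfigurationError(f"c_min must lie in [-1, 1], got {c_min}")
    n = graph.n_nodes
    sim_space = _similarity_space(graph, standardize)
    nonterm = [i for i in range(n) if not graph.terminal[i]]
    for i in nonterm:
        if np.linalg.norm(sim_space[i]) == 0:
            raise SimilarityUndefinedError(
                f"node {i} has a zero-norm state vector; cosine similarity undefined"
            )

    # Union-style bookkeeping: remap[i] -> representative id; vectors mutate.
    raw = {i: graph.states[i].astype(float).copy() for i in nonterm}
    sim = {i: sim_space[i].astype(float).copy() for i in nonterm}
    remap = {i: i for i in range(n)}
    active = set(nonterm)

    # Pass 1: collapse exact duplicates (same raw bytes => same similarity vector).
    by_key: dict[bytes, int] = {}
    for i in sorted(active):
        key = raw[i].tobytes()
        rep = by_key.setdefault(key, i)
        if rep != i:
            remap[i] = rep
            active.discard(i)

    def cosine(u: np.ndarray, v: np.ndarray) -> float:
        return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))

    # Pass 2: greedy most-similar-first with an incrementally updated heap.
    version = {i: 0 for i in active}
    heap: list[tuple[float, int, int, int, int]] = []
    order = sorted(active)
    if order:
        mat = np.stack([sim[i] for i in order])
        norms = np.linalg.norm(mat, axis=1)
        cos = (mat @ mat.T) / np.outer(norms, norms)
        for p in range(len(order)):
            for q in range(p + 1, len(order)):
                if cos[p, q] >= c_min:
                    i, j = order[p], order[q]
                    heapq.heappush(heap, (-cos[p, q], i, j, 0, 0))

    while heap:
        negsim, i, j, vi, vj = heapq.heappop(heap)
        if i not in active or j not in active or version[i] != vi or version[j] != vj:
            continue
        # Merge j into i (i < j by construction): mean in both spaces.
        raw[i] = (raw[i] + raw[j]) / 2.0
        sim[i] = (sim[i] + sim[j]) / 2.0
        if np.linalg.norm(sim[i]) == 0:
            raise SimilarityUndefinedError(
                f"merge of nodes {i} and {j} produced a zero-norm state"
            )
        remap[j] = i
        active.discard(j)
        version[i] += 1
        for k in sorted(active):
            if k == i:
                continue
            c = cosine(sim[i], sim[k])
            if c >= c_min:
                a, b = (i, k) if i < k else (k, i)
                heapq.heappush(heap, (-c, a, b, version[a], version[b]))

    def resolve(i: int) -> int:
        while remap[i] != i:
            remap[i] = remap[remap[i]]
            i = remap[i]
        return i

    kept = [i for i in range(n) if resolve(i) == i]
    new_id = {old: new for new, old in enumerate(kept)}
    states = [raw[i] if i in raw and not graph.terminal[i] else graph.states[i].copy() for i in kept]
    terminal = [graph.terminal[i] for i in kept]
    outcomes = [graph.outcomes[i] for i in kept]
    arcs = [
        Arc(new_id[resolve(a.source)], a.action.copy(), new_id[resolve(a.target)])
        for a in graph.arcs
    ]
    initial = sorted({new_id[resolve(i)] for i in graph.initial_nodes})
    return TransitionGraph(states, terminal, outcomes, arcs, initial)


def _log_weights(
    actions: np.ndarray, a_t: np.ndarray, config: GraphSimConfig
) -> np.ndarray:
    d2 = np.sum((actions - a_t[None, :]) ** 2, axis=1)
    if config.literal_eq7_sign:
        return d2 / 2.0
    return -d2 / (2.0 * config.kernel_bandwidth**2)


def transition_distribution(
    graph: TransitionGraph,
    node: int,
    action: np.ndarray,
    config: GraphSimConfig | None = None,
) -> dict[int, float]:
    """Next-node distribution at ``node`` under action ``action``.

    Each outgoing arc is weighted by the action kernel; the probability of a
    successor is the normalised sum of the weights of the arcs that land on
    it.  Probabilities sum to one.
    """

    config = config or GraphSimConfig()
    if not (0 <= node < graph.n_nodes):
        raise StateError(f"node {node} not in graph")
    if graph.terminal[node]:
        raise StateError(f"node {node} is terminal")
    out = graph.out_arcs(node)
    if not out:
        raise StateError(f"node {node} has no outgoing arcs")
    a_t = np.asarray(action, dtype=float)
    acts = np.stack([a.action for a in out])
    if a_t.shape != (acts.shape[1],):
        raise ActionError(f"action shape {a_t.shape} != ({acts.shape[1]},)")
    logw = _log_weights(acts, a_t, config)
    w = np.exp(logw - logw.max())  # stable under either exponent sign
    w /= w.sum()
    probs: dict[int, float] = {}
    for arc, wi in zip(out, w):
        probs[arc.target] = probs.get(arc.target, 0.0) + float(wi)
    return probs


def sample_transition(
    graph: TransitionGraph,
    node: int,
    action: np.ndarray,
    config: GraphSimConfig,
    rng: np.random.Generator,
) -> int:
    probs = transition_distribution(graph, node, action, config)
    targets = sorted(probs)
    p = np.array([probs[t] for t in targets])
    return int(targets[rng.choice(len(targets), p=p / p.sum())])


class GraphSim(Environment):
    """The merged transition graph served as an episodic POMDP.

    Observation = current node's state vector; actions are continuous dose
    vectors; rewards are terminal-only (``r_death`` / ``r_discharge``).
    Episodes start at a uniformly drawn logged initial state and end on
    reaching a terminal node or the configured horizon.
    """

    def __init__(self, graph: TransitionGraph, config: GraphSimConfig | None = None) -> None:
        super().__init__()
        self.graph = graph
        self.config = config or GraphSimConfig()
        k = graph.arcs[0].action.shape[0] if graph.arcs else 1
        self._spec = EnvSpec(
            observation_dim=graph.state_dim,
            observation_bounds=tuple((-np.inf, np.inf) for _ in range(graph.state_dim)),
            action_space=ContinuousActions(k),
            reward_support="terminal_only",
            horizon=self.config.horizon,
        )
        self._node = -1
        self._steps = 0

    @classmethod
    def from_histories(
        cls, histories: Sequence[ClinicalHistory], config: GraphSimConfig | None = None
    ) -> "GraphSim":
        config = config or GraphSimConfig()
        graph = merge_similar_states(build_graph(histories), config.c_min, config.standardize)
        return cls(graph, config)

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any]) -> "GraphSim":
        """Build from a plain config map: ``histories`` CSV path plus knob keys."""

        from .histories import read_histories

        cfg = dict(cfg)
        path = cfg.pop("histories", None)
        if path is None:
            raise ConfigurationError("config needs a 'histories' CSV path")
        return cls.from_histories(read_histories(path), GraphSimConfig(**cfg))

    @property
    def spec(self) -> EnvSpec:
        return self._spec

    @property
    def current_node(self) -> int:
        return self._node

    def candidate_actions(self, max_actions: int = 32) -> list[np.ndarray]:
        """Distinct logged arc actions — a natural discrete action set for baselines."""

        seen: dict[bytes, np.ndarray] = {}
        for arc in self.graph.arcs:
            seen.setdefault(arc.action.tobytes(), arc.action)
            if len(seen) >= max_actions:
                break
        return list(seen.values())

    def _reset_state(self, rng: np.random.Generator) -> np.ndarray:
        self._node = int(self.graph.initial_nodes[rng.integers(len(self.graph.initial_nodes))])
        self._steps = 0
        return self.graph.states[self._node]

    def _step(self, action: np.ndarray, rng: np.random.Generator) -> StepResult:
        nxt = sample_transition(self.graph, self._node, np.asarray(action, float), self.config, rng)
        self._node = nxt
        self._steps += 1
        info: dict[str, Any] = {"node": nxt}
        if self.graph.terminal[nxt]:
            outcome = self.graph.outcomes[nxt]
            reward = self.config.r_death if outcome == "death" else self.config.r_discharge
            info["outcome"] = outcome
            return StepResult(self.graph.states[nxt], float(reward), True, info)
        truncated = self._steps >= self.config.horizon
        return StepResult(self.graph.states[nxt], 0.0, truncated, info)


def graph_from_histories(
    histories: Sequence[ClinicalHistory], config: GraphSimConfig | None = None
) -> TransitionGraph:
    """Convenience: build + merge in one call using the config's threshold."""

    config = config or GraphSimConfig()
    return merge_similar_states(build_graph(histories), config.c_min, config.standardize)
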