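"""Simulator-effectiveness machinery: accuracy, difficulty, reward shaping.

Two complementary effectiveness criteria for patient simulators:

* **Accuracy** — how well the simulator's transition model predicts real
  held-out trajectories, measured as the mean Euclidean error between the
  simulator's expected next state and the observed next state over all
  held-out dynamic transitions.

* **Difficulty** — how hard the simulator is for standard learning
  algorithms, probed by comparing a uniform-random policy against a tabular
  Q-learning baseline (quantile-discretized observations) trained for a
  fixed step budget and then frozen.

Also provided is the SOFA-score shaping reward used by sepsis simulators to
densify terminal-only outcomes: a penalty for a persistently positive SOFA
score, a term proportional to the SOFA change, and a saturating (tanh) term
in the lactate change.  Its three coefficients are deliberately required
configuration — no published constants exist to default to.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np

from .core import (
    ContinuousActions,
    DiscreteActions,
    Environment,
    InputError,
    Policy,
    run_episode,
)
from .graphsim import TransitionGraph, GraphSimConfig, transition_distribution
from .histories import ClinicalHistory

__all__ = [
    "ShapingConfig",
    "sofa_shaping_reward",
    "PredictiveErrorResult",
    "mean_predictive_error",
    "TabularQConfig",
    "TabularQAgent",
    "AgentResult",
    "DifficultyReport",
    "difficulty_probe",
]


@dataclass(frozen=True)
class ShapingConfig:
    """Coefficients of the SOFA shaping reward; all required, all finite."""

    C0: float
    C1: float
    C2: float

    def __post_init__(self) -> None:
        for name in ("C0", "C1", "C2"):
            if not math.isfinite(getattr(self, name)):
                raise InputError(f"{name} must be finite")


def sofa_shaping_reward(
    state_t: Mapping[str, float], state_t1: Mapping[str, float], config: ShapingConfig
) -> float:
    """Shaping reward from consecutive SOFA scores and lactate levels.

    ``C0 * 1[SOFA unchanged and > 0] + C1 * (SOFA_{t+1} - SOFA_t)
    + C2 * tanh(Lactate_{t+1} - Lactate_t)``.
    """

    try:
        sofa_t, sofa_t1 = float(state_t["SOFA"]), float(state_t1["SOFA"])
        lact_t, lact_t1 = float(state_t["Lactate"]), float(state_t1["Lactate"])
    except KeyError as exc:
        raise InputError(f"state missing field {exc.args[0]!r}") from None
    for v in (sofa_t, sofa_t1, lact_t, lact_t1):
        if not math.isfinite(v):
            raise InputError("SOFA and Lactate values must be finite")
    unchanged_positive = 1.0 if (sofa_t1 == sofa_t and sofa_t1 > 0) else 0.0
    return (
        config.C0 * unchanged_positive
        + config.C1 * (sofa_t1 - sofa_t)
        + config.C2 * math.tanh(lact_t1 - lact_t)
    )


# ---------------------------------------------------------------------------
# Accuracy


@dataclass
class PredictiveErrorResult:
    """Root-mean-square Euclidean next-state prediction error and coverage counts."""

    rms_error: float
    n_transitions: int
    n_unmatched: int

    def __float__(self) -> float:
        return self.rms_error


def mean_predictive_error(
    graph: TransitionGraph,
    held_out: Sequence[ClinicalHistory],
    config: GraphSimConfig | None = None,
    n_samples: int | None = None,
    seed: int = 0,
    min_similarity: float = 0.0,
) -> PredictiveErrorResult:
    """Mean predictive error of a transition graph over held-out transitions.

    For each held-out transition ``(s_t, a_t, s_{t+1})`` the current state is
    matched to the most cosine-similar non-terminal graph node; the point
    prediction is the probability-weighted mean of the next-state
    distribution under ``a_t``, and the per-transition error is its squared
    Euclidean distance to the observed ``s_{t+1}``.  The reported error is
    the root mean of those squares — the loss under which the expectation is
    the optimal point prediction, so the metric improves consistently as the
    graph is built from more data.
    Held-out transitions are *dynamic* (state-to-state), so probability mass
    on terminal successors — which carry an outcome, not a next state — is
    excluded and the distribution renormalised over non-terminal successors.
    Transitions whose best match falls below ``min_similarity`` (or whose
    state has zero norm, or whose matched node leads only to terminal
    nodes) are counted as unmatched and excluded from the mean.
    ``n_samples`` subsamples the held-out transitions (seeded).
    """

    if not held_out:
        raise InputError("held_out must be non-empty")
    config = config or GraphSimConfig()
    transitions: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for h in held_out:
        for t in range(h.n_steps - 1):
            transitions.append((h.states[t], h.actions[t], h.states[t + 1]))
    if not transitions:
        raise InputError("held_out histories contain no dynamic transitions")
    if n_samples is not None and n_samples < len(transitions):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(transitions), size=n_samples, replace=False)
        transitions = [transitions[i] for i in sorted(idx)]

    nonterm = [i for i in range(graph.n_nodes) if not graph.terminal[i] and graph.out_arcs(i)]
    node_states = np.stack([graph.states[i] for i in nonterm])
    node_norms = np.linalg.norm(node_states, axis=1)
    node_norms[node_norms == 0] = np.inf  # zero-norm nodes can never be the match

    # Vectorized nearest-node matching over all held-out transitions at once.
    s_mat = np.stack([t[0] for t in transitions])
    s_norms = np.linalg.norm(s_mat, axis=1)
    safe_norms = np.where(s_norms == 0, np.inf, s_norms)
    sims = (s_mat @ node_states.T) / (safe_norms[:, None] * node_norms[None, :])
    best_idx = np.argmax(sims, axis=1)
    best_sim = sims[np.arange(len(transitions)), best_idx]

    # Point predictions repeat whenever (matched node, action) repeats.
    expectation_cache: dict[tuple[int, bytes], np.ndarray | None] = {}

    def expected_next(node: int, a_t: np.ndarray) -> np.ndarray | None:
        key = (node, a_t.tobytes())
        if key not in expectation_cache:
            probs = transition_distribution(graph, node, a_t, config)
            dyn_mass = sum(p for t, p in probs.items() if not graph.terminal[t])
            if dyn_mass == 0:
                expectation_cache[key] = None
            else:
                expected = np.zeros(graph.state_dim)
                for target, p in probs.items():
                    if not graph.terminal[target]:
                        expected += (p / dyn_mass) * graph.states[target]
                expectation_cache[key] = expected
        return expectation_cache[key]

    errors: list[float] = []
    unmatched = 0
    for i, (s_t, a_t, s_t1) in enumerate(transitions):
        if s_norms[i] == 0 or best_sim[i] < min_similarity:
            unmatched += 1
            continue
        expected = expected_next(nonterm[int(best_idx[i])], np.asarray(a_t, dtype=float))
        if expected is None:
            unmatched += 1
            continue
        errors.append(float(np.sum((expected - s_t1) ** 2)))
    rms = float(np.sqrt(np.mean(errors))) if errors else float("nan")
    return PredictiveErrorResult(rms, len(errors), unmatched)


# ---------------------------------------------------------------------------
# Difficulty


@dataclass(frozen=True)
class TabularQConfig:
    """Baseline Q-learning knobs: step budget, observation grid, schedule."""

    training_steps: int = 50_000
    n_bins: int = 8
    bin_fit_samples: int = 1_000
    learning_rate: float = 0.2
    discount: float = 0.99
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05


class TabularQAgent:
    """Tabular Q-learning over a per-dimension quantile discretization.

    Bin edges are fitted from random-policy observations; unseen states
    default to zero Q-values with ties broken towards the lowest action
    index.  Continuous-action environments are handled through a finite
    candidate-action set (the environment's ``candidate_actions()`` if it
    provides one).
    """

    def __init__(
        self,
        env: Environment,
        config: TabularQConfig | None = None,
        candidate_actions: Sequence[Any] | None = None,
    ) -> None:
        self.env = env
        self.config = config or TabularQConfig()
        space = env.spec.action_space
        if isinstance(space, DiscreteActions):
            self._actions: list[Any] = list(range(space.n))
        else:
            if candidate_actions is None and hasattr(env, "candidate_actions"):
                candidate_actions = env.candidate_actions()
            if not candidate_actions:
                raise InputError(
                    "continuous-action environment needs a candidate_actions set"
                )
            self._actions = list(candidate_actions)
        self.q: dict[tuple[int, ...], np.ndarray] = defaultdict(
            lambda: np.zeros(len(self._actions))
        )
        self._edges: np.ndarray | None = None

    def _fit_bins(self, seed: int) -> None:
        cfg = self.config
        rng = np.random.default_rng(seed)
        obs_list: list[np.ndarray] = []
        ep = 0
        while len(obs_list) < cfg.bin_fit_samples:
            obs = self.env.reset(seed + ep)
            obs_list.append(obs)
            for _ in range(self.env.spec.horizon):
                a = self._actions[rng.integers(len(self._actions))]
                res = self.env.step(a)
                obs_list.append(res.observation)
                if res.terminated or len(obs_list) >= cfg.bin_fit_samples:
                    break
            ep += 1
        data = np.stack(obs_list)
        qs = np.linspace(0, 1, cfg.n_bins + 1)[1:-1]
        self._edges = np.quantile(data, qs, axis=0)  # (n_bins-1, dim)

    def _discretize(self, obs: np.ndarray) -> tuple[int, ...]:
        assert self._edges is not None
        return tuple(
            int(np.searchsorted(self._edges[:, j], obs[j], side="right"))
            for j in range(len(obs))
        )

    def train(self, seed: int = 0) -> None:
        cfg = self.config
        self._fit_bins(seed)
        rng = np.random.default_rng(seed + 1)
        steps = 0
        ep = 0
        n_a = len(self._actions)
        while steps < cfg.training_steps:
            obs = self.env.reset(seed + 10_000 + ep)
            s = self._discretize(obs)
            for _ in range(self.env.spec.horizon):
                frac = steps / max(1, cfg.training_steps)
                eps = cfg.epsilon_start + frac * (cfg.epsilon_end - cfg.epsilon_start)
                if rng.random() < eps:
                    ai = int(rng.integers(n_a))
                else:
                    ai = int(np.argmax(self.q[s]))
                res = self.env.step(self._actions[ai])
                s2 = self._discretize(res.observation)
                target = res.reward
                if not res.terminated:
                    target += cfg.discount * float(np.max(self.q[s2]))
                self.q[s][ai] += cfg.learning_rate * (target - self.q[s][ai])
                s = s2
                steps += 1
                if res.terminated or steps >= cfg.training_steps:
                    break
            ep += 1

    def policy(self) -> Policy:
        """Frozen greedy policy (requires :meth:`train` first)."""

        if self._edges is None:
            raise InputError("agent not trained")

        def act(obs: np.ndarray) -> Any:
            s = self._discretize(obs)
            return self._actions[int(np.argmax(self.q[s]))]

        return act


@dataclass
class AgentResult:
    mean_return: float
    std_error: float
    note: str = ""


@dataclass
class DifficultyReport:
    """Per-agent mean return ± standard error over a common episode budget."""

    agents: dict[str, AgentResult]
    n_episodes: int
    seeds: tuple[int, int] = (0, 0)  # (first eval seed, training seed)

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_episodes": self.n_episodes,
            "seeds": list(self.seeds),
            "agents": {
                k: {"mean_return": v.mean_return, "std_error": v.std_error, "note": v.note}
                for k, v in self.agents.items()
            },
        }


def _evaluate(
    env: Environment, policy: Policy, n_episodes: int, seed: int
) -> AgentResult:
    returns = []
    note = ""
    for ep in range(n_episodes):
        trace = run_episode(env, policy, seed=seed + ep)
        r = trace.total_return
        if not math.isfinite(r):
            note = f"non-finite return in episode {ep}"
            continue
        returns.append(r)
    arr = np.asarray(returns)
    mean = float(arr.mean()) if arr.size else float("nan")
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return AgentResult(mean, se, note)


def difficulty_probe(
    env: Environment,
    n_episodes: int = 200,
    seed: int = 0,
    q_config: TabularQConfig | None = None,
    user_policy: Policy | None = None,
) -> DifficultyReport:
    """Probe an environment's difficulty with baseline agents.

    Evaluates (a) a uniform-random policy, (b) the tabular Q-learning
    baseline trained for its configured budget and frozen, and optionally
    (c) a user-supplied policy, each over ``n_episodes`` seeded episodes.
    A simulator that a tabular baseline already solves is an easy benchmark;
    one where the baseline cannot beat the random policy is a hard one.
    """

    if n_episodes < 2:
        raise InputError("n_episodes must be >= 2")
    space = env.spec.action_space
    agents: dict[str, AgentResult] = {}

    if isinstance(space, DiscreteActions):
        act_set: list[Any] = list(range(space.n))
    elif hasattr(env, "candidate_actions"):
        act_set = list(env.candidate_actions())
    else:
        act_set = []

    if act_set:
        def make_random_policy(rng_seed: int) -> Policy:
            rng = np.random.default_rng(rng_seed)
            return lambda _obs: act_set[int(rng.integers(len(act_set)))]

        agents["random"] = _evaluate(env, make_random_policy(seed), n_episodes, seed)
        agent = TabularQAgent(env, q_config, candidate_actions=act_set)
        agent.train(seed=seed + 100_000)
        agents["tabular_q"] = _evaluate(env, agent.policy(), n_episodes, seed)
    else:
        rng = np.random.default_rng(seed)
        if isinstance(space, ContinuousActions):
            low = space.low if math.isfinite(space.low) else -1.0
            high = space.high if math.isfinite(space.high) else 1.0
            rand: Policy = lambda _obs: rng.uniform(low, high, size=space.dim)
            agents["random"] = _evaluate(env, rand, n_episodes, seed)
        agents["tabular_q"] = AgentResult(
            float("nan"), 0.0, "skipped: no finite candidate action set"
        )

    if user_policy is not None:
        agents["user"] = _evaluate(env, user_policy, n_episodes, seed)
    return DifficultyReport(agents, n_episodes, (seed, seed + 100_000))
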