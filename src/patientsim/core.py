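"""Episodic partially observable MDP contract shared by every simulator in the suite.

A patient simulator is modelled as the tuple
``(S_nt, S_t, A, O, p_o, p_s, p_r, p_init)``: non-terminal and terminal
patient states, actions, observations, and the observation / transition /
reward / initial-state distributions.  Terminal states (death, discharge,
heart attack, end of episode) end the episode.  Every environment in this
package implements the :class:`Environment` interface below: ``reset(seed)``
samples ``p_init`` and returns the first observation, ``step(action)``
samples ``p_s``, ``p_o`` and ``p_r`` and returns a :class:`StepResult`.

The random number generator is owned by the environment and seeded at
``reset``; one seed therefore fully determines an episode given the action
sequence.  Rewards are undiscounted; discounting is an agent concern.
"""

from __future__ import annotations

import json
import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "PatientSimError",
    "ConfigurationError",
    "ActionError",
    "LifecycleError",
    "InputError",
    "DiscreteActions",
    "ContinuousActions",
    "EnvSpec",
    "StepResult",
    "EpisodeTrace",
    "Environment",
    "run_episode",
    "validate_env",
]


class PatientSimError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PatientSimError):
    """Environment or component configured inconsistently or not at all."""


class ActionError(PatientSimError):
    """Action outside the environment's action space."""


class LifecycleError(PatientSimError):
    """Operation invalid in the episode's current phase (e.g. step after termination)."""


class InputError(PatientSimError):
    """Malformed user-supplied data."""


@dataclass(frozen=True)
class DiscreteActions:
    """A finite action set ``{0, ..., n - 1}``."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"discrete action count must be >= 1, got {self.n}")

    def contains(self, action: Any) -> bool:
        return (
            isinstance(action, (int, np.integer))
            and not isinstance(action, bool)
            and 0 <= int(action) < self.n
        )


@dataclass(frozen=True)
class ContinuousActions:
    """A box of real action vectors of fixed dimension."""

    dim: int
    low: float = -math.inf
    high: float = math.inf

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ConfigurationError(f"continuous action dimension must be >= 1, got {self.dim}")

    def contains(self, action: Any) -> bool:
        arr = np.asarray(action, dtype=float)
        if arr.shape != (self.dim,):
            return False
        return bool(np.all(np.isfinite(arr)) and np.all(arr >= self.low) and np.all(arr <= self.high))


@dataclass(frozen=True)
class EnvSpec:
    """Static description of an environment's interface.

    ``reward_support`` distinguishes simulators that shape rewards during the
    episode (``"all_states"``) from those that only reward the terminal
    outcome (``"terminal_only"``) — the latter are harder benchmarks because
    credit assignment must span the whole episode.
    """

    observation_dim: int
    observation_bounds: tuple[tuple[float, float], ...]
    action_space: DiscreteActions | ContinuousActions
    reward_support: str  # "terminal_only" | "all_states"
    horizon: int

    def __post_init__(self) -> None:
        if self.observation_dim < 1:
            raise ConfigurationError("observation_dim must be positive")
        if len(self.observation_bounds) != self.observation_dim:
            raise ConfigurationError(
                f"observation_bounds has {len(self.observation_bounds)} entries "
                f"for observation_dim {self.observation_dim}"
            )
        for low, high in self.observation_bounds:
            if low > high:
                raise ConfigurationError(f"bound pair ({low}, {high}) is inverted")
        if self.reward_support not in ("terminal_only", "all_states"):
            raise ConfigurationError(f"unknown reward_support {self.reward_support!r}")
        if self.horizon < 1:
            raise ConfigurationError("horizon must be >= 1")


@dataclass
class StepResult:
    """Outcome of one environment step."""

    observation: np.ndarray
    reward: float
    terminated: bool
    info: dict[str, Any] = field(default_factory=dict)


@dataclass
class EpisodeTrace:
    """Ordered record of one episode: observations, actions, rewards.

    Contains one more observation than actions/rewards (the initial one);
    ``total_return`` is the undiscounted reward sum.
    """

    observations: list[np.ndarray]
    actions: list[Any]
    rewards: list[float]
    terminated: bool

    @property
    def total_return(self) -> float:
        return float(sum(self.rewards))

    def __len__(self) -> int:
        return len(self.actions)

    def to_json(self) -> str:
        def _tolist(x: Any) -> Any:
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.integer,)):
                return int(x)
            if isinstance(x, (np.floating,)):
                return float(x)
            return x

        return json.dumps(
            {
                "observations": [_tolist(o) for o in self.observations],
                "actions": [_tolist(a) for a in self.actions],
                "rewards": [float(r) for r in self.rewards],
                "terminated": self.terminated,
                "total_return": self.total_return,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EpisodeTrace":
        d = json.loads(text)
        return cls(
            observations=[np.asarray(o, dtype=float) for o in d["observations"]],
            actions=d["actions"],
            rewards=[float(r) for r in d["rewards"]],
            terminated=bool(d["terminated"]),
        )


class Environment(ABC):
    """Abstract episodic POMDP environment.

    Subclasses implement :meth:`_reset_state` and :meth:`_step` and expose a
    :class:`EnvSpec` via :attr:`spec`.  Lifecycle (seeding, termination
    bookkeeping, action validation) is handled here so that every simulator
    honours the same contract.
    """

    def __init__(self) -> None:
        self._rng: np.random.Generator | None = None
        self._terminated = True  # require a reset before the first step
        self._needs_reset = True

    @property
    @abstractmethod
    def spec(self) -> EnvSpec:
        ...

    @abstractmethod
    def _reset_state(self, rng: np.random.Generator) -> np.ndarray:
        """Sample the initial state and return the initial observation."""

    @abstractmethod
    def _step(self, action: Any, rng: np.random.Generator) -> StepResult:
        """Advance one step; action has already been validated."""

    @property
    def rng(self) -> np.random.Generator:
        if self._rng is None:
            raise LifecycleError("environment used before reset()")
        return self._rng

    def reset(self, seed: int = 0) -> np.ndarray:
        if seed is None or int(seed) < 0:
            raise ConfigurationError(f"seed must be a non-negative integer, got {seed!r}")
        self._rng = np.random.default_rng(int(seed))
        self._terminated = False
        self._needs_reset = False
        obs = self._reset_state(self._rng)
        return np.asarray(obs, dtype=float)

    def step(self, action: Any) -> StepResult:
        if self._needs_reset:
            raise LifecycleError("step() called before reset()")
        if self._terminated:
            raise LifecycleError("step() called after termination; call reset()")
        if not self.spec.action_space.contains(action):
            raise ActionError(f"action {action!r} outside {self.spec.action_space}")
        result = self._step(action, self.rng)
        result.observation = np.asarray(result.observation, dtype=float)
        if result.terminated:
            self._terminated = True
        return result


Policy = Callable[[np.ndarray], Any]


def run_episode(
    env: Environment,
    policy: Policy,
    seed: int = 0,
    max_steps: int | None = None,
) -> EpisodeTrace:
    """Roll out ``policy`` in ``env`` and record the full trace.

    Stops at termination or after ``max_steps`` actions, whichever comes
    first (``max_steps=None`` uses the environment horizon).  The trace
    always holds one more observation than actions.
    """

    if max_steps is None:
        max_steps = env.spec.horizon
    if max_steps < 0:
        raise InputError("max_steps must be >= 0")
    obs = env.reset(seed)
    observations = [obs]
    actions: list[Any] = []
    rewards: list[float] = []
    terminated = False
    for _ in range(max_steps):
        action = policy(obs)
        result = env.step(action)
        actions.append(action)
        rewards.append(float(result.reward))
        observations.append(result.observation)
        obs = result.observation
        if result.terminated:
            terminated = True
            break
    return EpisodeTrace(observations, actions, rewards, terminated)


def _random_action(space: DiscreteActions | ContinuousActions, rng: np.random.Generator) -> Any:
    if isinstance(space, DiscreteActions):
        return int(rng.integers(space.n))
    low = space.low if math.isfinite(space.low) else -1.0
    high = space.high if math.isfinite(space.high) else 1.0
    return rng.uniform(low, high, size=space.dim)


def random_policy(env: Environment, rng: np.random.Generator) -> Policy:
    """Uniform-random policy over the environment's action space."""

    space = env.spec.action_space
    return lambda _obs: _random_action(space, rng)


def validate_env(env: Environment, n_episodes: int = 5, seed: int = 0) -> list[str]:
    """Run seeded random rollouts and report contract violations.

    Returns a list of human-readable violation descriptions — empty for a
    conforming environment.  Violations are report entries, never raised.
    """

    report: list[str] = []
    spec = env.spec

    def check_obs(obs: np.ndarray, where: str) -> None:
        if obs.shape != (spec.observation_dim,):
            report.append(f"{where}: observation shape {obs.shape} != ({spec.observation_dim},)")
            return
        for i, ((low, high), v) in enumerate(zip(spec.observation_bounds, obs)):
            if not (low <= v <= high) and not math.isnan(v):
                report.append(f"{where}: observation[{i}] = {v} outside [{low}, {high}]")
            if math.isnan(v):
                report.append(f"{where}: observation[{i}] is NaN")

    for ep in range(n_episodes):
        ep_seed = seed + ep
        try:
            obs = env.reset(ep_seed)
        except PatientSimError as exc:
            report.append(f"reset(seed={ep_seed}) raised {exc!r}")
            continue
        check_obs(obs, f"reset(seed={ep_seed})")
        action_rng = np.random.default_rng(ep_seed)
        for t in range(spec.horizon):
            action = _random_action(spec.action_space, action_rng)
            try:
                result = env.step(action)
            except PatientSimError as exc:
                report.append(f"episode {ep} step {t}: raised {exc!r}")
                break
            check_obs(result.observation, f"episode {ep} step {t}")
            if not math.isfinite(result.reward):
                report.append(f"episode {ep} step {t}: non-finite reward {result.reward}")
            if (
                spec.reward_support == "terminal_only"
                and not result.terminated
                and result.reward != 0.0
            ):
                report.append(
                    f"episode {ep} step {t}: non-zero reward {result.reward} in "
                    "non-terminal state of a terminal_only environment"
                )
            if result.terminated:
                break
        else:
            report.append(f"episode {ep}: did not terminate within horizon {spec.horizon}")
    return report


def load_config(path: str) -> dict[str, Any]:
    """Load a plain YAML mapping used to construct environments."""

    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigurationError(f"config file {path} does not contain a mapping")
    return dict(cfg)
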