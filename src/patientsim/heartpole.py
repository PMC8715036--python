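"""HeartPole: a transparent rule-based lifestyle/productivity simulator.

The scenario is a creative professional trading short-term productivity
against long-term cardiac health.  Six fully observed state variables —
alertness, hypertension, intoxication, hours awake, total hours elapsed and
total work done — evolve under four discrete actions: *just work*, *drink
coffee* (raises alertness and hypertension), *drink beer* (lowers alertness,
raises hypertension and intoxication) and *go to bed* (consumes several
hours but clears hypertension and intoxication and restores alertness).

Each waking step covers half an hour.  The agent earns a small positive
reward proportional to productivity ``eta(alert, tox)`` and a large negative
reward if a heart attack occurs; the per-step heart-attack probability is
``sigmoid(hypert)**2``.  Sleep deprivation, caffeine and alcohol all raise
hypertension, so strategies that look productive over a day lose out over a
week — the environment is intentionally simple enough to see exactly why a
policy failed.

All rate constants and boost magnitudes are design choices of this package
(only their signs and qualitative effects are prescribed by the scenario);
they ship in :class:`HeartPoleParams` and are fully configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np

from .core import ActionError, DiscreteActions, EnvSpec, Environment, StepResult

__all__ = [
    "ACTIONS",
    "JUST_WORK",
    "DRINK_COFFEE",
    "DRINK_BEER",
    "GO_TO_BED",
    "HeartPoleState",
    "HeartPoleParams",
    "productivity",
    "heart_attack_probability",
    "apply_action",
    "HeartPole",
    "heuristic_policy",
    "always_beer_policy",
]

JUST_WORK, DRINK_COFFEE, DRINK_BEER, GO_TO_BED = 0, 1, 2, 3
ACTIONS = ("just_work", "drink_coffee", "drink_beer", "go_to_bed")


@dataclass(frozen=True)
class HeartPoleState:
    """The six HeartPole state variables (all dimensionless except times, in hours)."""

    alert: float = 1.0
    hypert: float = -8.0
    tox: float = 0.0
    tawake: float = 0.0
    ttotal: float = 0.0
    done: float = 0.0

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.alert, self.hypert, self.tox, self.tawake, self.ttotal, self.done],
            dtype=float,
        )


@dataclass(frozen=True)
class HeartPoleParams:
    """Tunable dynamics constants.

    Magnitudes are package defaults chosen for qualitative plausibility, not
    physiological fits: a coffee perks you up for a few hours, a beer is
    metabolised overnight, hypertension relaxes towards a healthy baseline
    over days and sleeping eight hours resets alertness.
    """

    timestep_hours: float = 0.5
    coffee_alert_boost: float = 0.2
    coffee_hypert_boost: float = 0.1
    beer_alert_drop: float = 0.1
    beer_hypert_boost: float = 0.3
    beer_tox_boost: float = 0.25
    sleep_duration_hours: float = 8.0
    sleep_hypert_relief: float = 2.0
    sleep_tox_clear_rate: float = 0.5  # per hour, during sleep
    sleep_alert_restore: float = 1.0
    alert_decay_rate: float = 0.03  # per hour awake
    alert_decay_accel_after: float = 16.0  # hours awake before decay doubles
    hypert_baseline: float = -8.0
    hypert_baseline_decay: float = 0.05  # per hour, relaxation towards baseline
    tox_metabolism_rate: float = 0.2  # per hour awake
    drink_work_fraction: float = 0.5  # share of a drinking step still spent working
    productivity_reward_scale: float = 1.0  # reward per productive hour
    heart_attack_penalty: float = -100.0
    horizon_hours: float = 168.0

    def __post_init__(self) -> None:
        if self.timestep_hours <= 0:
            raise ValueError("timestep_hours must be > 0")
        if self.sleep_duration_hours <= self.timestep_hours:
            raise ValueError("sleep_duration_hours must exceed timestep_hours")
        if not (self.heart_attack_penalty < 0 < self.productivity_reward_scale):
            raise ValueError("need heart_attack_penalty < 0 < productivity_reward_scale")


def productivity(alert: float, tox: float, params: HeartPoleParams | None = None) -> float:
    """Work output rate ``eta(alert, tox)`` in [0, 1].

    Default surface: ``clip(alert, 0, 1) * max(0, 1 - tox)`` — full output at
    maximal alertness and zero intoxication, falling linearly in either
    direction.  This closed form is this package's interpretation of the
    qualitative surface (non-decreasing in alertness, non-increasing in
    intoxication), not a fitted model.
    """

    del params  # reserved for alternative surfaces
    g = min(max(float(alert), 0.0), 1.0)
    return g * max(0.0, 1.0 - float(tox))


def heart_attack_probability(hypert: float) -> float:
    """Per-step heart-attack probability ``sigmoid(hypert)**2``, in (0, 1)."""

    h = float(hypert)
    if h >= 0:
        s = 1.0 / (1.0 + math.exp(-h))
    else:  # avoid overflow for very negative hypertension
        e = math.exp(h)
        s = e / (1.0 + e)
    return s * s


def _decay(value: float, rate: float, hours: float) -> float:
    return value * math.exp(-rate * hours)


def apply_action(
    state: HeartPoleState, action: int, params: HeartPoleParams | None = None
) -> HeartPoleState:
    """Deterministic state update for one action (no heart-attack draw).

    Waking actions advance time by one timestep; ``go_to_bed`` atomically
    consumes a full night so the process stays Markov in the six variables.
    """

    p = params or HeartPoleParams()
    if action not in (JUST_WORK, DRINK_COFFEE, DRINK_BEER, GO_TO_BED):
        raise ActionError(f"unknown HeartPole action {action!r}")

    if action == GO_TO_BED:
        dt = p.sleep_duration_hours
        hypert = p.hypert_baseline + _decay(
            state.hypert - p.hypert_baseline, p.hypert_baseline_decay, dt
        )
        hypert = max(p.hypert_baseline, hypert - p.sleep_hypert_relief)
        return HeartPoleState(
            alert=p.sleep_alert_restore,
            hypert=hypert,
            tox=_decay(state.tox, p.sleep_tox_clear_rate, dt),
            tawake=0.0,
            ttotal=state.ttotal + dt,
            done=state.done,
        )

    dt = p.timestep_hours
    rate = p.alert_decay_rate * (2.0 if state.tawake > p.alert_decay_accel_after else 1.0)
    alert = _decay(state.alert, rate, dt)
    hypert = p.hypert_baseline + _decay(
        state.hypert - p.hypert_baseline, p.hypert_baseline_decay, dt
    )
    tox = _decay(state.tox, p.tox_metabolism_rate, dt)
    work_fraction = 1.0
    if action == DRINK_COFFEE:
        alert += p.coffee_alert_boost
        hypert += p.coffee_hypert_boost
        work_fraction = p.drink_work_fraction
    elif action == DRINK_BEER:
        alert = max(0.0, alert - p.beer_alert_drop)
        hypert += p.beer_hypert_boost
        tox += p.beer_tox_boost
        work_fraction = p.drink_work_fraction
    eta = productivity(alert, tox, p)
    return HeartPoleState(
        alert=alert,
        hypert=hypert,
        tox=tox,
        tawake=state.tawake + dt,
        ttotal=state.ttotal + dt,
        done=state.done + eta * dt * work_fraction,
    )


_BOUNDS = (
    (0.0, math.inf),  # alert
    (-math.inf, math.inf),  # hypert
    (0.0, math.inf),  # tox
    (0.0, math.inf),  # tawake
    (0.0, math.inf),  # ttotal
    (0.0, math.inf),  # done
)


class HeartPole(Environment):
    """HeartPole as an episodic POMDP (fully observed: observation = state).

    Reward per step is ``productivity_reward_scale * eta * worked_hours``,
    plus ``heart_attack_penalty`` (and termination) when the per-step
    Bernoulli heart-attack draw fires.  Reaching the time horizon ends the
    episode neutrally.
    """

    def __init__(self, params: HeartPoleParams | None = None) -> None:
        super().__init__()
        self.params = params or HeartPoleParams()
        self._state = HeartPoleState(hypert=self.params.hypert_baseline)
        horizon = math.ceil(self.params.horizon_hours / self.params.timestep_hours)
        self._spec = EnvSpec(
            observation_dim=6,
            observation_bounds=_BOUNDS,
            action_space=DiscreteActions(len(ACTIONS)),
            reward_support="all_states",
            horizon=horizon,
        )

    @classmethod
    def from_config(cls, config: Mapping[str, Any]) -> "HeartPole":
        return cls(HeartPoleParams(**dict(config)))

    @property
    def spec(self) -> EnvSpec:
        return self._spec

    @property
    def state(self) -> HeartPoleState:
        return self._state

    def _reset_state(self, rng: np.random.Generator) -> np.ndarray:
        self._state = HeartPoleState(hypert=self.params.hypert_baseline)
        return self._state.as_vector()

    def _step(self, action: int, rng: np.random.Generator) -> StepResult:
        p = self.params
        before = self._state
        after = apply_action(before, int(action), p)
        worked = after.done - before.done
        reward = p.productivity_reward_scale * worked
        info: dict[str, Any] = {
            "eta": productivity(after.alert, after.tox, p),
            "heart_attack": False,
        }
        terminated = False
        risk = heart_attack_probability(after.hypert)
        info["heart_attack_probability"] = risk
        if rng.random() < risk:
            reward += p.heart_attack_penalty
            terminated = True
            info["heart_attack"] = True
        if after.ttotal >= p.horizon_hours:
            terminated = True
        self._state = after
        return StepResult(after.as_vector(), float(reward), terminated, info)


def heuristic_policy(obs: np.ndarray) -> int:
    """Never drink; work while rested, sleep once 16 h awake."""

    tawake = float(obs[3])
    return GO_TO_BED if tawake >= 16.0 else JUST_WORK


def always_beer_policy(obs: np.ndarray) -> int:
    """Drink a beer every single step — short-term comfort, long-term ruin."""

    return DRINK_BEER
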