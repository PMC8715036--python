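"""Auto-ALS interface layer: event catalogue, decayed-relevance encoding, rewards.

Auto-ALS is a text-mode resuscitation interface: instead of a rendered 3D
scene the agent sees a stream of named clinical *events* — patient reactions
revealed by assessment actions (``AssessAirway`` can reveal ``AirwayVomit``),
seven numeric *measurements* (heart rate, MAP, ...) and the reward-pathway
events ``Blunder``, ``Failure``, ``Success`` and the once-per-timestep
``Tick``.  Crucially, an event registers only when the agent performed the
assessment that reveals it; assessment skill is part of the task.

The observation at time ``t`` summarises the whole episode history with a
decaying-relevance code: each event contributes ``exp(t_i - t)`` where
``t_i`` is the time it *last* occurred.  Binary events need only that
recency (their value is always one), so the compacted vector stores one
component per binary event and a ``(magnitude, recency)`` pair per
measurement: ``36 + 7*2 = 50`` components instead of the full interleaved
``(36 + 7)*2 = 86``.  Events never observed encode as zero, the limit of
``exp(t_i - t)`` as ``t_i -> -inf``.

Patient *dynamics* are external to this package; the module is an adapter
(:func:`gate_events` + :func:`encode_observation` + :func:`reward_for_tick`)
driven either by the external engine or by the scripted fixture episodes
shipped for testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import InputError, PatientSimError

__all__ = [
    "CatalogueError",
    "TemporalError",
    "EventCatalogue",
    "EventRecord",
    "AlsRewardConfig",
    "load_default_catalogue",
    "compact_size",
    "full_size",
    "encode_observation",
    "encode_observation_full",
    "reward_for_tick",
    "gate_events",
    "scripted_fixture_episode",
    "SCENARIOS",
]


class CatalogueError(PatientSimError):
    """Event or action name absent from the catalogue."""


class TemporalError(PatientSimError):
    """Event record timestamped after the query time."""


@dataclass(frozen=True)
class EventCatalogue:
    """The Auto-ALS vocabulary: binary events, measurements, actions, triggers."""

    binary_events: tuple[str, ...]
    measurements: tuple[str, ...]
    actions: tuple[str, ...]
    triggers: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        names = list(self.binary_events) + list(self.measurements)
        if len(set(names)) != len(names):
            raise CatalogueError("event names must be unique across binary events and measurements")
        known = set(names)
        for action, revealed in self.triggers.items():
            if action not in self.actions:
                raise CatalogueError(f"trigger key {action!r} is not a catalogued action")
            unknown = set(revealed) - known
            if unknown:
                raise CatalogueError(f"trigger events {sorted(unknown)} not in catalogue")

    def is_measurement(self, name: str) -> bool:
        return name in self.measurements

    def __contains__(self, name: str) -> bool:
        return name in self.binary_events or name in self.measurements


@dataclass(frozen=True)
class EventRecord:
    """One time-stamped event occurrence; magnitude present iff a measurement."""

    name: str
    time: float
    magnitude: float | None = None


@dataclass(frozen=True)
class AlsRewardConfig:
    """Reward magnitudes: blunders and ticks are penalised, outcomes are ±1."""

    r_blunder: float = -0.1
    r_tick: float = -0.01
    r_success: float = 1.0
    r_failure: float = -1.0

    def __post_init__(self) -> None:
        if self.r_blunder > 0 or self.r_tick > 0:
            raise ValueError("r_blunder and r_tick must be <= 0")


def load_default_catalogue() -> EventCatalogue:
    """Load the packaged catalogue (36 binary events, 7 measurements, 35 actions)."""

    text = resources.files("patientsim.data").joinpath("autoals_catalogue.json").read_text()
    raw = json.loads(text)
    return EventCatalogue(
        binary_events=tuple(raw["binary_events"]),
        measurements=tuple(raw["measurements"]),
        actions=tuple(raw["actions"]),
        triggers={k: frozenset(v) for k, v in raw["triggers"].items()},
    )


def compact_size(catalogue: EventCatalogue) -> int:
    """Length of the compacted observation: one slot per binary event, two per measurement."""

    return len(catalogue.binary_events) + 2 * len(catalogue.measurements)


def full_size(catalogue: EventCatalogue) -> int:
    """Length of the non-compacted encoding: a (value, recency) pair for every event type."""

    return 2 * (len(catalogue.binary_events) + len(catalogue.measurements))


def _last_occurrences(
    history: Iterable[EventRecord], t: float, catalogue: EventCatalogue
) -> tuple[dict[str, float], dict[str, tuple[float, float]]]:
    last_binary: dict[str, float] = {}
    last_meas: dict[str, tuple[float, float]] = {}
    for rec in history:
        if rec.name not in catalogue:
            raise CatalogueError(f"event {rec.name!r} not in catalogue")
        if rec.time > t:
            raise TemporalError(f"event {rec.name!r} at time {rec.time} is after query time {t}")
        if catalogue.is_measurement(rec.name):
            if rec.magnitude is None:
                raise InputError(f"measurement {rec.name!r} lacks a magnitude")
            prev = last_meas.get(rec.name)
            if prev is None or rec.time >= prev[0]:
                last_meas[rec.name] = (rec.time, rec.magnitude)
        else:
            if rec.magnitude is not None:
                raise InputError(f"binary event {rec.name!r} carries a magnitude")
            last_binary[rec.name] = max(last_binary.get(rec.name, -math.inf), rec.time)
    return last_binary, last_meas


def encode_observation(
    history: Sequence[EventRecord], t: float, catalogue: EventCatalogue
) -> np.ndarray:
    """Compacted decayed-relevance observation vector at query time ``t``.

    One ``exp(t_i - t)`` recency per binary event (0 if never observed) and a
    ``(last magnitude, recency)`` pair per measurement ((0, 0) if never
    observed), in catalogue order.
    """

    last_binary, last_meas = _last_occurrences(history, t, catalogue)
    out = np.zeros(compact_size(catalogue), dtype=float)
    for i, name in enumerate(catalogue.binary_events):
        if name in last_binary:
            out[i] = math.exp(last_binary[name] - t)
    base = len(catalogue.binary_events)
    for j, name in enumerate(catalogue.measurements):
        if name in last_meas:
            ti, mag = last_meas[name]
            out[base + 2 * j] = mag
            out[base + 2 * j + 1] = math.exp(ti - t)
    return out


def encode_observation_full(
    history: Sequence[EventRecord], t: float, catalogue: EventCatalogue
) -> np.ndarray:
    """Non-compacted variant: an explicit (value, recency) pair for every event type.

    Binary events store value 1 once observed; kept for size comparison and
    agents that prefer a homogeneous layout.
    """

    last_binary, last_meas = _last_occurrences(history, t, catalogue)
    out = np.zeros(full_size(catalogue), dtype=float)
    for i, name in enumerate(catalogue.binary_events):
        if name in last_binary:
            out[2 * i] = 1.0
            out[2 * i + 1] = math.exp(last_binary[name] - t)
    base = 2 * len(catalogue.binary_events)
    for j, name in enumerate(catalogue.measurements):
        if name in last_meas:
            ti, mag = last_meas[name]
            out[base + 2 * j] = mag
            out[base + 2 * j + 1] = math.exp(ti - t)
    return out


def reward_for_tick(
    events_this_tick: Sequence[EventRecord], config: AlsRewardConfig
) -> float:
    """Reward for one timestep: ``r_tick`` once, plus per-event outcome terms.

    Blunders, Success and Failure contribute their configured rewards;
    assessments and other observation events contribute nothing.
    """

    reward = config.r_tick
    for rec in events_this_tick:
        if rec.name == "Blunder":
            reward += config.r_blunder
        elif rec.name == "Success":
            reward += config.r_success
        elif rec.name == "Failure":
            reward += config.r_failure
    return reward


def gate_events(
    revealed: set[str],
    action: str,
    true_events: Mapping[str, float | None] | Iterable[str],
    catalogue: EventCatalogue,
    t: float = 0.0,
) -> list[EventRecord]:
    """Information gating: only events revealed by ``action`` register.

    ``true_events`` is what is actually happening to the patient (a mapping
    name -> magnitude, or an iterable of names for binary-only sets); the
    returned records are the subset the agent learns about by performing
    ``action``, per the catalogue's trigger table.  ``revealed`` is the set
    of names already known; re-assessment re-registers an event (refreshing
    its recency), so it is not used for filtering, only updated.
    """

    if action not in catalogue.actions:
        raise CatalogueError(f"unknown action {action!r}")
    if isinstance(true_events, Mapping):
        items = dict(true_events)
    else:
        items = {name: None for name in true_events}
    visible = catalogue.triggers.get(action, frozenset())
    records: list[EventRecord] = []
    for name in catalogue.binary_events + catalogue.measurements:
        if name not in items or name not in visible:
            continue
        magnitude = items[name]
        if catalogue.is_measurement(name):
            if magnitude is None:
                raise InputError(f"measurement {name!r} requires a magnitude")
            records.append(EventRecord(name, t, float(magnitude)))
        else:
            records.append(EventRecord(name, t))
        revealed.add(name)
    unknown = set(items) - set(catalogue.binary_events) - set(catalogue.measurements)
    if unknown:
        raise CatalogueError(f"events {sorted(unknown)} not in catalogue")
    return records


# ---------------------------------------------------------------------------
# Scripted fixture episodes.  These stand in for the external resuscitation
# engine: deterministic action/event scripts that together exercise every
# catalogue entry.  Measurement magnitudes are drawn from seeded, clinically
# plausible ranges.

_MEAS_RANGES = {
    "MeasuredHeartRate": (40.0, 160.0),
    "MeasuredRespRate": (8.0, 40.0),
    "MeasuredCapillaryGlucose": (2.0, 20.0),
    "MeasuredTemperature": (34.0, 41.0),
    "MeasuredMAP": (50.0, 120.0),
    "MeasuredSats": (70.0, 100.0),
    "MeasuredResps": (8.0, 40.0),
}

# Each script: ordered (action, revealed event names) pairs; Tick is appended
# to every step and Success/Failure close the episode.
_SCRIPTS: dict[str, list[tuple[str, list[str]]]] = {
    "responsive_recovery": [
        ("AssessResponse", ["ResponseVerbal"]),
        ("AssessDisability", ["AVPU_A", "PupilsNormal", "MeasuredCapillaryGlucose"]),
        ("AssessAirway", ["AirwayClear"]),
        ("AssessBreathing", ["BreathingEqualChestExpansion", "MeasuredRespRate"]),
        ("AssessCirculation", ["RadialPulsePalpable", "MeasuredHeartRate"]),
        ("AssessExposure", ["ExposureRash", "MeasuredTemperature"]),
        ("BPCuffOn", []),
        ("AssessMonitor", ["HeartRhythm0", "MeasuredHeartRate", "MeasuredMAP",
                           "MeasuredSats", "MeasuredResps"]),
        ("Finish", ["Success"]),
    ],
    "obstructed_airway_failure": [
        ("AssessResponse", ["ResponseGroan"]),
        ("AssessDisability", ["AVPU_V", "PupilsPinpoint"]),
        ("AssessAirway", ["AirwayVomit", "AirwayBlood"]),
        ("Yankeur", []),
        ("AssessAirway", ["AirwayTongue"]),
        ("Guedel", []),
        ("AssessBreathing", ["BreathingSnoring", "BreathingSeeSaw", "VentilationResistance"]),
        ("GiveMidazolam", ["Blunder"]),
        ("AssessCirculation", ["RadialPulseNonPalpable"]),
        ("AssessExposure", ["ExposurePeripherallyShutdown"]),
        ("AssessDisability", ["AVPU_P"]),
        ("Finish", ["Failure"]),
    ],
    "cardiac_arrest_resus": [
        ("AssessResponse", ["ResponseNone"]),
        ("AssessDisability", ["AVPU_U"]),
        ("AssessBreathing", ["BreathingNone"]),
        ("AssessMonitor", ["HeartRhythm1"]),
        ("DefibOn", []),
        ("DefibAttachPads", []),
        ("DefibShock", ["Blunder"]),  # shocked before charging
        ("DefibCharge", []),
        ("DefibShock", []),
        ("AssessMonitor", ["HeartRhythm2"]),
        ("BVM", []),
        ("AssessBreathing", ["BreathingWheeze", "BreathingBibasalCrepitations",
                             "MeasuredRespRate"]),
        ("AssessMonitor", ["HeartRhythm3", "MeasuredHeartRate", "MeasuredSats"]),
        ("AssessExposure", ["ExposureStainedUnderwear"]),
        ("AssessBreathing", ["BreathingCoarseCrepitationsAtBase",
                             "BreathingPneumothoraxSymptoms"]),
        ("AssessMonitor", ["HeartRhythm4"]),
        ("Finish", ["Success"]),
    ],
}

SCENARIOS = tuple(sorted(_SCRIPTS))


def scripted_fixture_episode(
    scenario_id: str, seed: int = 0, catalogue: EventCatalogue | None = None
) -> list[tuple[str, list[EventRecord]]]:
    """Deterministic (action, events) stream for a named scenario.

    Every step carries a ``Tick`` record; measurement magnitudes are drawn
    from plausible clinical ranges with a generator seeded by ``seed``.
    Together the shipped scenarios cover the entire catalogue.
    """

    from .core import ConfigurationError

    if scenario_id not in _SCRIPTS:
        raise ConfigurationError(
            f"unknown scenario {scenario_id!r}; shipped scenarios: {', '.join(SCENARIOS)}"
        )
    cat = catalogue or load_default_catalogue()
    rng = np.random.default_rng(seed)
    stream: list[tuple[str, list[EventRecord]]] = []
    for t, (action, names) in enumerate(_SCRIPTS[scenario_id]):
        time = float(t)
        records = [EventRecord("Tick", time)]
        for name in names:
            if cat.is_measurement(name):
                low, high = _MEAS_RANGES[name]
                records.append(EventRecord(name, time, float(np.round(rng.uniform(low, high), 1))))
            else:
                records.append(EventRecord(name, time))
        stream.append((action, records))
    return stream
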