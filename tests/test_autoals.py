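"""Auto-ALS catalogue, decayed-relevance encoding, rewards and event gating."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from patientsim import (
    AlsRewardConfig,
    CatalogueError,
    ConfigurationError,
    EventCatalogue,
    EventRecord,
    InputError,
    TemporalError,
    compact_size,
    encode_observation,
    encode_observation_full,
    full_size,
    gate_events,
    reward_for_tick,
    scripted_fixture_episode,
)
from patientsim.autoals import SCENARIOS


class TestCatalogue:
    def test_packaged_catalogue_counts(self, catalogue):
        assert len(catalogue.binary_events) == 36
        assert len(catalogue.measurements) == 7
        assert len(catalogue.actions) == 35

    def test_packaged_sizes_match_printed_dimensions(self, catalogue):
        assert compact_size(catalogue) == 50
        assert full_size(catalogue) == 86

    def test_degenerate_catalogue_sizes(self):
        cat = EventCatalogue((), ("MeasuredHeartRate",), ("AssessMonitor",), {})
        assert compact_size(cat) == 2
        assert full_size(cat) == 2

    def test_compact_strictly_smaller_when_binary_events_exist(self, catalogue):
        assert compact_size(catalogue) < full_size(catalogue)

    def test_duplicate_names_rejected(self):
        with pytest.raises(CatalogueError):
            EventCatalogue(("X",), ("X",), ("A",), {})

    def test_trigger_referencing_unknown_event_rejected(self):
        with pytest.raises(CatalogueError):
            EventCatalogue(("X",), (), ("A",), {"A": frozenset({"Y"})})


class TestEncoding:
    def test_empty_history_encodes_to_zero_vector(self, catalogue):
        vec = encode_observation([], 10.0, catalogue)
        assert vec.shape == (50,)
        assert np.all(vec == 0.0)

    def test_event_observed_now_has_unit_recency(self, catalogue):
        vec = encode_observation([EventRecord("AirwayVomit", 5.0)], 5.0, catalogue)
        idx = catalogue.binary_events.index("AirwayVomit")
        assert vec[idx] == pytest.approx(1.0)

    def test_measurement_stores_magnitude_and_decayed_recency(self, catalogue):
        t = 7.0
        vec = encode_observation([EventRecord("MeasuredHeartRate", t - 1.0, 80.0)], t, catalogue)
        base = len(catalogue.binary_events)
        j = catalogue.measurements.index("MeasuredHeartRate")
        assert vec[base + 2 * j] == pytest.approx(80.0)
        assert vec[base + 2 * j + 1] == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_only_last_occurrence_matters(self, catalogue):
        history = [
            EventRecord("ResponseGroan", 1.0),
            EventRecord("ResponseGroan", 4.0),
            EventRecord("ResponseGroan", 2.0),
        ]
        vec = encode_observation(history, 5.0, catalogue)
        idx = catalogue.binary_events.index("ResponseGroan")
        assert vec[idx] == pytest.approx(math.exp(4.0 - 5.0))

    def test_full_encoding_marks_binary_values_as_one(self, catalogue):
        vec = encode_observation_full([EventRecord("AirwayClear", 2.0)], 3.0, catalogue)
        assert vec.shape == (86,)
        i = catalogue.binary_events.index("AirwayClear")
        assert vec[2 * i] == 1.0
        assert vec[2 * i + 1] == pytest.approx(math.exp(-1.0))

    def test_unknown_event_name_rejected(self, catalogue):
        with pytest.raises(CatalogueError):
            encode_observation([EventRecord("NotAnEvent", 0.0)], 1.0, catalogue)

    def test_future_event_rejected(self, catalogue):
        with pytest.raises(TemporalError):
            encode_observation([EventRecord("AirwayClear", 2.0)], 1.0, catalogue)

    def test_binary_event_with_magnitude_rejected(self, catalogue):
        with pytest.raises(InputError):
            encode_observation([EventRecord("AirwayClear", 0.0, 1.0)], 1.0, catalogue)

    @given(
        times=st.lists(st.floats(0, 50), min_size=1, max_size=30),
        query_offset=st.floats(0, 10),
        data=st.data(),
    )
    def test_encoding_depends_only_on_last_occurrence_per_name(
        self, catalogue, times, query_offset, data
    ):
        # Brute-force oracle: recency from an explicit max over each name's times.
        names = data.draw(
            st.lists(
                st.sampled_from(catalogue.binary_events),
                min_size=len(times),
                max_size=len(times),
            )
        )
        t = max(times) + query_offset
        history = [EventRecord(n, ti) for n, ti in zip(names, times)]
        perm = data.draw(st.permutations(history))
        vec = encode_observation(history, t, catalogue)
        vec_perm = encode_observation(perm, t, catalogue)
        assert np.allclose(vec, vec_perm)
        for i, name in enumerate(catalogue.binary_events):
            occ = [ti for n, ti in zip(names, times) if n == name]
            expected = math.exp(max(occ) - t) if occ else 0.0
            assert vec[i] == pytest.approx(expected, abs=1e-12)

    @given(gap=st.floats(0.0, 100.0))
    def test_recency_in_unit_interval_and_decaying(self, catalogue, gap):
        vec_now = encode_observation([EventRecord("AVPU_P", 0.0)], gap, catalogue)
        vec_later = encode_observation([EventRecord("AVPU_P", 0.0)], gap + 1.0, catalogue)
        idx = catalogue.binary_events.index("AVPU_P")
        assert 0.0 < vec_now[idx] <= 1.0
        assert vec_later[idx] < vec_now[idx]


class TestRewards:
    CFG = AlsRewardConfig(r_blunder=-0.1, r_tick=-0.01)

    def test_quiet_tick_costs_only_tick_penalty(self):
        assert reward_for_tick([], self.CFG) == pytest.approx(-0.01)

    def test_success_adds_unit_reward(self):
        events = [EventRecord("Success", 3.0)]
        assert reward_for_tick(events, self.CFG) == pytest.approx(-0.01 + 1.0)

    def test_failure_subtracts_unit_reward(self):
        events = [EventRecord("Failure", 3.0)]
        assert reward_for_tick(events, self.CFG) == pytest.approx(-0.01 - 1.0)

    def test_two_blunders_accumulate(self):
        events = [EventRecord("Blunder", 1.0), EventRecord("Blunder", 1.0)]
        assert reward_for_tick(events, self.CFG) == pytest.approx(-0.21)

    def test_observation_events_contribute_nothing(self):
        events = [EventRecord("AirwayClear", 1.0), EventRecord("MeasuredMAP", 1.0, 70.0)]
        assert reward_for_tick(events, self.CFG) == pytest.approx(-0.01)

    def test_positive_penalties_rejected(self):
        with pytest.raises(ValueError):
            AlsRewardConfig(r_blunder=0.5)


class TestGating:
    def test_revealing_assessment_registers_event(self, catalogue):
        out = gate_events(set(), "AssessAirway", {"AirwayVomit": None}, catalogue, t=2.0)
        assert [r.name for r in out] == ["AirwayVomit"]
        assert out[0].time == 2.0

    def test_non_triggering_action_reveals_nothing(self, catalogue):
        out = gate_events(set(), "AssessResponse", {"AirwayVomit": None}, catalogue)
        assert out == []

    def test_do_nothing_reveals_nothing(self, catalogue):
        truth = {"AirwayVomit": None, "MeasuredHeartRate": 88.0, "ResponseNone": None}
        assert gate_events(set(), "DoNothing", truth, catalogue) == []

    def test_measurements_carry_magnitude_through_gate(self, catalogue):
        out = gate_events(set(), "AssessMonitor", {"MeasuredMAP": 65.0}, catalogue, t=1.0)
        assert out == [EventRecord("MeasuredMAP", 1.0, 65.0)]

    def test_unknown_action_rejected(self, catalogue):
        with pytest.raises(CatalogueError):
            gate_events(set(), "CastFireball", {"AirwayVomit": None}, catalogue)

    def test_revealed_set_is_updated(self, catalogue):
        revealed = set()
        gate_events(revealed, "AssessAirway", {"AirwayVomit": None}, catalogue)
        assert revealed == {"AirwayVomit"}


class TestScriptedFixtures:
    def test_scenarios_jointly_cover_entire_catalogue(self, catalogue):
        seen = set()
        for sid in SCENARIOS:
            for _action, events in scripted_fixture_episode(sid, seed=0):
                seen.update(r.name for r in events)
        assert seen == set(catalogue.binary_events) | set(catalogue.measurements)

    def test_streams_are_deterministic_per_scenario_and_seed(self):
        for sid in SCENARIOS:
            assert scripted_fixture_episode(sid, 3) == scripted_fixture_episode(sid, 3)

    def test_each_scenario_ends_with_exactly_one_outcome(self):
        for sid in SCENARIOS:
            stream = scripted_fixture_episode(sid, 0)
            outcomes = [
                r.name for _a, evs in stream for r in evs if r.name in ("Success", "Failure")
            ]
            assert len(outcomes) == 1
            final_names = {r.name for r in stream[-1][1]}
            assert outcomes[0] in final_names

    def test_events_respect_trigger_table(self, catalogue):
        for sid in SCENARIOS:
            for action, events in scripted_fixture_episode(sid, 0):
                allowed = catalogue.triggers.get(action, frozenset()) | {"Tick"}
                assert {r.name for r in events} <= allowed

    def test_streams_encode_cleanly(self, catalogue):
        for sid in SCENARIOS:
            stream = scripted_fixture_episode(sid, 1)
            history = [r for _a, evs in stream for r in evs]
            t = max(r.time for r in history)
            vec = encode_observation(history, t, catalogue)
            assert vec.shape == (50,)
            assert np.all(np.isfinite(vec))

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ConfigurationError):
            scripted_fixture_episode("not_a_scenario", 0)
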