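"""Encode an Auto-ALS resuscitation episode as decayed-relevance vectors.

Replays a scripted episode (a stand-in for the external resuscitation
engine), accumulates its event stream, and prints the compacted 50-component
observation at the final timestep plus the per-tick rewards.
"""

from patientsim import (
    AlsRewardConfig,
    encode_observation,
    full_size,
    compact_size,
    load_default_catalogue,
    reward_for_tick,
)
from patientsim.autoals import scripted_fixture_episode


def main():
    catalogue = load_default_catalogue()
    print(
        f"Catalogue: {len(catalogue.binary_events)} binary events, "
        f"{len(catalogue.measurements)} measurements, {len(catalogue.actions)} actions"
    )
    print(
        f"Observation sizes: compacted {compact_size(catalogue)}, "
        f"full (value, recency) layout {full_size(catalogue)}\n"
    )

    rewards = AlsRewardConfig(r_blunder=-0.1, r_tick=-0.01)
    stream = scripted_fixture_episode("cardiac_arrest_resus", seed=0)
    history = []
    total = 0.0
    for t, (action, events) in enumerate(stream):
        history.extend(events)
        r = reward_for_tick(events, rewards)
        total += r
        shown = ", ".join(e.name for e in events if e.name != "Tick") or "-"
        print(f"t={t:2d}  {action:18s} -> {shown:55s} reward {r:+.2f}")

    t_final = float(len(stream) - 1)
    obs = encode_observation(history, t_final, catalogue)
    nonzero = int((obs != 0).sum())
    print(f"\nEpisode return {total:+.2f}")
    print(
        f"Final observation: {obs.shape[0]} components, {nonzero} non-zero; "
        "each non-zero binary slot holds exp(t_last - t), each measurement a "
        "(magnitude, recency) pair - recent findings stay near 1, stale ones fade."
    )


if __name__ == "__main__":
    main()
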