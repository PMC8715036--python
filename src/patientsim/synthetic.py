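"""Synthetic MIMIC-like clinical histories from a known latent MDP.

Real intensive-care trajectories are access-restricted, so the test bed for
GraphSim and the evaluation harness is generated from an explicit ground
truth: a small latent Markov chain over patient conditions.  Each latent
state emits a continuous vital/lab vector (its emission mean plus optional
Gaussian noise); each step the logging "behaviour policy" administers one of
a few treatment archetypes (action prototype vectors, optionally jittered);
the latent chain then moves according to a per-(state, prototype) transition
row whose support includes the absorbing outcomes death and discharge.

Because the generating model is known exactly, graph compression can be
checked for latent-skeleton recovery and the environment's transition
frequencies can be compared against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import InputError, PatientSimError
from .histories import ClinicalHistory

__all__ = ["GenerationError", "GroundTruthModel", "sample_ground_truth", "generate_histories"]

DEATH, DISCHARGE = "death", "discharge"


class GenerationError(PatientSimError):
    """Could not construct a valid ground-truth model within the retry budget."""


@dataclass
class GroundTruthModel:
    """Known latent MDP behind the synthetic histories.

    ``transitions[(s, p)]`` is a probability vector over
    ``n_latent`` latent states followed by the two absorbing outcomes
    (death, discharge), indexed ``0..n_latent+1``.
    """

    n_latent: int
    state_dim: int
    action_dim: int
    emission_means: np.ndarray  # (n_latent, d)
    emission_noise_sd: float
    action_prototypes: np.ndarray  # (n_prototypes, k)
    transitions: dict[tuple[int, int], np.ndarray]
    initial_distribution: np.ndarray

    def __post_init__(self) -> None:
        self.emission_means = np.asarray(self.emission_means, dtype=float)
        self.action_prototypes = np.asarray(self.action_prototypes, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        if self.n_latent < 2:
            raise InputError("need at least 2 latent states")
        if self.emission_means.shape != (self.n_latent, self.state_dim):
            raise InputError("emission_means shape mismatch")
        if self.emission_noise_sd < 0:
            raise InputError("emission_noise_sd must be >= 0")
        if abs(self.initial_distribution.sum() - 1.0) > 1e-12:
            raise InputError("initial_distribution must sum to 1")
        n_out = self.n_latent + 2
        for (s, p), row in self.transitions.items():
            row = np.asarray(row, dtype=float)
            if row.shape != (n_out,):
                raise InputError(f"transition row ({s}, {p}) has wrong length")
            if abs(row.sum() - 1.0) > 1e-12 or (row < 0).any():
                raise InputError(f"transition row ({s}, {p}) is not a probability vector")
            self.transitions[(s, p)] = row
        # Separability: merging at a high threshold must not conflate latents.
        means = self.emission_means
        norms = np.linalg.norm(means, axis=1)
        if (norms == 0).any():
            raise InputError("emission means must have non-zero norm")
        cos = (means @ means.T) / np.outer(norms, norms)
        off = cos[~np.eye(self.n_latent, dtype=bool)]
        if off.size and off.max() >= 0.9:
            raise InputError("emission means must have pairwise cosine similarity < 0.9")

    @property
    def n_prototypes(self) -> int:
        return self.action_prototypes.shape[0]


def sample_ground_truth(
    n_latent: int = 4,
    d: int = 6,
    k: int = 3,
    n_prototypes: int = 2,
    seed: int = 0,
    emission_noise_sd: float = 0.0,
    absorbing_mass: float = 0.04,
    dirichlet_alpha: float = 0.3,
    min_prototype_distance: float = 4.0,
    max_retries: int = 200,
) -> GroundTruthModel:
    """Draw a random ground-truth model satisfying all invariants.

    Defaults emulate a small ICU cohort process: a handful of well-separated
    patient conditions, a low per-step hazard of an absorbing outcome
    (``absorbing_mass``, giving stays of a few dozen charting steps), sparse
    mostly-deterministic latent dynamics (``dirichlet_alpha`` < 1) and a few
    clearly distinct treatment archetypes (prototypes at least
    ``min_prototype_distance`` apart, so the action kernel can tell them
    apart at its default bandwidth).
    """

    if n_latent < 2 or d < 2 or k < 1:
        raise InputError("need n_latent >= 2, d >= 2, k >= 1")
    if not (0.0 < absorbing_mass < 1.0):
        raise InputError("absorbing_mass must lie in (0, 1)")
    rng = np.random.default_rng(seed)

    means = None
    for _ in range(max_retries):
        cand = rng.normal(0.0, 1.0, size=(n_latent, d))
        norms = np.linalg.norm(cand, axis=1)
        if (norms == 0).any():
            continue
        cos = (cand @ cand.T) / np.outer(norms, norms)
        if cos[~np.eye(n_latent, dtype=bool)].max() < 0.9:
            means = cand * 10.0  # vitals-scale spread
            break
    if means is None:
        raise GenerationError("could not sample separable emission means")

    protos = None
    for _ in range(max_retries):
        cand = rng.normal(0.0, 3.0, size=(n_prototypes, k))
        ok = True
        for i in range(n_prototypes):
            for j in range(i + 1, n_prototypes):
                if np.linalg.norm(cand[i] - cand[j]) < min_prototype_distance:
                    ok = False
        if ok:
            protos = cand
            break
    if protos is None:
        raise GenerationError("could not sample well-separated action prototypes")

    transitions: dict[tuple[int, int], np.ndarray] = {}
    for s in range(n_latent):
        for p in range(n_prototypes):
            cont = rng.dirichlet(np.full(n_latent, dirichlet_alpha))
            death_share = rng.uniform(0.2, 0.8)
            row = np.concatenate(
                [
                    cont * (1.0 - absorbing_mass),
                    [absorbing_mass * death_share, absorbing_mass * (1.0 - death_share)],
                ]
            )
            row /= row.sum()
            transitions[(s, p)] = row

    init = rng.dirichlet(np.ones(n_latent))
    init /= init.sum()
    return GroundTruthModel(
        n_latent=n_latent,
        state_dim=d,
        action_dim=k,
        emission_means=means,
        emission_noise_sd=emission_noise_sd,
        action_prototypes=protos,
        transitions=transitions,
        initial_distribution=init,
    )


def generate_histories(
    model: GroundTruthModel,
    n_patients: int,
    max_len: int = 100,
    seed: int = 0,
    action_jitter_sd: float = 0.0,
    policy: Sequence[int] | None = None,
) -> list[ClinicalHistory]:
    """Sample patient trajectories from the ground truth.

    The behaviour policy picks a prototype uniformly at random each step
    (or follows the fixed prototype sequence ``policy``, cycled); the logged
    action is the prototype plus optional Gaussian jitter.  Episodes end on
    an absorbing outcome or are censored at ``max_len`` — censored episodes
    are labelled ``discharge`` with ``metadata["censored"] = True`` to keep
    the two-outcome convention.
    """

    if n_patients < 1 or max_len < 1:
        raise InputError("need n_patients >= 1 and max_len >= 1")
    rng = np.random.default_rng(seed)
    n_out = model.n_latent + 2
    histories: list[ClinicalHistory] = []
    for pid in range(n_patients):
        latent = int(rng.choice(model.n_latent, p=model.initial_distribution))
        states, actions, latents = [], [], []
        outcome, censored = None, False
        for t in range(max_len):
            emission = model.emission_means[latent]
            if model.emission_noise_sd > 0:
                emission = emission + rng.normal(0, model.emission_noise_sd, model.state_dim)
            proto_idx = (
                int(policy[t % len(policy)]) if policy is not None
                else int(rng.integers(model.n_prototypes))
            )
            action = model.action_prototypes[proto_idx]
            if action_jitter_sd > 0:
                action = action + rng.normal(0, action_jitter_sd, model.action_dim)
            states.append(np.asarray(emission, dtype=float))
            actions.append(np.asarray(action, dtype=float))
            latents.append(latent)
            nxt = int(rng.choice(n_out, p=model.transitions[(latent, proto_idx)]))
            if nxt == model.n_latent:
                outcome = DEATH
                break
            if nxt == model.n_latent + 1:
                outcome = DISCHARGE
                break
            latent = nxt
        if outcome is None:
            outcome, censored = DISCHARGE, True
        histories.append(
            ClinicalHistory(
                patient_id=f"p{pid:05d}",
                states=np.stack(states),
                actions=np.stack(actions),
                outcome=outcome,
                metadata={"censored": censored, "latents": latents},
            )
        )
    return histories
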