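# Methods

This note records the models implemented in `patientsim`, the design
decisions taken where the underlying descriptions were qualitative or open,
and what the synthetic test bed does and does not establish.

## The episodic POMDP contract

All simulators implement one contract
(`M = (S_nt, S_t, A, O, p_o, p_s, p_r, p_init)`): `reset(seed)` samples
`p_init` and returns the first observation; `step(action)` samples the
transition, observation and reward; entering a terminal state ends the
episode and further steps raise a lifecycle error. Design choices:

* **RNG ownership.** The environment owns a single `numpy` generator seeded
  at `reset`; it drives `p_init`, `p_s` and any stochastic rewards jointly,
  so `(seed, action sequence)` fully determines a trace.
* **Undiscounted traces.** `EpisodeTrace.total_return` is the raw reward
  sum; discounting is an agent concern, not part of the process definition.
* **Flat real observations.** Even fully observed environments (HeartPole,
  GraphSim) expose observations as flat vectors, keeping one agent
  interface. All three shipped simulators use *deterministic* observation
  maps; the contract admits stochastic `p_o` but none of the shipped
  environments needs it.
* `validate_env` performs seeded random rollouts and reports (never raises)
  bound violations, non-finite rewards, horizon overruns, and non-zero
  interior rewards in environments declared `terminal_only`.

## HeartPole

State: alertness `s_alert`, hypertension `s_hypert`, intoxication `s_tox`,
hours awake `s_tawake`, total hours `s_ttotal`, work done `s_done`. Actions:
just work / drink coffee / drink beer / go to bed, on a half-hour grid.

Only the signs and qualitative shape of the dynamics are externally
prescribed (coffee raises alertness and hypertension; beer lowers alertness
and raises hypertension and intoxication; sleep takes long but relieves
both and resets the wakefulness clock; alertness decays faster after long
wakefulness). All magnitudes are this package's defaults, chosen for
plausibility on a weekly time scale and shipped in one configurable block
(`HeartPoleParams`):

| parameter | default | meaning |
|---|---|---|
| `timestep_hours` | 0.5 | decision interval while awake |
| `coffee_alert_boost` / `coffee_hypert_boost` | 0.2 / 0.1 | per cup |
| `beer_alert_drop` / `beer_hypert_boost` / `beer_tox_boost` | 0.1 / 0.3 / 0.25 | per beer |
| `sleep_duration_hours` | 8 | consumed atomically by one `go_to_bed` |
| `sleep_hypert_relief` | 2.0 | additive drop, floored at baseline |
| `sleep_tox_clear_rate` | 0.5 /h | exponential clearance while asleep |
| `sleep_alert_restore` | 1.0 | alertness after a full night |
| `alert_decay_rate` | 0.03 /h | doubles once `tawake` > 16 h |
| `hypert_baseline` / `hypert_baseline_decay` | −8 / 0.05 /h | relaxation target and rate |
| `tox_metabolism_rate` | 0.2 /h | waking clearance |
| `drink_work_fraction` | 0.5 | share of a drinking step still worked |
| `productivity_reward_scale` | 1 | reward per productive hour |
| `heart_attack_penalty` | −100 | terminal penalty |
| `horizon_hours` | 168 | one week |

* **Productivity surface.** The reference description is graphical only; the
  default closed form is `η(alert, tox) = clip(alert, 0, 1) · max(0, 1 − tox)`
  — normalised to [0, 1], non-decreasing in alertness, non-increasing in
  intoxication. It is an interpretation, not a fitted surface.
* **Cardiac risk.** `P(heart attack per step) = sigmoid(s_hypert)²`, drawn
  as an independent Bernoulli each step (the simplest reading of "a very
  large negative reward if a heart attack occurs"); no hazard integral.
  The baseline −8 puts the healthy per-step risk near 1e−7.
* **Sleep restores alertness.** `HeartPoleParams` adds `sleep_alert_restore`
  (not in the qualitative description, where only the *absence* of sleep is
  discussed): without restoration alertness would decay monotonically for
  every policy and the sleep/wake trade-off would be vacuous.
* **Atomic sleep.** `go_to_bed` consumes 8 h in one step call, keeping the
  decision process Markov in the six state variables.
* Reaching `horizon_hours` terminates neutrally; it is not distinguished
  from "success".

With these defaults the intended ordering emerges rather than being coded:
constant beer drinking drives hypertension up ~0.6/h against a 5 %/h
relaxation and ends in a heart attack in essentially every episode, while
the sleep-on-schedule teetotaller finishes the week (≈ 88 productive
hours).

## Auto-ALS encoding

The catalogue packages the action/event vocabulary: 35 actions, 7
measurements, and 36 binary events. Enumerable patient reactions number 31;
the consciousness scale is completed with `AVPU_P` (alert/voice/pain/
unresponsive — the pain level is plainly part of the scale but absent from
the printed reaction lists), and the four reward-pathway events `Blunder`,
`Failure`, `Success`, `Tick` are catalogued as binary observations as well,
giving 36 and preserving the published sizes 50/86. Including them in the
observation is deliberate: whether a blunder has just been signalled is
information the agent legitimately has.

* **Encoding.** For each binary event one component `exp(t_i − t)` with
  `t_i` its *last* occurrence; for each measurement a `(magnitude,
  recency)` pair. Never-observed components are 0 — the limit of
  `exp(t_i − t)` as `t_i → −∞`. Time is measured in simulator ticks.
* **Gating.** `gate_events` filters the true patient condition through the
  trigger table (e.g. `AirwayVomit` registers only under `AssessAirway`);
  re-assessment re-registers an event, refreshing its recency.
* **Rewards.** Per tick: `r_tick` once, plus `r_blunder` per blunder and
  ±1 for `Success`/`Failure`. Defaults `r_tick = −0.01`, `r_blunder = −0.1`.
* **No patient dynamics.** The clinical engine is external software; the
  scripted fixture episodes (three scenarios jointly covering the whole
  catalogue) exist to drive the adapter deterministically in tests and
  examples, not to model resuscitation.

Known tensions in the source material — an observation space printed as
`[0, ∞)^36` with 34 actions versus the 50-component vector and 35
enumerated actions — are resolved in favour of the detailed table/formula
reading (50 components, 35 actions). Measurement magnitudes may be negative
even though recencies are non-negative.

## GraphSim

* **Construction.** One node per logged (patient, step) state, one
  outcome-labelled terminal node per history (carrying the final observed
  state so every node has a vector), one arc per step; `T` steps give
  `T + 1` nodes and `T` arcs. Initial nodes are the logged first states,
  sampled uniformly at reset (logged-frequency weighting would be the
  alternative; uniform is the simpler convention and is documented here).
* **Merging.** Greedy agglomerative: repeatedly merge the most
  cosine-similar eligible pair with similarity ≥ `c_min` into
  `(s_A + s_B)/2`, redirect arcs, recompute similarities; ties break to the
  lowest node ids. Terminal nodes never merge; the arc multiset is
  preserved. The printed inequality (`cos < c_min` called "below a
  similarity threshold") selects *dissimilar* pairs and would merge
  opposites; it is implemented as ≥, the only direction consistent with
  merging "very similar" states. Exactly identical states are collapsed in
  a linear pre-pass (greedy order would take those cosine-1 pairs first
  anyway), which keeps multi-thousand-node merges tractable; the general
  loop uses an incrementally updated similarity heap.
* **Similarity space.** Cosine is computed on raw vectors by default. A
  `standardize` flag re-centres and rescales per feature for heterogeneous
  clinical units, but it is off by default: standardisation uses
  node-population statistics and can rotate two distinct noiseless states
  into near-alignment, silently breaking latent-skeleton recovery.
* **Transitions.** Arc weights use the Gaussian action kernel
  `exp(−‖a_t − a‖²/(2σ²))`, σ = `kernel_bandwidth` (default 1, in action
  units); the probability of a successor is the normalised weight sum of
  arcs landing on it. The literal printed exponent (positive sign) is
  available via `literal_eq7_sign` for fidelity experiments — it up-weights
  *dissimilar* actions and is kept numerically stable by log-space
  normalisation — but the Gaussian kernel is the default, being the only
  reading under which the choice of timeline tracks the doctor's action.
* **Rewards and termination.** Terminal-only: 0 at every interior step,
  `r_discharge = +1` / `r_death = −1` on absorption. A horizon (default
  200 steps) guards against cycles introduced by merging and truncates with
  reward 0.

## Synthetic clinical histories

The generator emulates the *structure* of ICU trajectories — continuous
vital/lab state vectors, continuous dose-vector actions, variable-length
episodes ending in death or discharge — from an explicit latent MDP so that
recovery can be checked exactly.

Defaults (the study conditions for all shipped tests): 4 latent states,
state dimension 6, action dimension 3, 2 treatment prototypes, noiseless
emissions, per-step absorbing hazard 0.04 (mean stay ≈ 25 steps, echoing
multi-day ICU stays on a charting grid), sparse latent dynamics
(Dirichlet α = 0.3 rows scaled to the non-absorbing mass, death/discharge
split uniformly), emission means drawn at scale 10 with pairwise cosine
< 0.9 enforced by retry, prototypes ≥ 4 apart in action space so the
default kernel separates them (relative contamination ≤ e^−8). The
behaviour policy is uniform over prototypes with optional jitter (default
0) — action diversity at shared states is what gives the merged graph
multiple timelines. Censoring at `max_len` (default 100, hit with
probability ≈ e^−4 per patient) is labelled discharge with a
`censored` metadata flag, keeping the two-outcome reward convention.

What the synthetic bed does **not** emulate: real marginal distributions of
vitals, feature correlations, measurement noise structure, irregular
charting times, or demographic mix. Passing recovery tests therefore shows
the *algorithmic* pipeline is sound (graph construction, merging, kernel
transitions, frequency estimation), not that GraphSim built on real data is
clinically accurate.

## Evaluation

* **Accuracy.** `mean_predictive_error` matches each held-out state to the
  most cosine-similar non-terminal node, takes the expectation of the
  next-state distribution under the held-out action, and reports the root
  mean squared Euclidean distance to the observed next state. Squared loss
  is used because the expectation is its optimal point prediction, which
  makes the metric consistent: it decreases (weakly) as the training set
  grows. Terminal successors carry outcomes rather than next states, so
  their probability mass is excluded and the distribution renormalised;
  transitions with no match above `min_similarity`, zero-norm states, or
  only-terminal successors are counted and excluded.
* **Difficulty.** `difficulty_probe` compares a uniform-random policy with
  tabular Q-learning on per-dimension quantile bins (default 8 bins fitted
  from 1,000 random-policy observations; 50,000 training steps; learning
  rate 0.2, γ = 0.99, ε linearly annealed 1 → 0.05), frozen before
  evaluation. Continuous-action environments are handled through a finite
  candidate set — GraphSim exposes its distinct logged arc actions. Unseen
  states fall back to zero-initialised Q-values with ties broken toward the
  lowest action index.
* **SOFA shaping.** `C0·1[SOFA_{t+1} = SOFA_t > 0] + C1·(SOFA_{t+1} −
  SOFA_t) + C2·tanh(Lactate_{t+1} − Lactate_t)`. The coefficients have no
  published values and are therefore required configuration; the proposed
  third component penalising action severity is described without a formula
  anywhere and is deliberately not implemented. The reward is bounded by
  `|C0| + |C1|·ΔSOFA_max + |C2|` for bounded SOFA changes.

## Problem sizes used in the shipped tests

Latent-recovery experiments use 200 patients (≈ 5,000 transitions — about
250 arcs per (state, prototype) cell, enough for empirical frequencies to
sit within ±0.05 of ground truth); the accuracy-consistency experiment
scores training sizes 10/100/1000 against 400 held-out patients, a held-out
set chosen large enough to resolve the small 100 → 1000 improvement; the
difficulty probe trains for 50,000 steps and evaluates 200 episodes.

## Known limitations

* HeartPole's constants are plausibility choices; no physiological claim is
  made (nor intended — transparency is its purpose).
* GraphSim interpolates states only by averaging merged pairs; actions
  never interpolate, so an agent action far from every logged arc still
  selects among logged timelines (near-uniformly, by kernel symmetry).
* Greedy merge order is deterministic but not globally optimal; different
  orders can yield slightly different merged graphs when similarities tie
  near `c_min`.
* The tabular difficulty baseline is intentionally weak; it bounds
  difficulty from above (an environment it solves is easy) but says little
  about environments it fails on.
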