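# Methods

This note documents the models, parameter choices and numerical
details behind the package, and what the synthetic-data validation
does and does not establish.

## Data representation

Raw input is a table of timestamped behavior events (smile and
gaze-at-partner onsets/offsets per actor). Analysis operates on binary
time series binned at 1.0 s: a bin is scored 1 when the behavior
covers at least 50% of the bin interval (both the bin width and the
coverage threshold are configurable). Coordinates are 0-based with
half-open `[start, end)` episodes.

Because the infant can only respond to smiles it can see, analysis is
restricted to *gaze-gated episodes*: maximal runs of gaze-at-mother of
at least `min_len_bins` (default 2) bins. The same gate is applied by
default when the mother is the agent, for symmetry of the two
analyses; `require_gaze=False` disables it for the mother-as-agent
case, since the mother sees the infant's face throughout. Episodes
from all of a dyad's sessions are pooled, and elapsed-time counters
reset at each episode start.

## The plant: a semi-Markov toggle-hazard model

The modeled partner switches smile state at each bin transition with
probability *h*(*s*<sub>self</sub>, *s*<sub>other</sub>, τ), where
*s*<sub>self</sub> is the partner's own smile state, *s*<sub>other</sub>
the other member's, and τ the number of bins since the partner's own
last switch, capped at *K* − 1 (*K* = 30 by default; beyond 30 s
hazards are pooled). This family expresses the two dependencies the
analysis needs: responsivity (onset hazard raised while the other
smiles) and duration-dependent cessation (offset hazard rising in τ
while smiling alone). It assumes hazards depend only on the current
joint configuration and the partner's own elapsed time — not on the
other member's elapsed time or on longer history.

Estimation is by Laplace-smoothed counts, *h* = (toggles + α) /
(exposures + 2α) with α = 1 by default. The smoothing guarantees
strictly interior probabilities, so every plan and likelihood below is
well defined; unvisited cells fall back to 1/2, the no-information
value.

## The agent's decision problem

The agent's state is (*a*, *p*, τ<sub>a</sub>, τ<sub>p</sub>): both
smile states plus both elapsed times, with the agent's own cap
*K*<sub>a</sub> = 10 (the agent's elapsed time matters mainly through
its own policy, not the reward, so a smaller cap suffices; both caps
are configurable). Actions are keep and toggle. Within a bin the
action sets *a* deterministically, while the partner toggles with its
hazard evaluated at the *pre-action* agent state — a one-bin reaction
latency that encodes the causal ordering of turn-taking. Reward is 1
when the post-transition configuration matches the hypothesized goal.

The objective is infinite-horizon discounted occupancy with γ = 0.98
per second. An average-reward criterion would be the canonical reading
of "maximize time in a configuration"; discounted value iteration
approximates it for γ near 1 and is numerically simpler and guaranteed
to converge. Value iteration runs to a sup-norm Bellman residual below
1e−9 (typically ~1,000 sweeps of the 1,200-state problem at γ = 0.98).

### Wait-time performance curves

For the context "the agent has just stopped smiling while the partner
smiles", `wait_time_performance` evaluates the family of strategies
"keep for *t* bins, then toggle, then follow the optimal policy". If
the partner's state changes during the wait, the commitment is
abandoned and the agent follows the optimal policy from that point —
the wait is defined relative to an unchanged context. The curve is
computed by exact dynamic programming over partner trajectories (no
sampling) and normalized by (1 − γ) to lie in [0, 1]. The optimal
value weakly dominates every such fixed-wait strategy by construction;
the shape of the curve shows the tradeoff between immediate occupancy
and keeping the partner's rising cessation hazard at bay.

With the default generator parameters, the deterministic optimal
policy in this context is to keep waiting, but the action-value
advantage of re-smiling increases strictly with the mother's elapsed
smiling time; a Boltzmann agent therefore re-smiles with a hazard that
grows over the wait, producing a short-to-moderate interior mode in
its empirical wait distribution.

## Goal inference

Observed keep/toggle decisions are scored against each goal's optimal
action values with a Boltzmann likelihood, *P*(*u* | *s*) ∝
exp(β·*Q*\*(*s*, *u*)). The rationality temperature β is a nuisance
parameter: the evidence for a goal marginalizes β over 16 log-spaced
points in [0.1, 100] with a uniform grid prior, computed in log space.
An ε-greedy likelihood is provided as a sensitivity alternative. Goal
posteriors combine the evidence with a uniform prior (0.25 per goal,
the chance level used for the prevalence tests); the per-dyad output
is the normalized posterior, its log-evidence vector and the MAP goal.
The partner model used for planning is fit on the same dyad's episodes
with the complementary role assignment (an optional holdout split is
available for cross-validated scoring).

Two identifiability caveats follow from the construction. First, if
the partner's behavior does not depend on the agent (e.g. a coin-flip
partner), the partner-side component of the goal is uninformative and
goals sharing an agent-side target receive identical evidence. Second,
β and goal sharpness trade off at small samples; marginalizing β makes
the posterior reflect fit across the whole rationality range rather
than a single tuned value.

## Synthetic data generator

The generator emulates the statistical regularities the analysis
assumes, at 1 s resolution:

| parameter | default | meaning |
|---|---|---|
| `base_onset_hazard` | 0.03 /s | partner smile onset, other not smiling |
| `responsive_onset_boost` | 4.0 | onset multiplier while the other smiles |
| `offset_c0`, `offset_c1` | 0.02, 0.02 | offset hazard alone: min(c0 + c1·τ, 0.5) |
| `offset_hazard_mutual` | 0.05 /s | offset hazard during mutual smiling |
| `gaze_on_prob` | 0.6 | stationary gaze-at-partner fraction |
| `gaze_run_mean_bins` | 8 | mean gaze run length (s) |
| `session_len_bins`, `n_sessions` | 300, 10 | weekly-session structure |

Hazards are capped at 0.5/s to keep toggling identifiable at 1 s bins.
The agent side is generated from the planner itself: it samples
actions from softmax(β·*Q*\*) for its assigned goal (β = 20 for the
default cohort), making the generative model self-consistent with the
inference model. A hand-coded reflex agent (smile with fixed
probability a fixed delay after a partner onset) is provided to probe
inference under misspecification. Cohorts of 13 dyads apply ~±20%
lognormal jitter to each dyad's hazard parameters as individual
differences, and ship a manifest of ground-truth goals and parameters.

What the generator does *not* emulate: graded smile intensity,
vocal/tactile channels, gaze that depends on the interaction state,
session-to-session development, coder noise, and real infants'
empirical 1 s modal wait time (the generator's wait mode falls at a
few seconds, where the planner's incentive to re-smile peaks). Passing
recovery tests therefore shows the pipeline is correct and internally
consistent — fit, plan and score invert the generative process — not
that real dyads satisfy the model's assumptions.

## The controller-versus-adult simulation

The companion experiment is replicated software-only: the "adult" is a
hazard-model plant from the same parametric family as the synthetic
mother (per-participant lognormal jitter stands in for individual
differences), not a human perceived through automated expression
recognition. Four controllers play 180 s sessions: the inferred infant
policy (deterministic argmax by default; a β flag enables stochastic
acting), replay of the previous participant's infant-controller robot
trace (participant 0 replays a seeded bootstrap session), a smile
mirror with a 1-bin latency, and infant-plus (the infant action, then
with probability 0.5/s overwritten by the participant's current
state). Condition order is Latin-square counterbalanced; since the
simulated adult carries no state across sessions, order affects only
bookkeeping. Within each bin the adult updates first, reacting to the
robot's previous state, then the controller emits its smile; the
post-update configuration is tallied, so the four occupancies
partition the session exactly.

The positivity rating is a proxy: mutual-smile seconds plus Gaussian
rater noise. The noise scale (sd 45 s) was calibrated by a sweep so
the rating/mutual-smiling correlation falls in the moderate range
(mean r ≈ 0.57 across replicate experiments); only this correlation
structure, not questionnaire content, is modeled.

## Statistical summaries

`binom_tail` is the exact upper-tail pmf sum (tested to 1e−12 against
the incomplete-beta form of the survival function). The
repeated-measures ANOVA uses the standard one-way within-subjects
decomposition; the Greenhouse–Geisser ε is estimated from the
double-centered condition covariance and applied to both degrees of
freedom whenever k > 2 (a flag restricts the correction to cases where
Mauchly's test rejects, and k = 2 reduces exactly to the paired t-test
with F = t²). η² is reported as partial (SS_effect / (SS_effect +
SS_error)), with the classical variant alongside. Under an iid normal
null the *uncorrected* p-values are exactly uniform, which is what the
null-calibration test checks; GG-corrected p-values under true
sphericity are mildly conservative by design. Identical conditions
yield F = 0, p = 1; a fully constant table is an error.

## Numerical and testing choices

- Value iteration: tol 1e−9 sup-norm, max 100,000 iterations;
  convergence failure raises rather than returning a stale plan.
- Evidence is accumulated with log-sum-exp throughout; posteriors are
  renormalized to machine precision.
- Oracle scales: Monte-Carlo checks use 100,000 draws; brute-force
  planning checks use a 5,000-step finite-horizon backward induction
  on K = K_a = 3 problems; wait-curve rollouts truncate at 700 bins,
  where the discount tail (γ⁷⁰⁰ < 1e−6) is far below Monte-Carlo
  error. The default synthetic cohort is 13 dyads × 10 sessions ×
  300 s, ~1,800 gazed bins per dyad.
- Seeds: all generators take explicit seeds; cohorts spawn per-dyad
  child seeds from a root `SeedSequence`, so per-dyad streams are
  independent and reproducible.

## Known limitations

- The hazard plant conditions on one elapsed-time variable only; real
  maternal smiling likely carries longer history and graded intensity.
- The discounted criterion with γ = 0.98 approximates, but is not, the
  average-occupancy objective; goal posteriors can shift slightly
  with γ.
- The Boltzmann noise model is an assumption, not an observed
  mechanism; the ε-greedy alternative is provided for sensitivity
  analysis but no model comparison between the two is built in.
- The simulated adult in the controller experiment inherits the
  synthetic mother's parametric family; conclusions about controller
  ranking are internal to that family.
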