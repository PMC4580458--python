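# smilegames

Inverse optimal control of mother–infant smile games.

Face-to-face smiling between a caregiver and a young infant is a
tightly timed exchange, but descriptive statistics of responsivity say
little about *why* each partner times their smiles as they do. This
package treats the interaction as a control problem and asks which
dyadic end state each partner's smile timing is best explained by. It
is intended for researchers in developmental psychology and
computational ethology working with binary behavioral time series
(smile on/off, gaze on/off) from dyadic interactions, whether observed
or simulated.

## The method

For an agent (say, the infant) and a plant (the mother), the analysis
runs in four steps:

1. **Fit the plant.** The partner's smiling is modeled as a
   discrete-time semi-Markov toggle process: at each 1 s bin the
   partner switches smile state with hazard *h*(*s*<sub>self</sub>,
   *s*<sub>other</sub>, τ), where τ is the time since the partner's own
   last switch. This captures responsive smile onsets and
   duration-dependent smile cessation. Hazards are Laplace-smoothed
   toggle/exposure counts from gaze-gated episodes.
2. **Hypothesize a goal.** Each candidate goal is one of the four joint
   smile configurations — both smiling, mother-only, infant-only,
   neither — rewarded 1 per second of occupancy.
3. **Plan.** The agent's problem is a discounted MDP over states
   (*a*, *p*, τ<sub>a</sub>, τ<sub>p</sub>) with actions keep/toggle;
   value iteration yields the optimal smile-timing policy π\* and
   action values *Q*\* for each goal (γ = 0.98 per second).
4. **Score.** Observed keep/toggle decisions are evaluated under a
   Boltzmann (softmax) rationality model, *P*(*u* | *s*) ∝
   exp(β·*Q*\*(*s*, *u*)), with β marginalized over a log-spaced grid;
   the resulting evidence per goal gives a posterior over the four
   goals (uniform prior, chance = 0.25).

The package also includes a synthetic-data generator with the same
statistical structure (for end-to-end goal-recovery validation), a
software-only replication of the companion study in which four smile
controllers (the inferred infant policy, replay, mirror, infant-plus)
interact with a simulated adult, and the statistical summaries used
throughout (exact binomial tails, repeated-measures ANOVA with
Greenhouse–Geisser correction, paired *t*, Pearson *r*).

## Worked example

Simulate one dyad whose infant pursues mother-only smiling, then infer
its goal from the data alone:

```python
import numpy as np
from smilegames import (
    DyadState, GeneratorParams, GoalSpec, build_mdp, extract_episodes,
    fit_hazard, goal_posterior, make_partner_hazard, simulate_dyad,
    value_iteration, wait_time_performance,
)

params = GeneratorParams()                      # responsive mother defaults
mother = make_partner_hazard(params)            # ground-truth plant

goal = GoalSpec(target="mother_only", agent_role="infant")
plan = value_iteration(build_mdp(mother, goal, gamma=0.98))
sessions = simulate_dyad(mother, goal, agent_beta=20.0, params=params, seed=7)
episodes = [ep for s in sessions for ep in extract_episodes(s, min_len_bins=2)]

fitted = fit_hazard(episodes, modeled_partner="mother", K=30, alpha=1.0)
posterior = goal_posterior(episodes, fitted, dyad_id="d00")
print("posterior:", posterior.p.round(3))
print("MAP goal:", posterior.map_goal)

curve = wait_time_performance(plan, DyadState(a=0, p=1), t_max=5)
print("wait-time performance:", curve.round(3))
```

Output:

```
posterior: [0. 0. 1. 0.]
MAP goal: mother_only
wait-time performance: [0.451 0.454 0.457 0.459 0.461 0.463]
```

The posterior is over (neither, infant-only, mother-only, mutual): the
generating goal is recovered with essentially all of the mass. The
wait-time curve gives the normalized expected mother-only occupancy of
"wait *t* seconds before smiling again, then follow the optimal
policy", from the context where the infant has just stopped smiling
while the mother smiles — longer waits score slightly better here, but
the advantage of waiting shrinks as the mother's cessation hazard
rises.

The same pipeline is available from the shell:

```bash
smilegames synth --out runs/demo --seed 0
smilegames infer --events runs/demo/events.csv --agent infant --out runs/demo/posteriors.csv
smilegames run-all --out runs/full --seed 0
```

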