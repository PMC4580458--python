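"""Bayesian goal inference from observed smile timing.

Inverse optimal control, step four: for each candidate dyadic goal,
score how well the agent's observed keep/toggle decisions match the
optimal policy for that goal, then combine scores into a posterior over
goals.  Actions are modeled as Boltzmann (softmax) rational — chosen
with probability proportional to exp(beta * Q) — with the rationality
temperature beta marginalized over a grid, so the inference does not
have to commit to how noisy the agent is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from smilegames.dyad_io import Episode, SmileSeries, extract_episodes
from smilegames.partner_model import HazardModel, fit_hazard
from smilegames.planner import (
    GOAL_TARGETS,
    GoalSpec,
    PlanResult,
    build_mdp,
    value_iteration,
)

logger = logging.getLogger(__name__)


@dataclass
class RationalityConfig:
    """Noise model linking action values to observed actions."""

    model: str = "softmax"
    beta_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.1, 100.0, 16)
    )
    epsilon_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.05, 0.501, 0.05)
    )
    goal_prior: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        if self.model not in ("softmax", "epsilon_greedy"):
            raise ValueError("model must be 'softmax' or 'epsilon_greedy'")
        self.beta_grid = np.asarray(self.beta_grid, dtype=float)
        self.epsilon_grid = np.asarray(self.epsilon_grid, dtype=float)
        self.goal_prior = np.asarray(self.goal_prior, dtype=float)
        if self.beta_grid.size == 0 or self.epsilon_grid.size == 0:
            raise ValueError("rationality grids must be nonempty")
        if not np.isclose(self.goal_prior.sum(), 1.0):
            raise ValueError("goal_prior must sum to 1")


@dataclass
class GoalPosterior:
    """Per-dyad posterior over the four dyadic goals."""

    dyad_id: str
    agent_role: str
    p: np.ndarray  # probabilities, GOAL_TARGETS order
    log_evidence: np.ndarray  # marginal action log-likelihood per goal
    map_goal: str

    def __post_init__(self) -> None:
        if not np.isclose(self.p.sum(), 1.0, atol=1e-12):
            raise ValueError("posterior must sum to 1")
        if (self.p < 0).any():
            raise ValueError("posterior entries must be non-negative")


def _episode_state_actions(episodes: list[Episode], mdp) -> tuple[np.ndarray, np.ndarray]:
    """Track (state index, action) pairs along observed episodes.

    Elapsed-time counters for both channels reset to 0 at each episode
    start and are capped at the model's K_a / K.
    """
    states: list[int] = []
    actions: list[int] = []
    K, K_a = mdp.K, mdp.K_a
    for ep in episodes:
        a_ch, p_ch = ep.agent_smile, ep.partner_smile
        tau_a = tau_p = 0
        for t in range(len(a_ch) - 1):
            s = ((int(a_ch[t]) * 2 + int(p_ch[t])) * K_a + tau_a) * K + tau_p
            u = int(a_ch[t + 1] != a_ch[t])
            states.append(s)
            actions.append(u)
            tau_a = 0 if u else min(tau_a + 1, K_a - 1)
            tau_p = 0 if p_ch[t + 1] != p_ch[t] else min(tau_p + 1, K - 1)
    return np.asarray(states, dtype=np.int64), np.asarray(actions, dtype=np.int64)


def action_loglik(
    episodes: list[Episode], plan: PlanResult, beta: float
) -> float:
    """Softmax action log-likelihood of observed keep/toggle decisions.

    Each bin transition contributes log softmax(beta * Q(s, .))[u] for
    the realized action u.
    """
    states, actions = _episode_state_actions(episodes, plan.mdp)
    if states.size == 0:
        return 0.0
    return float(_loglik_grid(states, actions, plan.Q, np.array([beta]))[0])


def _loglik_grid(
    states: np.ndarray, actions: np.ndarray, Q: np.ndarray, betas: np.ndarray
) -> np.ndarray:
    """Summed softmax log-likelihood for every beta in one pass."""
    q = Q[states]  # (T, 2)
    bq = betas[:, None, None] * q[None, :, :]  # (B, T, 2)
    logp = bq - logsumexp(bq, axis=2, keepdims=True)
    return logp[:, np.arange(len(actions)), actions].sum(axis=1)


def _loglik_grid_epsilon(
    states: np.ndarray, actions: np.ndarray, policy: np.ndarray, epsilons: np.ndarray
) -> np.ndarray:
    match = (policy[states] == actions).astype(float)
    out = np.empty(len(epsilons))
    for i, eps in enumerate(epsilons):
        out[i] = float(
            (match * np.log(1.0 - eps) + (1.0 - match) * np.log(eps)).sum()
        )
    return out


def goal_posterior(
    episodes: list[Episode],
    partner: HazardModel,
    config: RationalityConfig | None = None,
    gamma: float = 0.98,
    K_a: int = 10,
    dyad_id: str = "",
    agent_role: str = "infant",
    plans: dict[str, PlanResult] | None = None,
) -> GoalPosterior:
    """Posterior over the four dyadic goals for one agent.

    The evidence for each goal marginalizes the softmax temperature
    (or epsilon) over its grid with a uniform grid prior, computed in
    log space.  Pre-solved ``plans`` (keyed by goal target) may be
    supplied to avoid re-running value iteration.
    """
    config = config or RationalityConfig()
    if plans is None:
        plans = solve_goal_plans(partner, gamma=gamma, K_a=K_a, agent_role=agent_role)

    if not episodes:
        logger.warning("dyad %s: no episodes; returning the goal prior", dyad_id)
        prior = config.goal_prior
        return GoalPosterior(
            dyad_id=dyad_id,
            agent_role=agent_role,
            p=prior / prior.sum(),
            log_evidence=np.zeros(4),
            map_goal=GOAL_TARGETS[int(np.argmax(prior))],
        )

    log_evidence = np.empty(4)
    for g, target in enumerate(GOAL_TARGETS):
        plan = plans[target]
        states, actions = _episode_state_actions(episodes, plan.mdp)
        if config.model == "softmax":
            grid_ll = _loglik_grid(states, actions, plan.Q, config.beta_grid)
        else:
            grid_ll = _loglik_grid_epsilon(
                states, actions, plan.policy, config.epsilon_grid
            )
        log_evidence[g] = logsumexp(grid_ll) - np.log(len(grid_ll))

    log_post = np.log(config.goal_prior) + log_evidence
    log_post -= logsumexp(log_post)
    p = np.exp(log_post)
    p /= p.sum()
    return GoalPosterior(
        dyad_id=dyad_id,
        agent_role=agent_role,
        p=p,
        log_evidence=log_evidence,
        map_goal=GOAL_TARGETS[int(np.argmax(p))],
    )


def solve_goal_plans(
    partner: HazardModel,
    gamma: float = 0.98,
    K_a: int = 10,
    agent_role: str = "infant",
) -> dict[str, PlanResult]:
    """Value-iterate the four candidate goals against one partner model."""
    plans = {}
    for target in GOAL_TARGETS:
        goal = GoalSpec(target=target, agent_role=agent_role)
        plans[target] = value_iteration(build_mdp(partner, goal, gamma=gamma, K_a=K_a))
    return plans


@dataclass
class CohortResult:
    """Cohort-level goal inference: per-dyad posteriors and summaries."""

    posteriors: list[GoalPosterior]
    table: pd.DataFrame  # one row per dyad with posterior columns
    map_counts: pd.Series  # dyads per MAP goal, GOAL_TARGETS order
    mean_posterior: pd.Series
    ci95_halfwidth: pd.Series


def infer_cohort(
    dataset: dict[str, list[SmileSeries]],
    agent_role: str = "infant",
    config: RationalityConfig | None = None,
    gamma: float = 0.98,
    K: int = 30,
    K_a: int = 10,
    alpha: float = 1.0,
    min_len_bins: int = 2,
    require_gaze: bool = True,
) -> CohortResult:
    """Infer each dyad's goal and summarize the cohort.

    ``dataset`` maps dyad id to that dyad's session series; episodes
    from all sessions of a dyad are pooled.  For each dyad the partner
    model is fit on the same episodes with the complementary role, the
    four goal plans are solved against it, and the agent's actions are
    scored.  Dyads with no usable episodes are excluded with a log
    message.
    """
    if not dataset:
        raise ValueError("dataset must contain at least one dyad")
    config = config or RationalityConfig()
    posteriors: list[GoalPosterior] = []
    for dyad_id in sorted(dataset):
        episodes: list[Episode] = []
        for series in dataset[dyad_id]:
            episodes.extend(
                extract_episodes(
                    series,
                    agent="mother" if agent_role == "mother" else "infant",
                    min_len_bins=min_len_bins,
                    require_gaze=require_gaze,
                )
            )
        if not episodes:
            logger.warning("dyad %s: no usable episodes; excluded", dyad_id)
            continue
        partner = fit_hazard(
            episodes,
            modeled_partner="infant" if agent_role == "mother" else "mother",
            K=K,
            alpha=alpha,
        )
        posteriors.append(
            goal_posterior(
                episodes,
                partner,
                config=config,
                gamma=gamma,
                K_a=K_a,
                dyad_id=dyad_id,
                agent_role=agent_role,
            )
        )
    if not posteriors:
        raise ValueError("no dyad had usable episodes")

    table = pd.DataFrame(
        [
            {
                "dyad_id": gp.dyad_id,
                **{f"p_{t}": gp.p[i] for i, t in enumerate(GOAL_TARGETS)},
                "map_goal": gp.map_goal,
            }
            for gp in posteriors
        ]
    )
    counts = (
        table["map_goal"].value_counts().reindex(GOAL_TARGETS, fill_value=0)
    )
    probs = table[[f"p_{t}" for t in GOAL_TARGETS]]
    mean = probs.mean()
    n = len(probs)
    sem = probs.std(ddof=1) / np.sqrt(n) if n > 1 else probs.std(ddof=0)
    from scipy.stats import t as t_dist

    crit = t_dist.ppf(0.975, n - 1) if n > 1 else np.nan
    ci = sem * crit
    mean.index = GOAL_TARGETS
    ci.index = GOAL_TARGETS
    return CohortResult(
        posteriors=posteriors,
        table=table,
        map_counts=counts,
        mean_posterior=mean,
        ci95_halfwidth=ci,
    )
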