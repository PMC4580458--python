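"""Optimal smile-timing policies against a fitted partner model.

The agent's decision problem is a discounted Markov decision process
over dyadic states (a, p, tau_a, tau_p): the agent's and partner's
smile states plus elapsed time since each last toggled.  Actions are
``keep`` (0) and ``toggle`` (1).  The agent's action takes effect
immediately for itself, but the partner's hazard is evaluated at the
pre-action agent state — a one-bin reaction latency matching the causal
ordering of turn-taking.  Reward is 1 whenever the post-transition
configuration matches the hypothesized goal, so the discounted value is
(up to normalization) the expected time spent in the goal configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from smilegames.dyad_io import Episode
from smilegames.partner_model import HazardModel

# canonical goal order: matches the four dyadic smile configurations
# (neither partner, infant only, mother only, both)
GOAL_TARGETS = ("neither", "infant_only", "mother_only", "mutual")

KEEP, TOGGLE = 0, 1


@dataclass(frozen=True)
class GoalSpec:
    """A dyadic goal: maximize time in one joint smile configuration.

    ``target`` names the configuration in mother/infant terms;
    ``agent_role`` fixes which channel is the agent, so the goal can be
    expressed as a target pair (agent smiling, partner smiling).  A
    robot agent playing the infant's part uses ``agent_role="robot"``
    with the human partner in the mother/partner slot.
    """

    target: str
    agent_role: str = "infant"

    def __post_init__(self) -> None:
        if self.target not in GOAL_TARGETS:
            raise ValueError(f"target must be one of {GOAL_TARGETS}")
        if self.agent_role not in ("infant", "mother", "robot"):
            raise ValueError("agent_role must be 'infant', 'mother' or 'robot'")

    @property
    def agent_partner_target(self) -> tuple[int, int]:
        """(agent smiling, partner smiling) defining the rewarded states."""
        infant, mother = {
            "neither": (0, 0),
            "infant_only": (1, 0),
            "mother_only": (0, 1),
            "mutual": (1, 1),
        }[self.target]
        if self.agent_role == "mother":
            return mother, infant
        return infant, mother

    def reward(self, a: int, p: int) -> int:
        return int((a, p) == self.agent_partner_target)


@dataclass(frozen=True)
class DyadState:
    """Joint state (agent smile, partner smile, elapsed times)."""

    a: int
    p: int
    tau_a: int = 0
    tau_p: int = 0


@dataclass
class DyadMDP:
    """Tabular decision problem: sparse two-outcome transitions per action."""

    goal: GoalSpec
    gamma: float
    K: int
    K_a: int
    hazard: np.ndarray = field(repr=False)  # (S,) partner toggle prob
    next_stay: np.ndarray = field(repr=False)  # (S, 2) successor, partner keeps
    next_toggle: np.ndarray = field(repr=False)  # (S, 2) successor, partner toggles
    reward: np.ndarray = field(repr=False)  # (S,) reward of being in state

    @property
    def n_states(self) -> int:
        return 4 * self.K_a * self.K

    def state_index(self, s: DyadState) -> int:
        if not (0 <= s.tau_a < self.K_a and 0 <= s.tau_p < self.K):
            raise ValueError("elapsed times exceed the model caps")
        return ((s.a * 2 + s.p) * self.K_a + s.tau_a) * self.K + s.tau_p

    def state_tuple(self, idx: int) -> DyadState:
        tau_p = idx % self.K
        idx //= self.K
        tau_a = idx % self.K_a
        idx //= self.K_a
        return DyadState(a=idx // 2, p=idx % 2, tau_a=tau_a, tau_p=tau_p)


@dataclass
class PlanResult:
    """Converged value function, action values and greedy policy."""

    goal: GoalSpec
    gamma: float
    mdp: DyadMDP
    V: np.ndarray = field(repr=False)
    Q: np.ndarray = field(repr=False)
    policy: np.ndarray = field(repr=False)
    residual: float = np.nan
    iterations: int = 0


def build_mdp(
    partner: HazardModel, goal: GoalSpec, gamma: float = 0.98, K_a: int = 10
) -> DyadMDP:
    """Assemble the agent's decision problem against a partner hazard model.

    Transition law per bin: the chosen action deterministically sets the
    agent's smile (toggle resets tau_a); the partner toggles with
    probability ``h[p, a, tau_p]`` evaluated at the *pre-action* agent
    state.  Reward is collected on the post-transition configuration.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie strictly between 0 and 1")
    if K_a < 1:
        raise ValueError("K_a must be >= 1")
    K = partner.K
    h = partner.h
    S = 4 * K_a * K

    a, p, tau_a, tau_p = _unravel_states(K_a, K)
    a_t, p_t = goal.agent_partner_target
    reward = ((a == a_t) & (p == p_t)).astype(float)
    hazard = h[p, a, tau_p]

    next_stay = np.empty((S, 2), dtype=np.int64)
    next_toggle = np.empty((S, 2), dtype=np.int64)
    for u in (KEEP, TOGGLE):
        a_next = a ^ u
        tau_a_next = np.where(u == TOGGLE, 0, np.minimum(tau_a + 1, K_a - 1))
        tau_p_stay = np.minimum(tau_p + 1, K - 1)
        next_stay[:, u] = _ravel(a_next, p, tau_a_next, tau_p_stay, K_a, K)
        next_toggle[:, u] = _ravel(a_next, 1 - p, tau_a_next, 0, K_a, K)

    return DyadMDP(
        goal=goal,
        gamma=gamma,
        K=K,
        K_a=K_a,
        hazard=hazard,
        next_stay=next_stay,
        next_toggle=next_toggle,
        reward=reward,
    )


def _unravel_states(K_a: int, K: int):
    S = 4 * K_a * K
    idx = np.arange(S)
    tau_p = idx % K
    rest = idx // K
    tau_a = rest % K_a
    rest //= K_a
    p = rest % 2
    a = rest // 2
    return a, p, tau_a, tau_p


def _ravel(a, p, tau_a, tau_p, K_a: int, K: int):
    return ((a * 2 + p) * K_a + tau_a) * K + tau_p


def value_iteration(
    mdp: DyadMDP, tol: float = 1e-9, max_iter: int = 100_000
) -> PlanResult:
    """Solve the MDP to a sup-norm Bellman residual below ``tol``."""
    gamma = mdp.gamma
    R = mdp.reward
    hz = mdp.hazard[:, None]
    V = np.zeros(mdp.n_states)
    Q = np.zeros((mdp.n_states, 2))
    for it in range(1, max_iter + 1):
        Q = (1.0 - hz) * (R[mdp.next_stay] + gamma * V[mdp.next_stay]) + hz * (
            R[mdp.next_toggle] + gamma * V[mdp.next_toggle]
        )
        V_new = Q.max(axis=1)
        residual = float(np.abs(V_new - V).max())
        V = V_new
        if residual < tol:
            return PlanResult(
                goal=mdp.goal,
                gamma=gamma,
                mdp=mdp,
                V=V,
                Q=Q,
                policy=Q.argmax(axis=1),
                residual=residual,
                iterations=it,
            )
    raise RuntimeError(
        f"value iteration did not converge in {max_iter} iterations "
        f"(residual {residual:.3e})"
    )


def wait_time_performance(
    plan: PlanResult, context: DyadState, t_max: int = 10
) -> np.ndarray:
    """Expected goal occupancy of fixed-wait strategies from a context state.

    ``performance[t]`` is the normalized discounted goal-state occupancy
    of the strategy "keep the current smile state for t bins, then
    toggle, and follow the optimal policy thereafter".  If the partner's
    state changes during the wait the commitment is abandoned and the
    agent follows the optimal policy from that point on.  The curve is
    evaluated by exact dynamic programming over partner trajectories and
    normalized by (1 - gamma) so values lie in [0, 1].  Fig-2-style
    context: the agent has just stopped smiling while the partner
    smiles, i.e. ``DyadState(a=0, p=1)``.
    """
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    mdp = plan.mdp
    gamma = plan.gamma
    R = mdp.reward
    hz = mdp.hazard
    # U[t][s]: value of "keep for t more bins then toggle, abort to the
    # optimal policy on a partner toggle"
    U = plan.Q[:, TOGGLE].copy()
    s_stay = mdp.next_stay[:, KEEP]
    s_tog = mdp.next_toggle[:, KEEP]
    abort = R[s_tog] + gamma * plan.V[s_tog]
    idx = mdp.state_index(context)
    curve = np.empty(t_max + 1)
    curve[0] = U[idx]
    for t in range(1, t_max + 1):
        U = (1.0 - hz) * (R[s_stay] + gamma * U[s_stay]) + hz * abort
        curve[t] = U[idx]
    return curve * (1.0 - gamma)


@dataclass
class WaitDistribution:
    """Empirical distribution of wait times from a context entry."""

    probs: pd.Series  # index t = 1..max observed wait, sums to 1
    n_observed: int
    n_censored: int


def empirical_wait_distribution(
    episodes: list[Episode], context: DyadState
) -> WaitDistribution:
    """Distribution of bins the agent waits before toggling out of a context.

    A context entry is a bin where the agent has just toggled into
    ``context.a`` while the partner is in ``context.p``.  The wait is
    the number of bins until the agent's next toggle; waits cut short by
    the episode end are right-censored and excluded from the
    distribution but counted.
    """
    waits: list[int] = []
    n_censored = 0
    for ep in episodes:
        agent = ep.agent_smile
        partner = ep.partner_smile
        n = len(agent)
        for i in range(1, n):
            if (
                agent[i] == context.a
                and agent[i - 1] != context.a
                and partner[i] == context.p
            ):
                later = np.flatnonzero(agent[i + 1 :] != context.a)
                if later.size:
                    waits.append(int(later[0]) + 1)
                else:
                    n_censored += 1
    if not waits:
        return WaitDistribution(
            probs=pd.Series(dtype=float), n_observed=0, n_censored=n_censored
        )
    counts = pd.Series(waits).value_counts().sort_index()
    full = counts.reindex(range(1, int(counts.index.max()) + 1), fill_value=0)
    return WaitDistribution(
        probs=full / full.sum(), n_observed=len(waits), n_censored=n_censored
    )
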